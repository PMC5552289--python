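"""Per-position track and interval (BED) input/output.

Two coordinate dialects are in play and the conversion is localized here:

* per-position track files are tab-delimited ``chrom<TAB>pos<TAB>value``
  with 1-based positions, optionally bgzip-compressed and tabix-indexed
  (the tabix "generic" preset);
* interval files are standard BED: 0-based, half-open.

A missing position in a track means *value absent*, not zero; consumers
must treat the two differently (an uncovered base is not a base with
coverage 0 recorded).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pysam

__all__ = [
    "PositionTrack",
    "IntervalSet",
    "read_track",
    "write_track",
    "read_intervals",
    "write_intervals",
]


@dataclass
class PositionTrack:
    """Sparse per-base values on one chromosome (1-based, sorted positions)."""

    chrom: str
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have equal length")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            bad = int(np.flatnonzero(np.diff(self.positions) <= 0)[0]) + 1
            raise ValueError(
                f"positions not strictly increasing at entry {bad} "
                f"(position {self.positions[bad]})"
            )

    def __len__(self) -> int:
        return int(self.positions.size)

    def slice(self, start: int, end: int) -> "PositionTrack":
        """Rows with 1-based position in ``[start, end]`` inclusive."""
        lo = np.searchsorted(self.positions, start, side="left")
        hi = np.searchsorted(self.positions, end, side="right")
        return PositionTrack(self.chrom, self.positions[lo:hi], self.values[lo:hi])

    def to_dense(self, length: int, fill: float = np.nan) -> np.ndarray:
        """Dense array of ``length`` entries for positions 1..length."""
        dense = np.full(length, fill)
        inside = self.positions <= length
        dense[self.positions[inside] - 1] = self.values[inside]
        return dense


class IntervalSet:
    """A set of 0-based half-open genomic intervals, normalized to sorted,
    non-overlapping form per chromosome."""

    def __init__(self, intervals: Sequence[tuple[str, int, int]] = ()) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"invalid interval {chrom}:{start}-{end} (start >= end)")
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        self._data: dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            self._data[chrom] = _merge_sorted(np.array(sorted(ivs), dtype=np.int64))

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def intervals(self) -> Iterator[tuple[str, int, int]]:
        for chrom in self.chroms:
            for start, end in self._data[chrom]:
                yield chrom, int(start), int(end)

    def __len__(self) -> int:
        return sum(arr.shape[0] for arr in self._data.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return list(self.intervals()) == list(other.intervals())

    def total_length(self) -> int:
        return int(
            sum((arr[:, 1] - arr[:, 0]).sum() for arr in self._data.values())
        )

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a single 0-based position."""
        arr = self._data.get(chrom)
        if arr is None or arr.shape[0] == 0:
            return False
        i = int(np.searchsorted(arr[:, 0], pos, side="right")) - 1
        return i >= 0 and pos < arr[i, 1]

    def mask(self, chrom: str, length: int) -> np.ndarray:
        """Boolean membership array for 0-based positions 0..length-1."""
        out = np.zeros(length, dtype=bool)
        for start, end in self._data.get(chrom, np.empty((0, 2), dtype=np.int64)):
            out[max(0, start) : min(length, end)] = True
        return out

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(list(self.intervals()) + list(other.intervals()))

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out: list[tuple[str, int, int]] = []
        for chrom in self._data:
            a, b = self._data[chrom], other._data.get(chrom)
            if b is None:
                continue
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i, 0], b[j, 0])
                e = min(a[i, 1], b[j, 1])
                if s < e:
                    out.append((chrom, int(s), int(e)))
                if a[i, 1] <= b[j, 1]:
                    i += 1
                else:
                    j += 1
        return IntervalSet(out)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        out: list[tuple[str, int, int]] = []
        for chrom, arr in self._data.items():
            cuts = other._data.get(chrom, np.empty((0, 2), dtype=np.int64))
            for start, end in arr:
                s = int(start)
                for cs, ce in cuts:
                    if ce <= s or cs >= end:
                        continue
                    if cs > s:
                        out.append((chrom, s, int(cs)))
                    s = max(s, int(ce))
                    if s >= end:
                        break
                if s < end:
                    out.append((chrom, s, int(end)))
        return IntervalSet(out)


def _merge_sorted(arr: np.ndarray) -> np.ndarray:
    if arr.shape[0] <= 1:
        return arr
    # merge strictly overlapping intervals; touching intervals stay separate
    # (feature lists like exons must not be collapsed)
    merged = [list(arr[0])]
    for start, end in arr[1:]:
        if start < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return np.array(merged, dtype=np.int64)


def _open_text(path: str | os.PathLike) -> io.TextIOBase:
    path = os.fspath(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(pysam.BGZFile(path))  # type: ignore[arg-type]
    return open(path)


def read_track(
    path: str | os.PathLike,
    region: tuple[str, int, int] | None = None,
) -> PositionTrack:
    """Read a 3-column track file (``chrom pos value``; 1-based positions).

    ``region`` is ``(chrom, start, end)`` with an inclusive 1-based range.
    For bgzip+tabix files with a region the index is used for random access;
    otherwise the file is streamed and filtered.  Only single-chromosome
    reads are supported: a plain full read of a multi-chromosome file raises.
    """
    path = os.fspath(path)
    if region is not None and os.path.exists(path + ".tbi"):
        chrom, start, end = region
        pos, val = [], []
        with pysam.TabixFile(path) as tbx:
            if chrom in tbx.contigs:
                for line in tbx.fetch(chrom, start - 1, end):
                    f = line.rstrip("\n").split("\t")
                    pos.append(int(f[1]))
                    val.append(float(f[2]))
        return PositionTrack(region[0], np.array(pos, dtype=np.int64), np.array(val))

    chrom_seen: str | None = None
    pos, val = [], []
    last = -1
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            try:
                c, p, v = f[0], int(f[1]), float(f[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed track line {lineno}: {line!r}") from exc
            if region is not None:
                if c != region[0] or not (region[1] <= p <= region[2]):
                    continue
            if chrom_seen is None:
                chrom_seen = c
            elif c != chrom_seen:
                raise ValueError(
                    f"{path}: line {lineno}: multiple chromosomes in one read "
                    f"({chrom_seen!r} then {c!r}); read per chromosome or pass region="
                )
            if p <= last:
                raise ValueError(f"{path}: line {lineno}: unsorted position {p} after {last}")
            last = p
            pos.append(p)
            val.append(v)
    chrom = chrom_seen if chrom_seen is not None else (region[0] if region else "")
    return PositionTrack(chrom, np.array(pos, dtype=np.int64), np.array(val))


def write_track(
    track: PositionTrack,
    path: str | os.PathLike,
    header: str | None = None,
    index: bool = False,
) -> None:
    """Write a track; ``.gz`` paths are bgzip-compressed, ``index=True`` adds tabix."""
    path = os.fspath(path)
    plain = path[:-3] if path.endswith(".gz") else path
    with open(plain, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for p, v in zip(track.positions, track.values):
            fh.write(f"{track.chrom}\t{p}\t{v:.12g}\n")
    if path.endswith(".gz"):
        pysam.tabix_compress(plain, path, force=True)
        os.remove(plain)
        if index:
            pysam.tabix_index(path, seq_col=0, start_col=1, end_col=1, force=True,
                              meta_char="#")


def read_intervals(path: str | os.PathLike) -> IntervalSet:
    """Read a BED file (0-based half-open) into a normalized IntervalSet."""
    out: list[tuple[str, int, int]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed BED line {lineno}: {line!r}") from exc
            if start >= end:
                raise ValueError(f"{path}: line {lineno}: start {start} >= end {end}")
            out.append((chrom, start, end))
    return IntervalSet(out)


def write_intervals(
    intervals: IntervalSet, path: str | os.PathLike, header: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for chrom, start, end in intervals.intervals():
            fh.write(f"{chrom}\t{start}\t{end}\n")
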