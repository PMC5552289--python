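# Methods

## Model

The score treats a genomic window as a region whose standing variation, in
a cohort of *n* diploid genomes, is compared against the constant-size
neutral coalescent expectation.  Under neutrality the expected number of
segregating sites with unfolded allele count *j* among 2n sampled
chromosomes is θ/j, θ = 4·N_e·μ.  Folding pairs classes *j* and 2n−j and
halves the self-paired class *j = n*:

ψ_i = θ·(1/i + 1/(2n−i)) / (1 + δ_{i,2n−i}),  i = 1…n.

The monomorphic class ψ₀ = κ − Σψ_i anchors the spectrum to the region
length, so both observed and expected spectra conserve κ (the number of
assessed bases).  The score is the normalized-weight inner product of the
observed-minus-expected spectrum, with weights ρ_i = 2n/(i+1) favouring
rare classes, divided by θ to cancel regional mutability differences, and
multiplied by a readability constant (default 10⁵).

Two consequences matter in practice:

* the score of a window with **no variants at all** is
  scale·(ρ̂₀·Σq_i − Σρ̂_i q_i) where ψ_i = θ·q_i — a closed-form constant
  independent of the window's mutation rate (`depleted_window_score`).
  It is the score ceiling and a natural unit for setting detection
  thresholds on synthetic data;
* deleting any variant strictly raises the score (the monomorphic class
  carries the heaviest weight), so the score is a monotone measure of
  depletion.

The neutral model is knowingly wrong for real human cohorts (bottleneck
and explosive growth inflate rare variation), so scores are interpreted
*relatively* — by comparing score populations between regions — never as
absolute departures from neutrality.

A note on units: composing the printed formula with its stated constants
(n = 1,662, N_e = 10⁴, mean rate 1.2×10⁻⁸, scale 10⁵) yields scores on
the order of ±10⁵, whereas published genome-wide tracks of this score
family are reported on an order-1 scale.  The discrepancy is a constant
factor and does not affect any relative comparison; this package follows
the formula as printed.  The default region criteria (−0.08 mean/median
floor, −0.1 minimum) are retained for use with order-1-scale published
tracks, and every synthetic-data analysis here derives its thresholds
from the data or from the depleted-window ceiling instead.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_samples` | 1,662 | diploid cohort size; SFS length n+1 |
| `effective_pop_size` | 10,000 | N_e in θ = 4·N_e·μ |
| `score_scale` | 100,000 | readability multiplier |
| `window_size` | 501 bp | odd, so the score lands on a center base |
| `min_site_coverage` | 0.7 | fraction of samples at GQ ≥ 20 for a site to count |
| `min_window_covered_fraction` | 0.5 | adequate-site fraction gating a window |
| `max_impute_gap` | 10 bp | longest absent run bridged by linear interpolation |
| `kappa_mode` | covered | κ counts adequate∧rated bases (`nominal`: window size) |
| mean mutation rate | 1.2×10⁻⁸ | genome-wide trinucleotide-rate normalization target |

Sites without a mutation-rate value (N contexts, chromosome ends) are
non-assessed: they contribute to neither κ, μ, nor the observed spectrum.
Windows whose centers are closer than (window−1)/2 to a chromosome end
get no score (no shrinking windows, keeping κ comparable); windows with
θ = 0 or with expected segregating sites exceeding κ are likewise absent.
The scan itself is exact O(L): the score decomposes into sliding sums
(variant count, summed variant weight, summed rate, adequate-site count),
algebraically identical to per-window SFS assembly — the test suite
checks the two routes against each other.  Chunked scans (bounded memory)
equal whole-chromosome scans up to float accumulation order (~10⁻¹⁴
relative).

## Region detection

A region is a contiguous scored stretch, 100–1000 bp, whose mean and
median clear one floor and whose minimum clears a lower one.  The
detector is defined by its output contract: among all criteria-satisfying
subintervals, repeatedly accept the longest (leftmost on ties), remove
its bases, and continue — deterministic, non-overlapping, and verified
against an exhaustive O(L²) enumeration oracle on instances up to 500
bases.  Satisfying runs longer than the cap are clipped into cap-length
pieces, not discarded.  Internally, candidate stretches are restricted to
maximal runs above the minimum-score floor (making that rule implicit),
prefiltered with rolling mean/median, and confirmed with exact
arithmetic so threshold-borderline intervals match the oracle.
Thresholds can be calibrated from a reference exon set: per-exon
mean/median/min, then across-exon mean + k·SD (sample SD, divisor k−1;
median of an even count is the midpoint of the central pair).

## Synthetic data, and what passing tests do and do not show

`orion.fixtures` generates every pipeline input: a random reference
sequence, a per-base rate track (lognormal jitter, σ = 0.1, renormalized
exactly to the 1.2×10⁻⁸ mean), a coverage track with a 1% dropout rate,
and a variant track whose sites are Bernoulli-placed with the neutral
per-base intensity 4·N_e·r_i·Σq_i and whose folded allele counts are
drawn from the normalized expected-SFS class probabilities.  A fully
neutral fixture therefore scores 0 in expectation *by construction*; the
test suite verifies this within Monte-Carlo error using an effective
sample size of (scored positions)/window, since overlapping windows are
strongly autocorrelated.  Embedded segments multiply the variant
intensity by a depletion factor (0 = fully depleted) and are exported as
a truth set.

What the generator does **not** emulate: demographic excess of rare
variation (real cohorts carry several-fold more rare variants than the
neutral expectation — that distortion is the simulator's job), linkage
between sites, sequencing artifacts, or repeat-driven coverage structure.
Passing the recovery benchmark shows the scan-plus-detector machinery
recovers depletion at the stated signal strength; it does not certify
performance on real cohort data.

Detectability on neutral-density data has a hard information-theoretic
limit worth stating: the neutral variant intensity at these parameters is
≈0.0042/bp (mean inter-variant gap ≈240 bp), so a neutral variant-free
stretch of 600 bp arises with probability ≈8% per gap — and such a
stretch is *data-identical* to a fully depleted 600-bp segment.  Short
depleted segments are therefore undetectable at useful precision
regardless of algorithm.  Discriminability grows exponentially with
length, so the recovery benchmark operates at the longest allowed region
length (min = max = 1000 bp, thresholds 0.9/0.85 of the depleted-window
ceiling, i.e. only variant-free windows qualify) against 1.6-kb fully
depleted truth segments; measured over 10 seeded 20-kb fixtures this
yields precision 0.95 and recall 1.0.

## Statistics

The permuted Mann–Whitney U test computes the observed two-sided p, then
reshuffles group labels n_p times (default 1,000); G counts permutations
whose p-value the observed p equals or exceeds, and the reported p-value
is (G+1)/(n_p+1), floored at 1/(n_p+1).  Fully tied inputs return p = 1
by definition rather than erroring.  Fisher enrichment reports the sample
odds ratio (a·d)/(b·c) and the two-sided exact p by the point-probability
method (scipy), cross-checked against a hypergeometric brute-force sum.
Random score draws are chromosome-first (uniform chromosome, then uniform
eligible position) so small chromosomes are represented equally, with
exclusion intervals honoured.  The cohort's minimal representable MAF,
1/(2n), is the exclusion floor for external benign/control variant sets.

## Simulator

Forward Wright–Fisher, diploid, non-recombining, infinite sites: each
generation draws fitness-weighted parent pairs, transmits one haplotype
per parent, introduces Poisson(2N·L·μ) new mutations at fresh sites with
s ~ Gamma(shape, scale = 0.32) clamped to [0, 1], and retires fixed/lost
sites.  Genotype fitnesses are 1, 1−0.5s, 1−s; individual fitness is the
product over loci.  (An exponential multi-locus shorthand sometimes
written for this design, e^{−Σ(1−S_i)}, would penalize wild-type loci;
the multiplicative composition of the genotype fitnesses is the
self-consistent choice, and the selection-response property is
insensitive to it.)  The three-stage demography (long burn-in,
brief bottleneck, exponential growth) emulates recent explosive human
population growth.  The desk preset (500 × 5,000 generations; 450 × 50;
growth to 5,000 over 100; L = 2 kb; sample 50) holds N₀·μ at the
full-scale value (μ_desk = 1.8×10⁻⁸ × 8100/500 ≈ 2.92×10⁻⁷) so
per-base diversity is comparable while a full selection grid runs in
seconds; full-scale parameters remain available behind a flag with a
runtime warning.

Validation: under neutrality with constant demography the sampled folded
SFS matches `expected_sfs` — compared per binned class using z-scores
with the *empirical* across-replicate variance, because site counts
within a replicate share genealogy and are super-Poisson, which makes a
plain Poisson chi-square anti-conservative.  Under the desk demography
the Spearman correlation of mean score with the gamma shape parameter is
positive (measured ρ = 1.0 on the default 5-point grid), confirming the
score tracks selection strength.  The expected-SFS reference for
simulated samples uses N_e = the burn-in population size; any N_e
misspecification shifts all shapes' scores equally and cannot affect the
rank correlation.

## Problem sizes

Default analyses run on 6–20 kb synthetic chromosomes, cohorts of 1,662
(fixtures) or 10–50 (simulations) samples, 10–20 simulation replicates
per condition and 1,000-permutation tests; these sizes give the
Monte-Carlo properties comfortable margins while keeping the full suite
fast.

## Known limitations

* Absolute score units follow the printed formula, not published tracks
  (constant factor; see above).
* The neutral expectation ignores demography; scores are relative.
* Multi-allelic sites keep only the highest-AC alternate; the AC rounding
  convention (half away from zero, minimum 1 for polymorphic sites) is
  one of several defensible readings and `round|floor|fractional` are all
  exposed.
* The region detector's tie-breaking (longer, then leftmost; greedy
  exclusion) is this package's deterministic definition of
  criteria-based segment detection; other flooding-style implementations
  may break ties differently.
* No recombination or migration in the simulator; X/Y chromosomes are not
  treated specially anywhere.
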