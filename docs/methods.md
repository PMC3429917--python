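# Methods

## The problem

A QTL genome scan tests, at each of `n_m` markers, whether the phenotype
mean differs between the two genotype classes of a backcross (BC) or
doubled-haploid (DH) cross. The standard way to control the genome-wide
Type-I error rate (GWER) is the permutation approach of Churchill and
Doerge (CD): shuffle the phenotype vector many times, record the maximum
LOD score of each shuffled scan, and declare significance above the
`(1 − γ)` quantile of that empirical max-LOD distribution.

The CD threshold is constant across the genome, but the *location* of
the maximum under the null need not be uniform: when the distribution of
the max-LOD statistic `M = (δ, λ)` — magnitude `δ` and marker index `λ` —
has a non-uniform `λ` marginal (location bias), a constant threshold
concentrates false positives at the markers that attain the maximum
most often. The location-dependent threshold (LDT) removes this: it
targets the *joint* event

    P{δ > T_i, λ = i} = γ / n_m       for every marker i,

so the GWER is still `γ` but each marker carries an equal share of the
error budget — a constant local (comparison-wise) error rate.

## Construction

From `n_p` permutation draws of `(δ, λ)`:

* `p_i = P̂{λ = i}` — the empirical location distribution;
* `α_i = 1 / (n_m p_i)` — the location-bias factor (`α_i = 1` means
  marker `i` attains the maximum at exactly its uniform share);
* `T_LDT,i` — the empirical quantile of `δ` *conditioned on* `λ = i`
  at exceedance level `γ·α_i`.

Then the number of draws with `δ > T_i` and `λ = i` is at most
`⌊γ·n_p/n_m⌋` at every marker, which is the defining property. Where
`α_i > 1` (under-represented marker) the threshold drops below the
conditional-`γ` quantile; where `α_i < 1` it rises.

**Validity range.** The conditional exceedance level `γ·α_i` must stay
below 1, so the construction exists iff `γ < min_i{1/α_i} =
n_m·min_i p_i`. The constructor raises a descriptive error at or above
the bound. (The source material states the preserved range inconsistently
in one place — as `(min_i{1/α_i}, 1)` — but the existence condition and
the explicit interval `(0, min_i{1/α_i})` agree, and this package follows
them.) `ThresholdResult.valid_range_upper` always reports the bound.

**Adjusted P-values.** The CD-adjusted P-value of an observed LOD is the
marginal permutation P-value `(r + 1)/(n_p + 1)` with `r` the number of
sampled maxima `≥` the observation (add-one convention: valid, never
zero). The LDT-adjusted P-value at marker `i` is
`n_m·(r_i + 1)/(n_p + 1)` with `r_i` counting only draws at that marker
— a linear transformation (division by `α_i`) of the location-
conditioned P-value, and the smallest `γ` at which the observation would
cross `T_LDT,i`. It is capped at 1 for reporting; the uncapped value and
the marker's attainable maximum `1/α_i` are exposed because above
`1/α_i` the LDT family no longer covers the marker.

**Quantile convention.** All thresholds are order statistics of the
sampled values: the smallest sampled value whose *strict* exceedance is
at most the target. The realised error rate is therefore never above the
nominal one; with continuous phenotypes the shortfall is at most one
quantile step (`n_m/n_p` genome-wide). No kernel or parametric smoothing
is applied anywhere — every probability is a ratio of counts.

**Sampling depth.** Conditional quantiles need counts at every marker:
`n_p` should satisfy `n_p·p_i ≳ 1000` for all `i`
(`required_permutations`), with `5000·n_m` as the default rule of thumb
for moderate bias. A marker with zero conditional draws is a hard,
named error (with the depth rule in the message); Laplace `+1` smoothing
of the location counts is available only behind an explicit flag.

## LOD score

Single-marker regression with Gaussian errors:
`LOD = (n/2)·log10(RSS0/RSS1) = −(n/2)·log10(1 − R²)`. Monomorphic
markers and constant phenotypes score 0 so that permuted datasets always
yield a full scan. Only permutation *ranks* of the max enter the
thresholds, so any monotone-equivalent scan statistic gives identical
thresholds; absolute LOD scales from other software may differ slightly.
Argmax ties (measure-zero for continuous phenotypes) are broken uniformly
at random by default — a deterministic first-index rule would itself
inject location bias toward low indices.

## Simulator

Genotypes: per individual and chromosome, a two-state Markov chain —
first marker fair-coin, each subsequent marker flipping with the
interval's recombination fraction `r` (0 < r ≤ 0.5 within a chromosome;
chromosome boundaries behave as r = 0.5). Maps are specified either as
cM positions (converted by the Haldane function
`r = (1 − e^{−2d/100})/2`, i.e. no crossover interference) or as explicit
per-interval `r`, which takes precedence. BC and DH crosses are both
two-class and coded 0/1 identically. Null phenotypes are i.i.d. standard
normal; an optional additive QTL adds `effect × genotype` at one marker.

What the generator does *not* emulate: missing genotypes (rejected by
design), segregation distortion, crossover interference, epistasis,
non-Gaussian phenotypes, multi-allele crosses. Passing tests therefore
demonstrate the error-rate guarantees under clean two-class crosses with
complete data; on real data the permutation logic is identical but those
features can change the location distribution itself (which the method
estimates empirically anyway).

`simulate_balanced_unlinked` builds the exchangeable reference
condition — independent columns with *exactly* `n/2` individuals per
class, one marker per chromosome. Exact balance matters: conditional on
a realized genotype matrix, a marker's permutation LOD distribution
depends on its class split, so binomially sampled columns are only
approximately exchangeable and the CD ≡ LDT equivalence holds only up to
that imbalance.

## Bias diagnostics

`chisq_uniformity` tests the `λ` counts against uniformity
(`Σ(O_i − E)²/E`, `E = n_p/n_m`, `n_m − 1` df; upper-tail P from scipy).
The recombination sweep runs 11 levels `r = 0.01, 0.04, …, 0.31` on 10
equally spaced markers × 200 BC individuals, 300 replicates by default
(the packaged experiments use 30), 2,000 permutations per replicate
(≥ 100 expected per marker under uniformity; the per-replicate depth is
this package's choice). The 95th-percentile reference line is computed
from the χ² quantile function, never hard-coded. The observed pattern —
median statistics falling from ≫ the 95% cutoff at r = 0.01 to below it
by r = 0.31 — supports linkage tightness as a driver of location bias.

## Reproducibility and numerics

Permutations are generated in fixed 1,000-draw chunks; chunk `k` of root
seed `s` draws from `SeedSequence(s, spawn_key=(k,))`, so results are
independent of scheduling and a long run equals the concatenation of
chunk-aligned shorter runs (`chunk_offset`). The scan kernel is a single
BLAS matrix product per chunk (`X'Y` over all markers × permutations),
making 10⁵-draw runs a matter of seconds at the packaged problem sizes
(150–200 individuals, 10–34 markers). Count targets use
`⌊target·n + 10⁻⁹⌋` to guard the floor against floating-point error.
Degenerate inputs (R² = 1) yield `inf` LOD rather than an exception.

## Problem sizes used by the packaged experiments

* GWER calibration: DH, `n_obs = 150`, `n_m = 20` on 2 chromosomes with
  mixed 2-cM/16-cM spacing, `γ = 0.20`, `n_p = 100,000 = 5000·n_m` to
  build and an independent 100,000 to evaluate. Holdout GWER lands
  within 3 SE of `γ`; per-marker shares within 3 SE of `γ/n_m` (the SE
  budget of the holdout proportion; the build-side quantile noise is of
  the same order, so per-marker deviations near the edge of that band
  are expected occasionally).
* Equivalence: 10 balanced unlinked markers, `n_obs = 150`,
  `n_p = 50,000`.
* Sweep: 30 replicates per level (medians over 30 are stable enough to
  show the monotone trend with at most one inversion).

## Known limitations

* Marker-based only: no interval mapping or on-grid pseudomarkers.
* Two genotype classes only (BC/DH); F2 dominance is out of scope.
* Complete data required; no imputation.
* Near the validity bound `γ → min_i{1/α_i}` the LDT threshold at the
  most biased marker is driven by the location parameter alone and the
  adjusted P-values saturate at `1/α_i`; the package exposes the bound
  rather than extrapolating beyond it.
* Markers that essentially never attain the maximum make the LDT
  philosophy itself debatable (comparing an observed LOD with a
  conditional *max* distribution that has almost no mass); mixture-of-
  order-statistics alternatives are not implemented.
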