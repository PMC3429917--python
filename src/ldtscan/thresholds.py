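"""Empirical genome-wide thresholds and adjusted P-values.

Two permutation-based constructions of a genome-wide significance
threshold for a desired genome-wide error rate (GWER) ``gamma``:

* **CD** (Churchill-Doerge): the constant threshold ``T_CD`` with
  marginal exceedance ``P{delta > T_CD} = gamma``.  It controls the
  GWER but, when the location distribution of the maximum is not
  uniform (location bias), lets the local Type-I rate vary from marker
  to marker.

* **LDT** (location-dependent threshold): a per-marker threshold with
  ``P{delta > T_LDT,i, lambda = i} = gamma / n_m`` at every marker —
  the GWER is still ``gamma`` but each marker contributes the same
  share, so the local error rate is constant across the genome.

With the location-bias factor ``alpha_i = 1 / (n_m * P{lambda = i})``,
the LDT threshold at marker ``i`` is the location-conditioned quantile
of delta at exceedance level ``gamma * alpha_i``.  The construction
exists only for ``gamma < min_i {1 / alpha_i} = n_m * min_i P{lambda=i}``;
above that bound the most under-represented marker cannot reach its
share of the error budget.  When all markers are exchangeable
(``alpha_i = 1`` everywhere) the LDT and CD thresholds coincide.

All estimates are plain ratios of counts over the permutation sample;
no smoothing or parametric fitting is applied to the delta
distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sampler import MaxLodSample, required_permutations

__all__ = [
    "LocationDistribution",
    "ThresholdResult",
    "location_distribution",
    "empirical_exceedance",
    "quantile_threshold",
    "cd_threshold",
    "conditional_threshold",
    "ldt_threshold",
    "cd_adjusted_p",
    "ldt_adjusted_p",
    "ldt_adjusted_p_detail",
    "validity_range",
    "joint_exceedance",
]

_EPS = 1e-9  # guards floor() against floating error in count targets


@dataclass(frozen=True)
class LocationDistribution:
    """Estimated distribution of the max-LOD location, with bias factors.

    ``alpha[i] = 1 / (n_m * p_lambda[i])`` measures location bias at
    marker ``i+1``: 1 means the marker attains the genome-wide maximum at
    exactly its uniform share, above 1 less often, below 1 more often.
    Markers never observed at the maximum are listed in
    ``zero_count_markers`` and carry ``alpha = nan``.
    """

    p_lambda: np.ndarray
    alpha: np.ndarray
    counts: np.ndarray
    n_p: int
    zero_count_markers: tuple[int, ...] = ()
    smoothed: bool = False

    def __post_init__(self) -> None:
        p = np.asarray(self.p_lambda, dtype=float)
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("p_lambda must sum to 1")
        object.__setattr__(self, "p_lambda", p)
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts))

    @property
    def n_m(self) -> int:
        return self.p_lambda.size


@dataclass(frozen=True)
class ThresholdResult:
    """A per-marker threshold sequence with its target GWER.

    ``T`` is constant for method 'CD' and location-dependent for
    'conditional' and 'LDT'.  ``valid_range_upper`` is
    ``min_i {1/alpha_i}``, the supremum of GWER levels at which an LDT
    construction exists for this sample.
    """

    T: np.ndarray
    gamma: float
    method: str
    valid_range_upper: float

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        if np.any(T < 0):
            raise ValueError("thresholds must be non-negative")
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must be in (0, 1)")
        if self.method not in ("CD", "conditional", "LDT"):
            raise ValueError(f"unknown method {self.method!r}")
        object.__setattr__(self, "T", T)


def location_distribution(sample: MaxLodSample, smoothing: bool = False) -> LocationDistribution:
    """Estimate P{lambda = i} and the bias factors alpha_i from a sample.

    With ``smoothing=True`` a Laplace +1 count is added at every marker,
    giving every location positive estimated mass; the default reports
    the raw counts and flags zero-count markers instead.
    """
    counts = sample.lam_counts().astype(float)
    n_p = sample.n_p
    if smoothing:
        counts = counts + 1.0
        n_p += sample.n_m
    p = counts / counts.sum()
    zero = tuple((np.flatnonzero(counts == 0) + 1).tolist())
    with np.errstate(divide="ignore"):
        alpha = np.where(counts > 0, 1.0 / (sample.n_m * np.where(p > 0, p, 1.0)), np.nan)
    return LocationDistribution(p, alpha, counts.astype(np.int64), n_p, zero, smoothing)


def empirical_exceedance(values: np.ndarray, t: float) -> float:
    """Fraction of sampled values strictly greater than ``t``."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    return float(np.count_nonzero(v > t)) / v.size


def quantile_threshold(values: np.ndarray, target_exceedance: float) -> float:
    """Smallest sampled value whose strict exceedance is <= the target.

    The threshold is always one of the sampled order statistics, chosen
    conservatively: the achieved exceedance is the largest value not
    exceeding ``target_exceedance``, so the realised error rate never
    exceeds the nominal one.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty sample")
    if not 0 < target_exceedance <= 1:
        raise ValueError("target exceedance must be in (0, 1]")
    k = int(np.floor(target_exceedance * v.size + _EPS))  # allowed count above t*
    if k >= v.size:
        return float(v[0])
    return float(v[v.size - k - 1])


def _conditional_or_raise(sample: MaxLodSample, marker: int, what: str) -> np.ndarray:
    cond = sample.conditional_deltas(marker)
    if cond.size == 0:
        hint = required_permutations(sample.n_m)
        raise ValueError(
            f"marker {marker} never attained the genome-wide maximum in {sample.n_p} "
            f"permutations; {what} is undefined there. Deeper sampling is required "
            f"(rule of thumb: n_p >= 5000 * n_m = {hint}, enough that every marker "
            "accumulates ~1000 conditional draws)."
        )
    return cond


def cd_threshold(sample: MaxLodSample, gamma: float) -> ThresholdResult:
    """Churchill-Doerge threshold: the gamma-exceedance quantile of the
    marginal max-LOD distribution, constant across markers."""
    if not 0 < gamma < 1:
        raise ValueError("gamma must be in (0, 1)")
    t = quantile_threshold(sample.deltas, gamma)
    ld = location_distribution(sample)
    return ThresholdResult(np.full(sample.n_m, t), gamma, "CD", validity_range(ld))


def conditional_threshold(sample: MaxLodSample, gamma: float) -> ThresholdResult:
    """Per-marker threshold with constant *conditional* exceedance:
    P{delta > T_i | lambda = i} = gamma at every marker.

    This controls the local rate relative to each marker's own share of
    maxima but not the GWER; it is the intermediate object from which
    the LDT threshold is derived.
    """
    if not 0 < gamma < 1:
        raise ValueError("gamma must be in (0, 1)")
    T = np.empty(sample.n_m)
    for i in range(1, sample.n_m + 1):
        cond = _conditional_or_raise(sample, i, "a conditional threshold")
        T[i - 1] = quantile_threshold(cond, gamma)
    ld = location_distribution(sample)
    return ThresholdResult(T, gamma, "conditional", validity_range(ld))


def ldt_threshold(sample: MaxLodSample, gamma: float, smoothing: bool = False) -> ThresholdResult:
    """Location-dependent threshold preserving GWER with a constant local rate.

    ``T_LDT,i`` is the location-conditioned quantile of delta at
    exceedance level ``gamma * alpha_i``; the joint exceedance
    ``P{delta > T_i, lambda = i}`` then equals ``gamma / n_m`` at every
    marker (up to quantile-step discreteness), summing to GWER ``gamma``.
    Where ``alpha_i > 1`` (marker under-represented at the maximum) the
    threshold drops below the conditional one; where ``alpha_i < 1`` it
    rises.

    Raises ``ValueError`` when ``gamma >= min_i {1/alpha_i}`` — beyond
    that bound the required conditional exceedance level ``gamma *
    alpha_i`` reaches 1 at some marker and no threshold exists.
    """
    if not 0 < gamma < 1:
        raise ValueError("gamma must be in (0, 1)")
    ld = location_distribution(sample, smoothing=smoothing)
    if ld.zero_count_markers:
        _conditional_or_raise(sample, ld.zero_count_markers[0], "an LDT threshold")
    upper = validity_range(ld)
    if gamma >= upper:
        raise ValueError(
            f"LDT threshold exists only for gamma < min_i(1/alpha_i) = {upper:.6g}; "
            f"requested gamma = {gamma:.6g} is outside the valid range (0, {upper:.6g})"
        )
    T = np.empty(sample.n_m)
    for i in range(1, sample.n_m + 1):
        cond = sample.conditional_deltas(i)
        T[i - 1] = quantile_threshold(cond, gamma * ld.alpha[i - 1])
    return ThresholdResult(T, gamma, "LDT", upper)


def cd_adjusted_p(sample: MaxLodSample, observed_lod: float) -> float:
    """Marginal permutation P-value of an observed LOD score.

    Uses the add-one convention ``(r + 1) / (n_p + 1)`` with ``r`` the
    number of sampled maxima >= the observed score, so the result is a
    valid P-value and never exactly 0.
    """
    r = int(np.count_nonzero(sample.deltas >= observed_lod))
    return (r + 1) / (sample.n_p + 1)


def ldt_adjusted_p(sample: MaxLodSample, observed_lod: float, marker: int) -> float:
    """Location-adjusted permutation P-value at a marker (1-based).

    The smallest GWER at which the observed score would cross the LDT
    threshold at this marker: ``n_m`` times the joint exceedance
    estimate, i.e. a linear transformation of the location-conditioned
    P-value (conditional P divided by ``alpha_i``).  Capped at 1 for
    reporting; see :func:`ldt_adjusted_p_detail` for the uncapped value
    and the marker's attainable maximum ``1/alpha_i``.
    """
    return ldt_adjusted_p_detail(sample, observed_lod, marker)[0]


def ldt_adjusted_p_detail(
    sample: MaxLodSample, observed_lod: float, marker: int
) -> tuple[float, float, float]:
    """(capped P, uncapped P, max attainable 1/alpha_i) at a marker.

    The uncapped value can exceed 1 when the observed score is small at
    an over-represented marker; the attainable maximum ``1/alpha_i`` is
    the GWER level above which the LDT construction no longer covers
    this marker.
    """
    if not 1 <= marker <= sample.n_m:
        raise ValueError(f"marker must be in 1..{sample.n_m}, got {marker}")
    cond = sample.conditional_deltas(marker)
    r = int(np.count_nonzero(cond >= observed_lod))
    p_unc = sample.n_m * (r + 1) / (sample.n_p + 1)
    max_attainable = sample.n_m * cond.size / sample.n_p
    return min(1.0, p_unc), p_unc, max_attainable


def validity_range(ld: LocationDistribution) -> float:
    """Upper bound of the GWER range on which an LDT threshold exists.

    Equals ``min_i {1/alpha_i} = n_m * min_i P{lambda = i}``; 0 when some
    marker was never observed at the maximum.
    """
    if ld.zero_count_markers:
        return 0.0
    return float(ld.n_m * ld.p_lambda.min())


def joint_exceedance(sample: MaxLodSample, T: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-marker joint exceedance rates of a threshold sequence.

    Entry ``i`` is ``#{j : delta_j > T_i, lambda_j = i+1} / n_p``; the
    second return value is the genome-wide total (the empirical GWER of
    ``T`` on this sample).
    """
    T = np.asarray(T, dtype=float)
    if T.shape != (sample.n_m,):
        raise ValueError("threshold length must equal the marker count")
    per = np.array(
        [
            np.count_nonzero(sample.deltas[sample.lams == i] > T[i - 1])
            for i in range(1, sample.n_m + 1)
        ],
        dtype=float,
    ) / sample.n_p
    return per, float(per.sum())
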