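"""Single-marker-regression genome scans.

The LOD score at a marker compares the Gaussian likelihood of a one-way
model (phenotype mean differs between the two genotype classes) with the
null model of a common mean:

    LOD = (n/2) * log10(RSS0 / RSS1) = -(n/2) * log10(1 - R^2),

where RSS0/RSS1 are the null and fitted residual sums of squares and R^2
is the squared correlation between the genotype indicator and phenotype.
The max-LOD statistic of a scan is the pair M = (delta, lambda): the
largest LOD value and the (1-based) index of a marker attaining it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GenomeScan", "MaxLod", "marker_lod", "genome_scan", "max_lod", "lod_matrix"]

TIE_RULES = ("first", "random")


@dataclass(frozen=True)
class GenomeScan:
    """Per-marker LOD scores aligned to a marker map."""

    lod: np.ndarray
    markers: tuple[str, ...]

    def __post_init__(self) -> None:
        lod = np.asarray(self.lod, dtype=float)
        if lod.ndim != 1 or lod.size == 0:
            raise ValueError("lod must be a non-empty vector")
        if len(self.markers) != lod.size:
            raise ValueError("marker names and LOD vector lengths differ")
        if np.any(lod < 0) or np.any(np.isnan(lod)):
            raise ValueError("LOD scores must be non-negative")
        object.__setattr__(self, "lod", lod)

    @property
    def n_markers(self) -> int:
        return self.lod.size


@dataclass(frozen=True)
class MaxLod:
    """The max-LOD statistic M = (delta, lam); ``lam`` is 1-based."""

    delta: float
    lam: int


def marker_lod(genotype_column: np.ndarray, phenotype: np.ndarray) -> float:
    """LOD score of single-marker regression at one marker.

    Computed from residual sums of squares of the two-group fit.  A
    monomorphic marker (single genotype class) or a constant phenotype
    carries no information and scores 0.  A perfect fit (RSS1 = 0 with
    RSS0 > 0) yields ``inf``; this has probability zero for continuous
    phenotypes but can arise in contrived inputs.
    """
    g = np.asarray(genotype_column)
    y = np.asarray(phenotype, dtype=float)
    if g.shape != y.shape or g.ndim != 1:
        raise ValueError("genotype and phenotype must be equal-length vectors")
    n = g.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not np.isfinite(y).all():
        raise ValueError("phenotypes must be finite")
    if not np.isin(g, (0, 1)).all():
        raise ValueError("genotype column must contain only 0/1")
    mask1 = g == 1
    n1 = int(mask1.sum())
    if n1 == 0 or n1 == n:
        return 0.0  # monomorphic
    rss0 = float(((y - y.mean()) ** 2).sum())
    if rss0 == 0.0:
        return 0.0  # constant phenotype
    y1, y0 = y[mask1], y[~mask1]
    rss1 = float(((y1 - y1.mean()) ** 2).sum() + ((y0 - y0.mean()) ** 2).sum())
    if rss1 == 0.0:
        return float("inf")
    return max(0.0, (n / 2.0) * np.log10(rss0 / rss1))


def lod_matrix(genotypes: np.ndarray, phenotypes: np.ndarray) -> np.ndarray:
    """Vectorised LOD scores for a batch of phenotype vectors.

    Parameters
    ----------
    genotypes
        ``n_obs x n_m`` 0/1 matrix.
    phenotypes
        ``n_obs x B`` matrix of B phenotype vectors (columns).

    Returns
    -------
    ``n_m x B`` matrix of LOD scores, algebraically identical to calling
    :func:`marker_lod` per column pair (via the 1 - R^2 identity).
    """
    X = np.asarray(genotypes, dtype=float)
    Y = np.asarray(phenotypes, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    n1 = X.sum(axis=0)
    sxx = n1 - n1 * n1 / n  # per-marker genotype sum of squares about the mean
    ybar = Y.mean(axis=0)
    syy = (Y * Y).sum(axis=0) - n * ybar * ybar
    cross = X.T @ Y - np.outer(n1, ybar)
    denom = np.outer(sxx, syy)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, cross * cross / np.where(denom > 0, denom, 1.0), 0.0)
        lod = np.where(r2 < 1.0, -(n / 2.0) * np.log10(np.maximum(1.0 - r2, 0.0)), np.inf)
    return np.maximum(lod, 0.0)


def genome_scan(pop) -> GenomeScan:
    """LOD scores at every marker of a cross, in map order."""
    lod = lod_matrix(pop.genotypes, pop.phenotypes)[:, 0]
    return GenomeScan(lod, pop.map.markers)


def max_lod(
    scan: GenomeScan,
    tie_rule: str = "random",
    rng: "np.random.Generator | int | None" = None,
) -> MaxLod:
    """Extract M = (delta, lambda) from a scan.

    With ``tie_rule='random'`` (default) an argmax tie is resolved
    uniformly at random; a deterministic 'first' rule would bias the
    location distribution toward low marker indices whenever exact ties
    occur.  ``rng`` may be a seed or Generator for reproducibility.
    """
    if tie_rule not in TIE_RULES:
        raise ValueError(f"tie_rule must be one of {TIE_RULES}")
    lod = scan.lod
    delta = float(lod.max())
    ties = np.flatnonzero(lod == delta)
    if tie_rule == "first" or ties.size == 1:
        lam = int(ties[0]) + 1
    else:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        lam = int(gen.choice(ties)) + 1
    return MaxLod(delta, lam)
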