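"""Permutation sampling of the max-LOD statistic M = (delta, lambda).

Both the Churchill-Doerge and the location-dependent threshold methods
rest on the same empirical null: repeatedly shuffle the phenotype vector
(breaking any genotype-phenotype association while preserving the
genotype correlation structure), rescan the genome, and record the
magnitude and location of the maximum LOD score.  The full list of
(delta, lambda) pairs is retained because location-conditioned quantiles
at arbitrary levels are needed downstream.

Reproducibility contract
------------------------
Permutations are generated in fixed-size chunks of ``CHUNK_SIZE``.
Chunk ``k`` of a run with root seed ``s`` draws from
``SeedSequence(s, spawn_key=(k,))``, so results do not depend on how
chunks are scheduled, and a run of ``2 * CHUNK_SIZE`` permutations equals
the concatenation of two runs of ``CHUNK_SIZE`` started at chunk offsets
0 and 1 (see ``chunk_offset``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .scan import TIE_RULES, lod_matrix

__all__ = ["CHUNK_SIZE", "MaxLodSample", "sample_max_lod", "required_permutations"]

CHUNK_SIZE = 1000


@dataclass(frozen=True)
class MaxLodSample:
    """``n_p`` permutation draws of (delta, lambda); lambdas are 1-based."""

    deltas: np.ndarray
    lams: np.ndarray
    n_m: int
    seed: int | None = None
    tie_rule: str = "random"

    def __post_init__(self) -> None:
        d = np.asarray(self.deltas, dtype=float)
        l = np.asarray(self.lams, dtype=np.int64)
        if d.ndim != 1 or d.size == 0 or d.shape != l.shape:
            raise ValueError("deltas and lams must be equal-length non-empty vectors")
        if np.any(d < 0):
            raise ValueError("deltas must be non-negative")
        if np.any((l < 1) | (l > self.n_m)):
            raise ValueError(f"lambdas must be marker indices in 1..{self.n_m}")
        object.__setattr__(self, "deltas", d)
        object.__setattr__(self, "lams", l)

    @property
    def n_p(self) -> int:
        return self.deltas.size

    def conditional_deltas(self, marker: int) -> np.ndarray:
        """Deltas of the draws whose maximum occurred at ``marker`` (1-based)."""
        if not 1 <= marker <= self.n_m:
            raise ValueError(f"marker must be in 1..{self.n_m}, got {marker}")
        return self.deltas[self.lams == marker]

    def lam_counts(self) -> np.ndarray:
        """Number of draws attaining the maximum at each marker."""
        return np.bincount(self.lams, minlength=self.n_m + 1)[1:]


def _chunk_rngs(seed: int, chunk_index: int) -> tuple[np.random.Generator, np.random.Generator]:
    child = np.random.SeedSequence(seed, spawn_key=(chunk_index,))
    perm_ss, tie_ss = child.spawn(2)
    return np.random.default_rng(perm_ss), np.random.default_rng(tie_ss)


def sample_max_lod(
    pop,
    n_p: int,
    seed: int = 0,
    tie_rule: str = "random",
    chunk_offset: int = 0,
) -> MaxLodSample:
    """Draw ``n_p`` observations of M under phenotype permutation.

    Each draw shuffles the phenotype vector uniformly at random (sampling
    permutations with replacement across draws), scans all markers, and
    records the max-LOD pair.  Genotypes are never touched.

    ``chunk_offset`` starts the deterministic chunk sequence at a later
    chunk, supporting split runs that reproduce a single longer run
    exactly when splits fall on ``CHUNK_SIZE`` boundaries.
    """
    if n_p < 1:
        raise ValueError("n_p must be >= 1")
    if tie_rule not in TIE_RULES:
        raise ValueError(f"tie_rule must be one of {TIE_RULES}")
    X = pop.genotypes.astype(float)
    y = pop.phenotypes
    deltas = np.empty(n_p)
    lams = np.empty(n_p, dtype=np.int64)
    n_chunks = math.ceil(n_p / CHUNK_SIZE)
    for k in range(n_chunks):
        lo = k * CHUNK_SIZE
        m = min(CHUNK_SIZE, n_p - lo)
        rng_perm, rng_tie = _chunk_rngs(seed, chunk_offset + k)
        yperm = rng_perm.permuted(np.tile(y, (m, 1)), axis=1)
        lod = lod_matrix(X, yperm.T)  # n_m x m
        dmax = lod.max(axis=0)
        arg = lod.argmax(axis=0)
        if tie_rule == "random":
            tie_cols = np.flatnonzero((lod == dmax[None, :]).sum(axis=0) > 1)
            for j in tie_cols:
                arg[j] = rng_tie.choice(np.flatnonzero(lod[:, j] == dmax[j]))
        deltas[lo : lo + m] = dmax
        lams[lo : lo + m] = arg + 1
    return MaxLodSample(deltas, lams, pop.n_markers, seed, tie_rule)


def required_permutations(
    n_m: int,
    min_count: int = 1000,
    p_lambda: "np.ndarray | None" = None,
) -> int:
    """Sampling depth needed to estimate every conditional distribution.

    Accurate location-conditioned quantiles need roughly ``min_count``
    draws with the maximum at every marker, i.e. ``n_p * P{lambda=i} >=
    min_count`` for all ``i``.  Given a pilot estimate of the location
    distribution the exact requirement ``ceil(min_count / min_i p_i)`` is
    returned; without one, the rule of thumb ``5000 * n_m`` covers
    moderate location bias.
    """
    if n_m < 1:
        raise ValueError("n_m must be >= 1")
    if p_lambda is None:
        return 5000 * n_m
    p = np.asarray(p_lambda, dtype=float)
    if np.any(p <= 0):
        bad = np.flatnonzero(p <= 0) + 1
        raise ValueError(
            f"markers {bad.tolist()} have zero estimated probability of attaining the "
            "maximum; no finite number of permutations can accumulate counts there"
        )
    return int(math.ceil(min_count / p.min()))
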