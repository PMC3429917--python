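"""Simulation of two-genotype experimental crosses.

Backcross (BC) and doubled-haploid (DH) populations both segregate two
genotype classes at every marker, coded 0/1 here.  Genotypes along a
chromosome follow a two-state Markov chain per individual: the first
marker is 0 or 1 with probability one half, and each subsequent marker
flips state with probability equal to the recombination fraction of the
interval.  Chromosomes are mutually independent, which is equivalent to
a recombination fraction of 0.5 across chromosome boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "CROSS_TYPES",
    "GeneticMap",
    "CrossPopulation",
    "haldane_r_from_cm",
    "haldane_cm_from_r",
    "simulate_genotypes",
    "simulate_null_phenotypes",
    "simulate_qtl_phenotypes",
    "simulate_population",
    "dense_sparse_demo_map",
]

CROSS_TYPES = ("backcross", "doubled_haploid")


def haldane_r_from_cm(distance: float) -> float:
    """Convert a genetic distance in centiMorgans to a recombination fraction.

    Uses the Haldane map function ``r = (1 - exp(-2 d / 100)) / 2``, which
    assumes crossovers arrive as a Poisson process with no interference.
    The result lies in ``[0, 0.5)``.
    """
    if distance < 0:
        raise ValueError(f"genetic distance must be >= 0, got {distance}")
    return 0.5 * (1.0 - np.exp(-2.0 * distance / 100.0))


def haldane_cm_from_r(r: float) -> float:
    """Inverse Haldane map: recombination fraction to centiMorgans."""
    if not 0 <= r < 0.5:
        raise ValueError(f"recombination fraction must be in [0, 0.5), got {r}")
    return -50.0 * np.log(1.0 - 2.0 * r)


@dataclass(frozen=True)
class GeneticMap:
    """Marker map for a genome scan.

    Parameters
    ----------
    markers
        Marker identifiers, one per marker, in map order.
    chromosomes
        Chromosome identifier per marker.  Markers of a chromosome must be
        contiguous.
    r_adjacent
        Recombination fraction between each marker and the previous one.
        Entry 0 and entries at chromosome starts are 0.5 (unlinked).
    positions_cm
        Optional cM positions (strictly increasing within a chromosome).
        When a map is built from recombination fractions, positions are
        reconstructed with the inverse Haldane function for reporting.
    """

    markers: tuple[str, ...]
    chromosomes: tuple[str, ...]
    r_adjacent: np.ndarray
    positions_cm: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.markers)
        if n < 2:
            raise ValueError("a genetic map needs at least 2 markers")
        if len(self.chromosomes) != n or len(self.r_adjacent) != n:
            raise ValueError("markers, chromosomes and r_adjacent lengths differ")
        if len(set(self.markers)) != n:
            raise ValueError("duplicate marker names in map")
        seen: dict[str, int] = {}
        for i, c in enumerate(self.chromosomes):
            if c in seen and self.chromosomes[i - 1] != c:
                raise ValueError(f"markers of chromosome {c!r} are not contiguous")
            seen[c] = i
        r = np.asarray(self.r_adjacent, dtype=float)
        starts = self.chromosome_starts()
        if not np.all(r[starts] == 0.5):
            raise ValueError("r_adjacent must be 0.5 at chromosome starts")
        within = np.ones(n, dtype=bool)
        within[starts] = False
        if np.any((r[within] <= 0) | (r[within] > 0.5)):
            raise ValueError("within-chromosome recombination fractions must satisfy 0 < r <= 0.5")
        object.__setattr__(self, "r_adjacent", r)
        if self.positions_cm is not None:
            pos = np.asarray(self.positions_cm, dtype=float)
            if len(pos) != n:
                raise ValueError("positions_cm length differs from marker count")
            for c in dict.fromkeys(self.chromosomes):
                p = pos[self.chromosome_mask(c)]
                if np.any(np.diff(p) <= 0):
                    raise ValueError(f"positions on chromosome {c!r} not strictly increasing")
            object.__setattr__(self, "positions_cm", pos)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def chromosome_starts(self) -> np.ndarray:
        """Indices where a new chromosome begins (always includes 0)."""
        ch = self.chromosomes
        return np.array([0] + [i for i in range(1, len(ch)) if ch[i] != ch[i - 1]], dtype=int)

    def chromosome_mask(self, chromosome: str) -> np.ndarray:
        return np.array([c == chromosome for c in self.chromosomes])

    def positions_or_haldane(self) -> np.ndarray:
        """cM positions; reconstructed via inverse Haldane when absent.

        Reconstructed coordinates restart at 0 on each chromosome.
        """
        if self.positions_cm is not None:
            return self.positions_cm
        pos = np.empty(self.n_markers)
        cur = 0.0
        for i in range(self.n_markers):
            if self.r_adjacent[i] == 0.5 and (i == 0 or self.chromosomes[i] != self.chromosomes[i - 1]):
                cur = 0.0
            else:
                cur += haldane_cm_from_r(min(self.r_adjacent[i], 0.5 - 1e-12))
            pos[i] = cur
        return pos

    @classmethod
    def from_positions(
        cls,
        chromosomes: "list[str] | tuple[str, ...]",
        positions_cm: "list[float] | np.ndarray",
        markers: "list[str] | None" = None,
    ) -> "GeneticMap":
        """Build a map from cM positions; interval r via Haldane."""
        chromosomes = tuple(str(c) for c in chromosomes)
        pos = np.asarray(positions_cm, dtype=float)
        if markers is None:
            markers = [f"m{i + 1:03d}" for i in range(len(pos))]
        r = np.full(len(pos), 0.5)
        for i in range(1, len(pos)):
            if chromosomes[i] == chromosomes[i - 1]:
                if pos[i] <= pos[i - 1]:
                    raise ValueError(
                        f"positions on chromosome {chromosomes[i]!r} must be strictly "
                        f"increasing ({pos[i - 1]} then {pos[i]})"
                    )
                r[i] = haldane_r_from_cm(pos[i] - pos[i - 1])
        return cls(tuple(markers), chromosomes, r, pos)

    @classmethod
    def from_recomb(
        cls,
        chromosomes: "list[str] | tuple[str, ...]",
        r_prev: "list[float] | np.ndarray",
        markers: "list[str] | None" = None,
    ) -> "GeneticMap":
        """Build a map from per-interval recombination fractions.

        ``r_prev`` entries at chromosome starts are ignored (forced to 0.5).
        """
        chromosomes = tuple(str(c) for c in chromosomes)
        r = np.asarray(r_prev, dtype=float).copy()
        r[0] = 0.5
        for i in range(1, len(r)):
            if chromosomes[i] != chromosomes[i - 1]:
                r[i] = 0.5
        if markers is None:
            markers = [f"m{i + 1:03d}" for i in range(len(r))]
        return cls(tuple(markers), chromosomes, r, None)

    @classmethod
    def equally_spaced(cls, n_markers: int, r: float, chromosome: str = "1") -> "GeneticMap":
        """Single chromosome with a common recombination fraction between neighbours."""
        rv = np.full(n_markers, r)
        return cls.from_recomb([chromosome] * n_markers, rv)


@dataclass(frozen=True)
class CrossPopulation:
    """A complete two-genotype cross: genotypes, phenotypes and map.

    Genotype entries are 0/1 (the two classes of a BC or DH cross); no
    missing genotype or phenotype values are permitted.
    """

    genotypes: np.ndarray
    phenotypes: np.ndarray
    map: GeneticMap
    cross_type: str = "doubled_haploid"

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes)
        y = np.asarray(self.phenotypes, dtype=float)
        if self.cross_type not in CROSS_TYPES:
            raise ValueError(f"cross_type must be one of {CROSS_TYPES}, got {self.cross_type!r}")
        if g.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix (individuals x markers)")
        if not np.isin(g, (0, 1)).all():
            raise ValueError("genotypes must contain only 0/1 (missing data not supported)")
        if g.shape[1] != self.map.n_markers:
            raise ValueError(
                f"genotype matrix has {g.shape[1]} columns but map has {self.map.n_markers} markers"
            )
        if g.shape[0] < 3:
            raise ValueError("need at least 3 individuals for marker regression")
        if y.shape != (g.shape[0],):
            raise ValueError("phenotype vector length must equal the number of individuals")
        if not np.isfinite(y).all():
            raise ValueError("phenotypes must be finite (missing data not supported)")
        object.__setattr__(self, "genotypes", g.astype(np.uint8))
        object.__setattr__(self, "phenotypes", y)

    @property
    def n_obs(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]


def simulate_genotypes(
    gmap: GeneticMap,
    n_obs: int,
    cross_type: str = "doubled_haploid",
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Simulate a 0/1 genotype matrix for ``n_obs`` individuals.

    Each individual's chromosome is an independent two-state Markov chain:
    state flips between adjacent markers with probability equal to the
    interval recombination fraction.  The 0.5 fractions at chromosome
    starts make the first marker of every chromosome a fair coin,
    independent of the previous chromosome.
    """
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    if cross_type not in CROSS_TYPES:
        raise ValueError(f"cross_type must be one of {CROSS_TYPES}")
    rng = np.random.default_rng(seed)
    flips = rng.random((n_obs, gmap.n_markers)) < gmap.r_adjacent[None, :]
    # cumulative XOR of flips starting from state 0; the 0.5-probability
    # flip at each chromosome start randomises the initial state
    geno = np.bitwise_xor.accumulate(flips, axis=1)
    return geno.astype(np.uint8)


def simulate_balanced_unlinked(
    n_obs: int,
    n_m: int,
    seed: int | np.random.SeedSequence = 0,
    cross_type: str = "doubled_haploid",
) -> CrossPopulation:
    """Exchangeable null cross: unlinked, exactly balanced markers.

    Every genotype column is an independent random arrangement of exactly
    ``n_obs/2`` zeros and ones, and each marker sits on its own
    chromosome.  Under phenotype permutation all markers are then
    exchangeable, the max-LOD location distribution is uniform, and the
    location-dependent threshold collapses onto the constant one — the
    reference condition for equivalence checks.  Requires even ``n_obs``.
    """
    if n_obs < 4 or n_obs % 2:
        raise ValueError("balanced columns need an even n_obs >= 4")
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    geno_ss, pheno_ss = ss.spawn(2)
    rng = np.random.default_rng(geno_ss)
    base = np.repeat(np.array([0, 1], dtype=np.uint8), n_obs // 2)
    geno = np.column_stack([rng.permutation(base) for _ in range(n_m)])
    gmap = GeneticMap(
        tuple(f"m{i + 1:03d}" for i in range(n_m)),
        tuple(str(i + 1) for i in range(n_m)),
        np.full(n_m, 0.5),
    )
    pheno = simulate_null_phenotypes(n_obs, pheno_ss)
    return CrossPopulation(geno, pheno, gmap, cross_type)


def simulate_null_phenotypes(n_obs: int, seed: int | np.random.SeedSequence = 0) -> np.ndarray:
    """I.i.d. standard-normal phenotypes: the no-QTL null."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return np.random.default_rng(seed).standard_normal(n_obs)


def simulate_qtl_phenotypes(
    genotypes: np.ndarray,
    qtl_marker: int,
    effect: float,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Phenotypes with one additive QTL at a marker (1-based index).

    ``phenotype = effect * genotype + N(0, 1)`` at the chosen marker.
    """
    g = np.asarray(genotypes)
    if not 1 <= qtl_marker <= g.shape[1]:
        raise ValueError(f"qtl_marker must be in 1..{g.shape[1]}, got {qtl_marker}")
    noise = np.random.default_rng(seed).standard_normal(g.shape[0])
    return effect * g[:, qtl_marker - 1].astype(float) + noise


def simulate_population(
    gmap: GeneticMap,
    n_obs: int,
    cross_type: str = "doubled_haploid",
    seed: int | np.random.SeedSequence = 0,
    qtl_marker: int | None = None,
    effect: float = 0.0,
) -> CrossPopulation:
    """Simulate a full cross: genotypes plus null or QTL-bearing phenotypes."""
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    geno_seed, pheno_seed = ss.spawn(2)
    geno = simulate_genotypes(gmap, n_obs, cross_type, geno_seed)
    if qtl_marker is None:
        pheno = simulate_null_phenotypes(n_obs, pheno_seed)
    else:
        pheno = simulate_qtl_phenotypes(geno, qtl_marker, effect, pheno_seed)
    return CrossPopulation(geno, pheno, gmap, cross_type)


def dense_sparse_demo_map() -> GeneticMap:
    """The packaged 34-marker single-chromosome demonstration map.

    Two dense clusters (1-cM spacing) flank a sparse middle region
    (18-cM spacing), a layout that induces clear location bias in the
    max-LOD location distribution.
    """
    from . import crossio

    with resources.files("ldtscan.data").joinpath("dense_sparse_34.csv").open() as fh:
        return crossio.read_map_csv(fh)
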