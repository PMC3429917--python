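"""Readers and writers for cross data, permutation samples and results.

Cross files follow the R/qtl "csv" convention: the phenotype column
comes first, then one column per marker; row 1 holds names, row 2 the
chromosome of each marker (blank for phenotypes), row 3 the cM position,
and each following row one individual.  Genotypes are letter codes
(``A`` for one parental class, ``H`` or ``B`` for the other).  Missing
cells are rejected outright — the threshold methodology assumes complete
genotype and phenotype data.

Permutation samples persist as a two-column ``delta,lambda`` CSV plus a
JSON sidecar recording n_m, n_p, seed and tie rule, so an expensive run
can be reused across threshold levels.
"""

from __future__ import annotations

import csv
import json
import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sampler import MaxLodSample
from .simcross import CrossPopulation, GeneticMap

__all__ = [
    "DEFAULT_GENOTYPE_CODES",
    "read_map_csv",
    "write_map_csv",
    "read_cross_csv",
    "write_cross_csv",
    "read_sample_csv",
    "write_sample_csv",
    "write_scan_csv",
    "read_scan_csv",
    "write_threshold_csv",
    "write_adjusted_csv",
    "RunConfig",
    "load_run_config",
]

DEFAULT_GENOTYPE_CODES = {"A": 0, "H": 1, "B": 1}
_MISSING_TOKENS = {"", "-", "NA", "N/A", "na", "*"}


def _open(path_or_file, mode="r"):
    if hasattr(path_or_file, "read") or hasattr(path_or_file, "write"):
        return path_or_file, False
    return open(path_or_file, mode, newline=""), True


def read_map_csv(path_or_file) -> GeneticMap:
    """Read a marker map CSV.

    Header is either ``marker,chromosome,position_cM`` (cM positions,
    converted to recombination fractions with the Haldane function) or
    ``marker,chromosome,r_prev`` (explicit recombination fraction to the
    previous marker; blank/NA on the first marker of a chromosome).
    """
    fh, close = _open(path_or_file)
    try:
        rows = list(csv.reader(fh))
    finally:
        if close:
            fh.close()
    if not rows:
        raise ValueError("empty map file")
    header = [h.strip() for h in rows[0]]
    if header[:2] != ["marker", "chromosome"] or len(header) < 3:
        raise ValueError(f"unrecognised map header {header!r}")
    markers, chroms, vals = [], [], []
    for row in rows[1:]:
        if not row:
            continue
        markers.append(row[0].strip())
        chroms.append(row[1].strip())
        vals.append(row[2].strip())
    if header[2] == "position_cM":
        return GeneticMap.from_positions(chroms, [float(v) for v in vals], markers)
    if header[2] == "r_prev":
        r = [0.5 if v in _MISSING_TOKENS else float(v) for v in vals]
        return GeneticMap.from_recomb(chroms, r, markers)
    raise ValueError(f"third map column must be 'position_cM' or 'r_prev', got {header[2]!r}")


def write_map_csv(gmap: GeneticMap, path) -> None:
    fh, close = _open(path, "w")
    try:
        w = csv.writer(fh)
        if gmap.positions_cm is not None:
            w.writerow(["marker", "chromosome", "position_cM"])
            for m, c, p in zip(gmap.markers, gmap.chromosomes, gmap.positions_cm):
                w.writerow([m, c, f"{p:g}"])
        else:
            w.writerow(["marker", "chromosome", "r_prev"])
            starts = set(gmap.chromosome_starts().tolist())
            for i, (m, c) in enumerate(zip(gmap.markers, gmap.chromosomes)):
                w.writerow([m, c, "" if i in starts else f"{gmap.r_adjacent[i]:g}"])
    finally:
        if close:
            fh.close()


def write_cross_csv(
    pop: CrossPopulation,
    path,
    phenotype_name: str = "phenotype",
    codes: tuple[str, str] = ("A", "H"),
) -> None:
    """Write a cross in R/qtl csv format (phenotype first, 3 header rows)."""
    pos = pop.map.positions_or_haldane()
    fh, close = _open(path, "w")
    try:
        w = csv.writer(fh)
        w.writerow([phenotype_name, *pop.map.markers])
        w.writerow(["", *pop.map.chromosomes])
        w.writerow(["", *[f"{p:g}" for p in pos]])
        for i in range(pop.n_obs):
            w.writerow(
                [f"{pop.phenotypes[i]:.17g}", *[codes[g] for g in pop.genotypes[i]]]
            )
    finally:
        if close:
            fh.close()


def read_cross_csv(
    path,
    cross_type: str = "doubled_haploid",
    codes: "dict[str, int] | None" = None,
) -> CrossPopulation:
    """Read an R/qtl-style csv cross into a :class:`CrossPopulation`.

    Genotype letter codes map through ``codes`` (default A->0, H/B->1).
    Any missing genotype or phenotype cell is a hard error: the
    permutation thresholds are defined for complete data only.
    """
    codes = DEFAULT_GENOTYPE_CODES if codes is None else codes
    fh, close = _open(path)
    try:
        rows = list(csv.reader(fh))
    finally:
        if close:
            fh.close()
    if len(rows) < 6:
        raise ValueError("cross file needs 3 header rows and at least 3 individuals")
    header, chrom_row, pos_row = rows[0], rows[1], rows[2]
    # phenotype columns are those with a blank chromosome entry
    n_cols = len(header)
    pheno_cols = [j for j in range(n_cols) if j >= len(chrom_row) or not chrom_row[j].strip()]
    marker_cols = [j for j in range(n_cols) if j not in pheno_cols]
    if not pheno_cols:
        raise ValueError("no phenotype column found (column with blank chromosome row)")
    if len(marker_cols) < 2:
        raise ValueError("cross file must contain at least 2 marker columns")
    pheno_col = pheno_cols[0]  # first phenotype column is the analysed trait
    markers = [header[j].strip() for j in marker_cols]
    chroms = [chrom_row[j].strip() for j in marker_cols]
    positions = [float(pos_row[j]) for j in marker_cols]
    pheno, geno_rows = [], []
    raw_codes: list[set] = [set() for _ in markers]
    for r, row in enumerate(rows[3:], start=4):
        if not any(cell.strip() for cell in row):
            continue
        cell = row[pheno_col].strip() if pheno_col < len(row) else ""
        if cell in _MISSING_TOKENS:
            raise ValueError(
                f"missing phenotype at row {r}: complete data are required "
                "(the permutation null assumes no missing values)"
            )
        pheno.append(float(cell))
        grow = []
        for k, (j, name) in enumerate(zip(marker_cols, markers)):
            g = row[j].strip() if j < len(row) else ""
            if g in _MISSING_TOKENS:
                raise ValueError(
                    f"missing genotype at row {r}, marker {name!r}: complete genotype "
                    "data are required (missing values are not supported)"
                )
            if g not in codes:
                raise ValueError(
                    f"unknown genotype code {g!r} at row {r}, marker {name!r}; "
                    f"expected one of {sorted(codes)}"
                )
            raw_codes[k].add(g)
            grow.append(codes[g])
        geno_rows.append(grow)
    geno = np.asarray(geno_rows, dtype=np.uint8)
    for name, seen in zip(markers, raw_codes):
        if len(seen) > 2:
            raise ValueError(
                f"marker {name!r} shows {len(seen)} genotype classes ({sorted(seen)}); "
                "only two-genotype crosses (backcross / doubled haploid) are supported"
            )
    gmap = GeneticMap.from_positions(chroms, positions, markers)
    return CrossPopulation(geno, np.asarray(pheno), gmap, cross_type)


def write_sample_csv(sample: MaxLodSample, path) -> None:
    """Persist a permutation sample: ``delta,lambda`` CSV + JSON sidecar."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["delta", "lambda"])
        for d, l in zip(sample.deltas, sample.lams):
            w.writerow([f"{d:.17g}", int(l)])
    meta = {"n_m": sample.n_m, "n_p": sample.n_p, "seed": sample.seed, "tie_rule": sample.tie_rule}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_sample_csv(path, meta_path=None) -> MaxLodSample:
    path = Path(path)
    if meta_path is None:
        meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(Path(meta_path).read_text())
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.shape[0] != meta["n_p"]:
        raise ValueError(
            f"sample CSV has {data.shape[0]} rows but sidecar records n_p={meta['n_p']}"
        )
    return MaxLodSample(
        data[:, 0], data[:, 1].astype(np.int64), int(meta["n_m"]), meta.get("seed"),
        meta.get("tie_rule", "random"),
    )


def write_scan_csv(scan, gmap: GeneticMap, path) -> None:
    pos = gmap.positions_or_haldane()
    fh, close = _open(path, "w")
    try:
        w = csv.writer(fh)
        w.writerow(["marker", "chromosome", "position", "lod"])
        for m, c, p, l in zip(gmap.markers, gmap.chromosomes, pos, scan.lod):
            w.writerow([m, c, f"{p:g}", f"{l:.17g}"])
    finally:
        if close:
            fh.close()


def read_scan_csv(path) -> "tuple[list[str], np.ndarray]":
    """Return (marker names, LOD vector) from a scan CSV."""
    fh, close = _open(path)
    try:
        rows = list(csv.reader(fh))
    finally:
        if close:
            fh.close()
    if not rows or rows[0][:1] != ["marker"]:
        raise ValueError("not a scan CSV (expected 'marker,...,lod' header)")
    lod_col = rows[0].index("lod")
    markers = [r[0] for r in rows[1:] if r]
    lod = np.array([float(r[lod_col]) for r in rows[1:] if r])
    return markers, lod


def write_threshold_csv(gmap: GeneticMap, results: dict, ld, path) -> None:
    """Write per-marker thresholds plus the location distribution.

    ``results`` maps method tags ('CD', 'conditional', 'LDT') to
    :class:`~ldtscan.thresholds.ThresholdResult`; absent methods leave
    blank columns.
    """
    pos = gmap.positions_or_haldane()
    cd = results.get("CD")
    tl = results.get("conditional")
    ldt = results.get("LDT")
    fh, close = _open(path, "w")
    try:
        w = csv.writer(fh)
        w.writerow(
            ["marker", "chromosome", "position", "T_cd", "T_lambda", "T_ldt", "alpha", "p_lambda"]
        )
        for i in range(gmap.n_markers):
            w.writerow(
                [
                    gmap.markers[i],
                    gmap.chromosomes[i],
                    f"{pos[i]:g}",
                    "" if cd is None else f"{cd.T[i]:.6g}",
                    "" if tl is None else f"{tl.T[i]:.6g}",
                    "" if ldt is None else f"{ldt.T[i]:.6g}",
                    f"{ld.alpha[i]:.6g}",
                    f"{ld.p_lambda[i]:.6g}",
                ]
            )
    finally:
        if close:
            fh.close()


def write_adjusted_csv(gmap: GeneticMap, lod: np.ndarray, table: list, path) -> None:
    """Write per-marker adjusted P-values.

    ``table`` rows are (p_cd, p_ldt_capped, p_ldt_max_attainable) per marker.
    """
    fh, close = _open(path, "w")
    try:
        w = csv.writer(fh)
        w.writerow(["marker", "lod", "p_cd", "p_ldt", "p_ldt_max_attainable"])
        for i in range(gmap.n_markers):
            p_cd, p_ldt, p_max = table[i]
            w.writerow(
                [gmap.markers[i], f"{lod[i]:.6g}", f"{p_cd:.6g}", f"{p_ldt:.6g}", f"{p_max:.6g}"]
            )
    finally:
        if close:
            fh.close()


@dataclass
class RunConfig:
    """Configuration of a full threshold run (YAML or JSON)."""

    cross: str
    gammas: list = field(default_factory=lambda: [0.05])
    n_p: "int | str" = "auto"
    seed: int = 0
    tie_rule: str = "random"
    out_dir: str = "."
    smoothing: bool = False

    def __post_init__(self) -> None:
        for g in self.gammas:
            if not 0 < g < 1:
                raise ValueError(f"gamma {g} outside (0, 1)")
        if self.n_p != "auto" and int(self.n_p) < 1:
            raise ValueError("n_p must be >= 1 or 'auto'")
        if self.tie_rule not in ("first", "random"):
            raise ValueError(f"unknown tie_rule {self.tie_rule!r}")


def load_run_config(path) -> RunConfig:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return RunConfig(**data)
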