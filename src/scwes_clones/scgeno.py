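"""Single-cell QC and depth-stratified consensus SNV genotyping.

Cells are kept only when they cover at least 75% of the target and average at
least 10x depth. Per cell x site, the consensus rule set assigns a ternary
genotype from (depth, alt_depth):

* depth < 10            -> NA (missing)
* 10 <= depth <= 20     -> mutant iff alt_depth >= 10
* 20 <  depth <= 100    -> mutant iff alt_depth / depth >= 0.30
* depth > 100           -> mutant iff alt_depth / depth >= 0.20

Site-level filters then remove SNVs mutant in fewer than 3 cells, SNVs in
clustered regions (another retained SNV within 10 bp on the same chromosome;
all members of such a chain are dropped), and germline sites. The per-SNV
mutation frequency is the percentage of QC-passing cells that carry it.

The matrix is a cells x SNVs pandas DataFrame with values {0.0, 1.0, NaN};
column keys are ``chrom:pos:ref:alt`` strings sorted by genomic position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as sio

__all__ = [
    "FilterConfig",
    "GenotypeMatrix",
    "qc_cells",
    "call_genotype",
    "call_genotypes",
    "build_genotype_matrix",
    "filter_min_cells",
    "filter_clustered",
    "filter_germline",
    "mutation_frequency",
    "mutation_frequencies",
]


@dataclass
class FilterConfig:
    min_cell_covered_fraction: float = 0.75
    min_cell_mean_depth: float = 10.0
    na_depth_below: int = 10
    low_stratum_max_depth: int = 20
    low_stratum_min_alt_reads: int = 10
    mid_stratum_max_depth: int = 100
    mid_stratum_min_alt_fraction: float = 0.30
    high_stratum_min_alt_fraction: float = 0.20
    min_cells_per_snv: int = 3
    cluster_window_bp: int = 10

    def validate(self) -> None:
        for name in ("na_depth_below", "low_stratum_max_depth",
                     "low_stratum_min_alt_reads", "mid_stratum_max_depth",
                     "min_cells_per_snv", "cluster_window_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"filter.{name} must be positive")
        for name in ("min_cell_covered_fraction", "mid_stratum_min_alt_fraction",
                     "high_stratum_min_alt_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"filter.{name} must be in (0, 1], got {v}")
        if self.min_cell_mean_depth <= 0:
            raise ValueError("filter.min_cell_mean_depth must be positive")


class GenotypeMatrix:
    """Ternary cells x SNVs matrix plus a provenance map of removed SNVs."""

    def __init__(self, df: pd.DataFrame, provenance: dict[str, str] | None = None):
        values = df.to_numpy(dtype=float)
        ok = np.isnan(values) | (values == 0.0) | (values == 1.0)
        if not ok.all():
            raise ValueError("genotype values must be 0, 1 or NA")
        self.df = df.astype(float)
        self.provenance = dict(provenance or {})

    @property
    def cells(self) -> list[str]:
        return list(self.df.index)

    @property
    def snvs(self) -> list[str]:
        return list(self.df.columns)

    def drop_snvs(self, keys, reason: str) -> "GenotypeMatrix":
        keys = [k for k in keys if k in self.df.columns]
        prov = dict(self.provenance)
        prov.update({k: reason for k in keys})
        return GenotypeMatrix(self.df.drop(columns=keys), prov)

    def removals_table(self) -> pd.DataFrame:
        rows = sorted(self.provenance.items())
        return pd.DataFrame(rows, columns=["snv", "reason"])

    def __eq__(self, other) -> bool:
        return (isinstance(other, GenotypeMatrix)
                and self.df.equals(other.df)
                and self.provenance == other.provenance)


def cell_summaries(table: pd.DataFrame,
                   n_target_sites: int | None = None) -> pd.DataFrame:
    """Per-cell covered fraction and mean depth over the target.

    When the target size is not given it defaults to the number of distinct
    sites in the table (i.e. the table is assumed to enumerate the target).
    Sites absent from a cell's rows count as depth 0.
    """
    n_sites = (int(n_target_sites) if n_target_sites is not None
               else table[["chrom", "pos"]].drop_duplicates().shape[0])
    if n_sites <= 0:
        raise ValueError("target size must be positive")
    g = table.groupby("cell_id")["depth"]
    out = pd.DataFrame({
        "covered_fraction": g.apply(lambda d: (d >= 1).sum() / n_sites),
        "mean_depth": g.sum() / n_sites,
    })
    out.index.name = "cell_id"
    return out


def qc_cells(table: pd.DataFrame, cfg: FilterConfig,
             summaries: pd.DataFrame | None = None,
             n_target_sites: int | None = None
             ) -> tuple[list[str], pd.DataFrame]:
    """Split cells into kept and dropped (with reasons).

    Kept iff covered_fraction >= 0.75 (strict "less than 75%" exclusion) and
    mean depth >= 10.
    """
    cfg.validate()
    if summaries is None:
        if not {"depth", "cell_id"} <= set(table.columns):
            raise ValueError("need either summaries or a read table with depths")
        summaries = cell_summaries(table, n_target_sites)
    kept, dropped = [], []
    for cell, row in summaries.iterrows():
        reasons = []
        if row["covered_fraction"] < cfg.min_cell_covered_fraction:
            reasons.append("coverage")
        if row["mean_depth"] < cfg.min_cell_mean_depth:
            reasons.append("depth")
        if reasons:
            dropped.append((cell, "+".join(reasons)))
        else:
            kept.append(cell)
    return kept, pd.DataFrame(dropped, columns=["cell_id", "reason"])


def call_genotype(depth: int, alt_depth: int,
                  cfg: FilterConfig | None = None) -> float:
    """Ternary consensus call for one site: 0.0, 1.0 or NaN."""
    cfg = cfg or FilterConfig()
    if alt_depth > depth:
        raise ValueError(f"alt_depth {alt_depth} > depth {depth}")
    if alt_depth < 0:
        raise ValueError("alt_depth must be non-negative")
    if depth < cfg.na_depth_below:
        return float("nan")
    if depth <= cfg.low_stratum_max_depth:
        return float(alt_depth >= cfg.low_stratum_min_alt_reads)
    frac = alt_depth / depth
    if depth <= cfg.mid_stratum_max_depth:
        return float(frac >= cfg.mid_stratum_min_alt_fraction)
    return float(frac >= cfg.high_stratum_min_alt_fraction)


def call_genotypes(depth: np.ndarray, alt_depth: np.ndarray,
                   cfg: FilterConfig | None = None) -> np.ndarray:
    """Vectorised ``call_genotype`` over arrays of equal shape."""
    cfg = cfg or FilterConfig()
    depth = np.asarray(depth, dtype=float)
    alt = np.asarray(alt_depth, dtype=float)
    if (alt > depth).any():
        raise ValueError("alt_depth exceeds depth")
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    out = np.where(
        depth <= cfg.low_stratum_max_depth,
        (alt >= cfg.low_stratum_min_alt_reads).astype(float),
        np.where(depth <= cfg.mid_stratum_max_depth,
                 (frac >= cfg.mid_stratum_min_alt_fraction).astype(float),
                 (frac >= cfg.high_stratum_min_alt_fraction).astype(float)))
    out[depth < cfg.na_depth_below] = np.nan
    return out


def build_genotype_matrix(table: pd.DataFrame, kept_cells: list[str],
                          cfg: FilterConfig | None = None) -> GenotypeMatrix:
    """Apply the consensus rule per cell x site over QC-passing cells.

    Sites with no row for a cell are missing (NA). Columns are sorted by
    (chrom, pos).
    """
    cfg = cfg or FilterConfig()
    if len(kept_cells) == 0:
        raise ValueError("kept_cells is empty")
    sub = table[table["cell_id"].isin(kept_cells)].copy()
    if sub.duplicated(subset=["cell_id", "chrom", "pos", "alt"]).any():
        raise ValueError("duplicate (cell, site) entries in read table")
    if (sub["alt_depth"] > sub["depth"]).any():
        raise ValueError("alt_depth exceeds depth")
    sub["snv_key"] = [sio.make_key(c, p, r, a) for c, p, r, a in
                      zip(sub["chrom"], sub["pos"], sub["ref"], sub["alt"])]
    sub["geno"] = call_genotypes(sub["depth"].to_numpy(),
                                 sub["alt_depth"].to_numpy(), cfg)
    mat = sub.pivot(index="cell_id", columns="snv_key", values="geno")
    mat = mat.reindex(index=list(kept_cells))
    order = sio.key_frame(mat.columns).sort_values(["chrom", "pos"]).index
    return GenotypeMatrix(mat[order])


def filter_min_cells(m: GenotypeMatrix,
                     cfg: FilterConfig | None = None) -> GenotypeMatrix:
    """Drop SNVs mutant in fewer than ``min_cells_per_snv`` cells."""
    cfg = cfg or FilterConfig()
    counts = (m.df == 1.0).sum(axis=0)
    bad = counts.index[counts < cfg.min_cells_per_snv]
    return m.drop_snvs(bad, "min_cells")


def filter_clustered(m: GenotypeMatrix,
                     cfg: FilterConfig | None = None) -> GenotypeMatrix:
    """Drop every retained SNV within the cluster window of another.

    Cohort-level: the window test runs on the retained site list, not per
    cell, and removes all members of a proximal chain.
    """
    cfg = cfg or FilterConfig()
    if not m.snvs:
        return m
    sites = sio.key_frame(m.snvs).sort_values(["chrom", "pos"])
    bad = set()
    for _, grp in sites.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        keys = grp.index.to_numpy()
        close = np.diff(pos) <= cfg.cluster_window_bp
        for i in np.flatnonzero(close):
            bad.add(keys[i])
            bad.add(keys[i + 1])
    return m.drop_snvs(sorted(bad), "clustered")


def filter_germline(m: GenotypeMatrix, germline_sites: set[str]) -> GenotypeMatrix:
    """Drop SNVs whose (chrom, pos, ref, alt) key is in the germline set."""
    bad = [k for k in m.snvs if k in germline_sites]
    return m.drop_snvs(bad, "germline")


def germline_from_normals(m: GenotypeMatrix, normal_cells: list[str],
                          min_fraction: float = 0.5) -> set[str]:
    """Sites mutant in at least half of the normal-tissue cells.

    Optional augmentation of a germline call set when a matched normal VCF
    is unavailable.
    """
    normals = [c for c in normal_cells if c in m.df.index]
    if not normals:
        return set()
    sub = m.df.loc[normals]
    frac = (sub == 1.0).sum(axis=0) / len(normals)
    return set(frac.index[frac >= min_fraction])


def mutation_frequency(m: GenotypeMatrix, snv: str,
                       include_na_cells: bool = True) -> float:
    """Percentage of cells carrying the SNV.

    By default every QC-passing cell counts in the denominator (missing
    observations included); ``include_na_cells=False`` restricts to cells
    with a defined genotype at the site.
    """
    if snv not in m.df.columns:
        raise KeyError(f"unknown SNV {snv!r}")
    col = m.df[snv]
    denom = len(col) if include_na_cells else int(col.notna().sum())
    if denom == 0:
        return float("nan")
    return 100.0 * float((col == 1.0).sum()) / denom


def mutation_frequencies(m: GenotypeMatrix,
                         include_na_cells: bool = True) -> pd.Series:
    n = (m.df == 1.0).sum(axis=0)
    denom = float(len(m.df)) if include_na_cells else m.df.notna().sum(axis=0)
    out = 100.0 * n / denom
    out.name = "sc_frequency"
    return out
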