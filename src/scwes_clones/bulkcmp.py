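"""Bulk somatic-variant post-filtering and bulk vs single-cell concordance.

Bulk calls from two independent somatic callers are intersected (a variant
must be reported by both), then depth-filtered (>= 10x) and restricted to the
target regions. Against the single-cell genotype matrix, every SNV in the
union is classified common / bulk-specific / single-cell-specific; sc-specific
SNVs with read support in the bulk pileup below caller sensitivity are
rescued as low-MAF. Concordance is the Pearson correlation between per-SNV
single-cell mutation frequency and bulk mutant allele frequency. A simple
two-component VAF-split moment estimator stands in for a full Bayesian purity
model: purity = min(1, 2 x median VAF of the clonal (upper) cluster).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from sklearn.cluster import KMeans

from . import io as sio
from .scgeno import GenotypeMatrix, mutation_frequencies

__all__ = [
    "filter_bulk_variants",
    "classify_snvs",
    "rescue_low_maf",
    "concordance_correlation",
    "estimate_purity",
]

SITE_KEY = ["chrom", "pos", "ref", "alt"]


def _with_keys(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["snv_key"] = [sio.make_key(c, p, r, a) for c, p, r, a in
                     zip(df["chrom"], df["pos"], df["ref"], df["alt"])]
    return df


def _target_trees(targets: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in targets.itertuples(index=False):
        trees.setdefault(str(row.chrom), IntervalTree()).addi(
            int(row.start), int(row.end))
    return trees


def in_target(df: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Membership of 1-based variant positions in half-open 0-based intervals."""
    trees = _target_trees(targets)
    return np.array([bool(trees[c][p - 1]) if c in trees else False
                     for c, p in zip(df["chrom"].astype(str), df["pos"])])


def filter_bulk_variants(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                         targets: pd.DataFrame | None = None,
                         min_depth: int = 10) -> pd.DataFrame:
    """Consensus of two callers, depth >= 10x, restricted to targets.

    Depth and alt counts of a shared variant are averaged over the two
    callers, which makes the operation symmetric in its arguments.
    """
    if "sample_id" in calls_a.columns and "sample_id" in calls_b.columns:
        sa = set(calls_a["sample_id"].unique())
        sb = set(calls_b["sample_id"].unique())
        if sa and sb and sa != sb:
            raise ValueError(f"caller tables from different samples: {sa} vs {sb}")
    a = _with_keys(calls_a)
    b = _with_keys(calls_b)
    merged = a.merge(b[["snv_key", "depth", "alt_depth"]], on="snv_key",
                     suffixes=("", "_b"))
    merged["depth"] = (merged["depth"] + merged["depth_b"]) / 2.0
    merged["alt_depth"] = (merged["alt_depth"] + merged["alt_depth_b"]) / 2.0
    merged = merged.drop(columns=["depth_b", "alt_depth_b"])
    merged["caller_set"] = "A+B"
    merged = merged[merged["depth"] >= min_depth]
    if targets is not None:
        merged = merged[in_target(merged, targets)]
    merged["vaf"] = merged["alt_depth"] / merged["depth"]
    return merged.sort_values(["chrom", "pos"], kind="mergesort"
                              ).reset_index(drop=True)


def classify_snvs(sc: GenotypeMatrix, bulk: pd.DataFrame) -> pd.DataFrame:
    """Partition the SNV union into common / bulk_specific / sc_specific.

    Carries the single-cell mutation frequency (percent of cells) and the
    bulk MAF where defined.
    """
    bulk = _with_keys(bulk) if "snv_key" not in bulk.columns else bulk
    sc_keys = set(sc.snvs)
    bulk_keys = set(bulk["snv_key"])
    freqs = mutation_frequencies(sc)
    bulk_vaf = bulk.set_index("snv_key")["vaf"]
    rows = []
    for key in sorted(sc_keys | bulk_keys):
        in_sc, in_bulk = key in sc_keys, key in bulk_keys
        category = ("common" if in_sc and in_bulk
                    else "bulk_specific" if in_bulk else "sc_specific")
        rows.append({
            "snv_key": key,
            "category": category,
            "low_maf": False,
            "unresolvable": False,
            "sc_frequency": float(freqs[key]) if in_sc else np.nan,
            "bulk_maf": float(bulk_vaf[key]) if in_bulk else np.nan,
        })
    return pd.DataFrame(rows)


def category_percentages(categories: pd.DataFrame) -> pd.Series:
    return 100.0 * categories["category"].value_counts() / len(categories)


def rescue_low_maf(categories: pd.DataFrame, bulk_pileup: pd.DataFrame,
                   min_support: int = 2,
                   low_maf_ceiling: float = 0.05) -> pd.DataFrame:
    """Flag sc-specific SNVs with sub-caller-sensitivity bulk read support.

    An sc-specific SNV is low-MAF iff the bulk pileup shows at least
    ``min_support`` mutant reads at a VAF below ``low_maf_ceiling`` (present,
    but too faint for a somatic caller). Sites absent from the pileup are
    marked unresolvable. Common and bulk-specific rows are never touched.
    """
    pileup = (_with_keys(bulk_pileup)
              if "snv_key" not in bulk_pileup.columns else bulk_pileup)
    pileup = pileup.set_index("snv_key")
    out = categories.copy()
    for i, row in out.iterrows():
        if row["category"] != "sc_specific":
            continue
        key = row["snv_key"]
        if key not in pileup.index:
            out.at[i, "unresolvable"] = True
            continue
        depth = float(pileup.at[key, "depth"])
        alt = float(pileup.at[key, "alt_depth"])
        vaf = alt / depth if depth > 0 else np.nan
        out.at[i, "bulk_maf"] = vaf
        out.at[i, "low_maf"] = bool(alt >= min_support
                                    and np.isfinite(vaf)
                                    and vaf < low_maf_ceiling)
    return out


def concordance_correlation(categories: pd.DataFrame) -> tuple[float, int]:
    """Pearson r between sc frequency and bulk MAF over common + low-MAF SNVs."""
    sel = categories[(categories["category"] == "common")
                     | categories["low_maf"]]
    sel = sel.dropna(subset=["sc_frequency", "bulk_maf"])
    if len(sel) < 3:
        raise ValueError(f"need >= 3 paired SNVs, have {len(sel)}")
    r, _ = stats.pearsonr(sel["sc_frequency"], sel["bulk_maf"])
    return float(r), len(sel)


def estimate_purity(bulk: pd.DataFrame, min_snvs: int = 5,
                    random_state: int = 0) -> float:
    """Moment estimate of tumour purity from somatic VAFs.

    VAFs are split into two 1-D k-means components; the component with the
    higher mean is taken as the clonal cluster and purity is
    min(1, 2 x median clonal VAF) under a diploid heterozygous model. With
    fewer than 10 variants the split is skipped and all VAFs are used.
    """
    if len(bulk) == 0:
        raise ValueError("empty bulk variant table")
    vaf = bulk["vaf"].dropna().to_numpy(dtype=float)
    if len(vaf) < min_snvs:
        raise ValueError(f"need >= {min_snvs} somatic SNVs, have {len(vaf)}")
    if len(vaf) < 10 or np.allclose(vaf, vaf[0]):
        clonal = vaf
    else:
        km = KMeans(n_clusters=2, n_init=10, random_state=random_state)
        labels = km.fit_predict(vaf.reshape(-1, 1))
        upper = int(np.argmax(km.cluster_centers_.ravel()))
        clonal = vaf[labels == upper]
    return float(min(1.0, 2.0 * np.median(clonal)))
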