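"""Clone-group-specific mutated genes: chi-squared / FDR / fold-change test.

A cell counts as mutated for a gene when it carries at least one
nonsynonymous SNV of that gene; cells with no observation over the gene's
SNVs leave its denominator. Per gene, metastatic vs primary mutation rates
are compared in a 2x2 contingency table with an uncorrected Pearson
chi-squared test (Fisher's exact test substituted, and flagged, when any
expected count drops below 5), Benjamini-Hochberg correction across genes,
and a pseudocounted log2 fold change. A gene is selected when FDR < 0.05 and
|log2FC| > 1; it is additionally high-risk when any contributing
nonsynonymous SNV has SIFT < 0.05 and PolyPhen > 0.85.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "gene_mutation_table",
    "test_clone_specific_genes",
    "flag_high_risk",
    "bh_adjust",
]

GROUPS = ("metastatic_clones", "primary_clones")


def gene_mutation_table(m, assignment: pd.Series, ann: pd.DataFrame,
                        groups: dict[str, str]) -> pd.DataFrame:
    """Per gene x clone-group mutated/total cell counts.

    ``groups`` maps every clone label to ``primary_clones``,
    ``metastatic_clones`` or ``exclude`` (normal clones); an unmapped clone
    label raises. Only SNVs annotated nonsynonymous contribute, so
    synonymous-only genes are absent.
    """
    assignment = assignment.reindex(m.df.index)
    groups_n = {str(k): v for k, v in groups.items()}
    unmapped = sorted({str(c) for c in assignment.unique()} - set(groups_n))
    if unmapped:
        raise ValueError(f"clone labels without a group mapping: {unmapped}")
    bad = set(groups_n.values()) - set(GROUPS) - {"exclude"}
    if bad:
        raise ValueError(f"unknown group values: {sorted(bad)}")
    cell_group = assignment.astype(str).map(groups_n)
    ann_ns = ann[(ann["consequence"] == "nonsynonymous")
                 & ann["snv_key"].isin(m.df.columns)]
    rows = []
    for gene, sub in ann_ns.groupby("gene"):
        cols = m.df[sub["snv_key"].unique()]
        observed = cols.notna().any(axis=1)
        mutated = (cols == 1.0).any(axis=1)
        for group in GROUPS:
            in_group = (cell_group == group) & observed
            rows.append({
                "gene": gene,
                "group": group,
                "n_cells_mutated": int((mutated & in_group).sum()),
                "n_cells_total": int(in_group.sum()),
            })
    out = pd.DataFrame(rows, columns=["gene", "group", "n_cells_mutated",
                                      "n_cells_total"])
    out["mutation_rate"] = (out["n_cells_mutated"]
                            / out["n_cells_total"].where(out["n_cells_total"] > 0))
    return out


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q_i = min_{j>=i} p_j*m/j)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def test_clone_specific_genes(table: pd.DataFrame, fdr_threshold: float = 0.05,
                              lfc_threshold: float = 1.0,
                              min_cells_mutated: int = 3,
                              continuity_correction: bool = False
                              ) -> pd.DataFrame:
    """Metastatic vs primary gene mutation-rate test with BH correction.

    Genes mutated in fewer than ``min_cells_mutated`` cells overall are not
    tested. The 2x2 table is [mutated, unmutated] x [metastatic, primary];
    Fisher's exact test replaces the chi-squared when an expected count is
    below 5 (``fisher`` flag set). log2FC uses a pseudocount
    eps = 0.5 / max(group size).
    """
    if table.empty:
        raise ValueError("empty gene/clone-group table")
    wide = table.pivot(index="gene", columns="group",
                       values=["n_cells_mutated", "n_cells_total"])
    rows = []
    for gene in wide.index:
        m_mut = int(wide.loc[gene, ("n_cells_mutated", "metastatic_clones")])
        m_tot = int(wide.loc[gene, ("n_cells_total", "metastatic_clones")])
        p_mut = int(wide.loc[gene, ("n_cells_mutated", "primary_clones")])
        p_tot = int(wide.loc[gene, ("n_cells_total", "primary_clones")])
        if m_tot == 0 or p_tot == 0:
            continue
        if m_mut + p_mut < min_cells_mutated:
            continue
        obs = np.array([[m_mut, m_tot - m_mut], [p_mut, p_tot - p_mut]])
        total = obs.sum()
        expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
        use_fisher = bool((expected < 5).any())
        if use_fisher:
            _, p_value = stats.fisher_exact(obs, alternative="two-sided")
            chi2 = np.nan
        else:
            chi2, p_value, _, _ = stats.chi2_contingency(
                obs, correction=continuity_correction)
        eps = 0.5 / max(m_tot, p_tot)
        rate_m, rate_p = m_mut / m_tot, p_mut / p_tot
        # difference-of-logs form so that swapping the groups negates the
        # fold change exactly, bit for bit
        lfc = float(np.log2(rate_m + eps) - np.log2(rate_p + eps))
        rows.append({
            "gene": gene, "chi2_stat": chi2, "p_value": float(p_value),
            "fisher": use_fisher, "rate_metastatic": rate_m,
            "rate_primary": rate_p, "log2_fold_change": lfc,
        })
    if not rows:
        raise ValueError("no gene passed the minimum-mutated-cells filter")
    res = pd.DataFrame(rows).sort_values("gene", kind="mergesort"
                                         ).reset_index(drop=True)
    res["fdr"] = bh_adjust(res["p_value"].to_numpy())
    res["selected"] = (res["fdr"] < fdr_threshold) \
        & (res["log2_fold_change"].abs() > lfc_threshold)
    res["direction"] = np.where(res["log2_fold_change"] >= 0,
                                "metastatic", "primary")
    res["high_risk"] = False
    return res


def flag_high_risk(results: pd.DataFrame, ann: pd.DataFrame,
                   sift_threshold: float = 0.05,
                   polyphen_threshold: float = 0.85) -> pd.DataFrame:
    """High-risk genes: any nonsynonymous SNV with SIFT < 0.05, PolyPhen > 0.85.

    Missing scores never qualify.
    """
    ns = ann[ann["consequence"] == "nonsynonymous"]
    hit = ns[(ns["sift_score"] < sift_threshold)
             & (ns["polyphen_score"] > polyphen_threshold)]
    risky = set(hit["gene"])
    out = results.copy()
    out["high_risk"] = out["gene"].isin(risky)
    return out
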