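"""Self-contained evaluation experiments over synthetic data.

Each function regenerates its inputs from a seed, runs the relevant pipeline
stages and measures recovery of the known truth: clustering accuracy, clone
genotype and topology recovery, bulk/single-cell concordance, low-MAF rescue
sensitivity, gene-test calibration and power, purity recovery, and run
determinism. Used by the acceptance harness and the test suite.
"""

from __future__ import annotations

import filecmp
import os
from dataclasses import replace

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score, silhouette_score

from . import bulkcmp, clones, datasets, genesel, lineage, scgeno, sim
from .config import config_from_dict
from .pipeline import run_pipeline

DEFAULT_SIM = dict(n_clones=4, n_snvs=200, n_cells_per_clone=15,
                   ado_rate=0.2, fp_rate=0.002, mean_depth=80.0,
                   missing_rate=0.1)


def _filtered_matrix(cells, truth, germline=frozenset()):
    cfg = scgeno.FilterConfig()
    kept, _ = scgeno.qc_cells(cells, cfg, n_target_sites=len(truth.snv_catalog))
    m = scgeno.build_genotype_matrix(cells, kept, cfg)
    m = scgeno.filter_min_cells(m, cfg)
    m = scgeno.filter_clustered(m, cfg)
    return scgeno.filter_germline(m, germline)


def grid_agreement(max_depth: int = 150) -> dict:
    """Consensus-call rule vs an independent piecewise restatement, full grid."""
    n = agree = 0
    for depth in range(max_depth + 1):
        for alt in range(depth + 1):
            got = scgeno.call_genotype(depth, alt)
            # independent restatement of the depth-stratified rule set
            if depth < 10:
                want = None
            elif depth <= 20:
                want = 1 if alt >= 10 else 0
            elif depth <= 100:
                want = 1 if alt / depth >= 0.30 else 0
            else:
                want = 1 if alt / depth >= 0.20 else 0
            ok = (np.isnan(got) and want is None) or \
                 (want is not None and got == want)
            agree += ok
            n += 1
    return {"value": 100.0 * agree / n, "n": n}


BOUNDARY_CASES = [
    ((9, 9), None), ((15, 10), 1), ((15, 9), 0), ((50, 15), 1),
    ((50, 14), 0), ((120, 24), 1), ((120, 23), 0),
]


def boundary_fidelity() -> dict:
    """The seven printed boundary cases of the stratified rule."""
    correct = 0
    for (depth, alt), want in BOUNDARY_CASES:
        got = scgeno.call_genotype(depth, alt)
        correct += (np.isnan(got) and want is None) or got == want
    return {"value": correct, "n": len(BOUNDARY_CASES)}


def toy_filter_counts() -> dict:
    """Removal counts by reason on the constructed 20x30 filter fixture."""
    m, germline = datasets.toy_filter_fixture()
    m = scgeno.filter_min_cells(m)
    m = scgeno.filter_clustered(m)
    m = scgeno.filter_germline(m, germline)
    reasons = m.removals_table()["reason"].value_counts().to_dict()
    return {"value": int(sum(reasons.values())), "n": 30,
            "by_reason": {k: int(v) for k, v in sorted(reasons.items())}}


def _map_clusters_to_clones(labels: pd.Series, truth_clone: pd.Series) -> dict:
    mapping = {}
    for cluster, cells in labels.groupby(labels).groups.items():
        mapping[cluster] = truth_clone.reindex(cells).mode().iloc[0]
    return mapping


def clone_recovery(seed: int) -> dict:
    """Clustering ARI (at the generative clone count) and MDS silhouette."""
    cfg = sim.SimConfig(seed=seed, **DEFAULT_SIM)
    truth = sim.simulate_clone_tree(cfg)
    cells, meta = sim.simulate_cells(truth, cfg)
    m = _filtered_matrix(cells, truth)
    dist = clones.pairwise_cell_distance(m)
    labels, _ = clones.hierarchical_cluster(dist, k=cfg.n_clones)
    truth_clone = meta.set_index("cell_id")["clone"].reindex(labels.index)
    ari = float(adjusted_rand_score(truth_clone, labels))
    coords = clones.classical_mds(dist, dims=2)
    sil = float(silhouette_score(coords.to_numpy(),
                                 truth_clone.reindex(coords.index)))
    return {"ari": ari, "mds_silhouette": sil, "n_cells": int(len(labels))}


def genotype_recovery(seed: int, noiseless: bool = False) -> dict:
    """Clone consensus genotype agreement with truth; tree RF when noiseless."""
    cfg = sim.SimConfig(seed=seed, **DEFAULT_SIM)
    if noiseless:
        cfg = sim.noiseless(cfg)
    truth = sim.simulate_clone_tree(cfg)
    cells, meta = sim.simulate_cells(truth, cfg)
    m = _filtered_matrix(cells, truth)
    dist = clones.pairwise_cell_distance(m)
    labels, _ = clones.hierarchical_cluster(dist, k=cfg.n_clones)
    truth_clone = meta.set_index("cell_id")["clone"].reindex(labels.index)
    mapping = _map_clusters_to_clones(labels, truth_clone)
    em = lineage.ErrorModel(alpha=cfg.fp_rate, beta=cfg.ado_rate) \
        if not noiseless else lineage.ErrorModel(alpha=0.0, beta=0.0)
    geno, _ = lineage.infer_clone_genotypes(m, labels, em)
    total = agree = 0
    for cluster in geno.index:
        want = truth.clone_genotypes.loc[mapping[cluster], geno.columns]
        agree += int((geno.loc[cluster].to_numpy() == want.to_numpy()).sum())
        total += geno.shape[1]
    out = {"agreement_pct": 100.0 * agree / total, "n_entries": int(total)}
    tumour = set(truth.tumour_clones())
    tumour_clusters = [c for c in geno.index if mapping[c] in tumour]
    named = geno.loc[tumour_clusters]
    named.index = [mapping[c] for c in tumour_clusters]
    if not named.index.has_duplicates and len(named) >= 2:
        ct = lineage.build_tree(named, merge_duplicates=True)
        inferred = lineage.tree_splits(ct.tree)
        expected = lineage.parent_map_splits(truth.parent, truth.root,
                                             taxa=tumour)
        out["rf_distance"] = lineage.robinson_foulds(inferred, expected)
    return out


SUBCLONE_SIM = dict(n_clones=4, n_snvs=200, ado_rate=0.2, fp_rate=0.002,
                    mean_depth=80.0, missing_rate=0.1, purity=1.0,
                    bulk_mean_depth=300.0,
                    cells_per_clone=[20, 38, 38, 4],
                    clone_fractions={"T": [0.475, 0.475, 0.05]})


def concordance_eval(seed: int, caller_min_vaf: float = 0.05,
                     caller_min_alt: int = 4) -> dict:
    """Frequency/MAF correlation and low-MAF rescue of a 5% subclone.

    The bulk sample is a purity-1 mixture in which the last (leaf) clone is
    planted at 5%; a caller-sensitivity threshold on the simulated bulk
    stands in for the upstream somatic callers, so the subclone's private
    SNVs arrive sc-specific and must be rescued from the pileup.
    """
    cfg = sim.SimConfig(seed=seed, **SUBCLONE_SIM)
    truth = sim.simulate_clone_tree(cfg)
    cells, meta = sim.simulate_cells(truth, cfg)
    bulk = sim.simulate_bulk(truth, cfg)["T"]
    m = _filtered_matrix(cells, truth)
    called = bulk[(bulk["vaf"].fillna(0) >= caller_min_vaf)
                  & (bulk["alt_depth"] >= caller_min_alt)]
    filtered = bulkcmp.filter_bulk_variants(called, called)
    cats = bulkcmp.rescue_low_maf(bulkcmp.classify_snvs(m, filtered), bulk)
    r, n_pairs = bulkcmp.concordance_correlation(cats)
    sub = truth.clones[-1]
    private = {k for k, e in truth.branch_assignment.items() if e == sub}
    sc_specific = cats[cats["category"] == "sc_specific"]
    priv_rows = sc_specific[sc_specific["snv_key"].isin(private)]
    sens = (100.0 * priv_rows["low_maf"].mean()) if len(priv_rows) else np.nan
    return {"r": float(r), "n_pairs": int(n_pairs),
            "low_maf_sensitivity_pct": float(sens),
            "n_private_detected": int(len(priv_rows))}


def purity_recovery(seed: int, purity: float = 0.6, n_snvs: int = 200,
                    depth: float = 300.0) -> dict:
    """Purity estimate on a clonal-only bulk sample."""
    cfg = sim.SimConfig(seed=seed, n_clones=2, n_snvs=n_snvs, purity=purity,
                        bulk_mean_depth=depth, cluster_fraction=0.0)
    truth = sim.simulate_clone_tree(cfg)
    bulk = sim.simulate_bulk(truth, cfg)["T"]
    est = bulkcmp.estimate_purity(bulk)
    return {"estimate": float(est), "true_purity": purity, "n_snvs": n_snvs}


def _binomial_gene_table(rng, n_genes, rate_met, rate_pri, n_met, n_pri,
                         prefix="G"):
    rows = []
    for i in range(n_genes):
        m_mut = int(rng.binomial(n_met, rate_met))
        p_mut = int(rng.binomial(n_pri, rate_pri))
        gene = f"{prefix}{i:04d}"
        rows.append((gene, "metastatic_clones", m_mut, n_met))
        rows.append((gene, "primary_clones", p_mut, n_pri))
    df = pd.DataFrame(rows, columns=["gene", "group", "n_cells_mutated",
                                     "n_cells_total"])
    df["mutation_rate"] = df["n_cells_mutated"] / df["n_cells_total"]
    return df


def null_calibration(seed: int, n_genes: int = 1000, rate: float = 0.3,
                     n_cells: int = 30) -> dict:
    """Type-I error of the gene test on equal-rate binomial nulls."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(10,)))
    table = _binomial_gene_table(rng, n_genes, rate, rate, n_cells, n_cells)
    res = genesel.test_clone_specific_genes(table)
    frac = float((res["p_value"] < 0.05).mean())
    return {"raw_p_lt_05_pct": 100.0 * frac,
            "n_selected": int(res["selected"].sum()),
            "n_tested": int(len(res))}


def planted_gene_power(seed: int, n_replicates: int = 100,
                       rate_met: float = 0.6, rate_pri: float = 0.05,
                       n_cells: int = 30, n_null: int = 20) -> dict:
    """Selection rate for one high-contrast gene among binomial nulls."""
    hits = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(11, rep)))
        null = _binomial_gene_table(rng, n_null, 0.3, 0.3, n_cells, n_cells)
        planted = _binomial_gene_table(rng, 1, rate_met, rate_pri,
                                       n_cells, n_cells, prefix="PLANTED")
        res = genesel.test_clone_specific_genes(pd.concat([null, planted]))
        row = res[res["gene"] == "PLANTED0000"]
        hits += int(len(row) and bool(row["selected"].iloc[0]))
    return {"n_selected": hits, "n_replicates": n_replicates}


def determinism_check(seed: int, work_dir: str) -> dict:
    """Two full pipeline runs with one seed must write identical summaries."""
    cfg1 = config_from_dict({"seed": int(seed)})
    cfg2 = config_from_dict({"seed": int(seed)})
    d1, d2 = os.path.join(work_dir, "runA"), os.path.join(work_dir, "runB")
    run_pipeline(cfg1, d1)
    run_pipeline(cfg2, d2)
    same = filecmp.cmp(os.path.join(d1, "summary.json"),
                       os.path.join(d2, "summary.json"), shallow=False)
    return {"identical": int(same)}
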