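"""End-to-end driver: simulate -> genotype -> concordance -> clones ->
lineage -> genes, with every intermediate written to the run directory and a
machine-readable JSON summary.

Each stage draws randomness from a stream derived from the single run seed
and a fixed stage index, so stages are independently reproducible and the
whole run is byte-deterministic.
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score, silhouette_score

from . import bulkcmp, clones, genesel, lineage, scgeno, sim
from . import io as sio
from .config import PipelineConfig

log = logging.getLogger("scwes_clones")

__all__ = ["run_pipeline", "majority_tissue"]


def _round(x, nd: int = 10):
    if isinstance(x, (float, np.floating)):
        return round(float(x), nd)
    return x


def majority_tissue(labels: pd.Series, tissues: pd.Series) -> dict[str, str]:
    """Dominant true tissue per cluster (evaluation / group mapping only)."""
    out = {}
    for cluster, cells in labels.groupby(labels).groups.items():
        counts = tissues.reindex(cells).value_counts()
        out[str(cluster)] = str(counts.idxmax()) if len(counts) else "normal"
    return out


def run_pipeline(cfg: PipelineConfig, out_dir: str | None = None) -> dict:
    """Run all stages on a synthetic dataset; returns the summary dict."""
    cfg.validate()
    out_dir = out_dir or cfg.out_dir
    os.makedirs(out_dir, exist_ok=True)
    summary: dict = {"seed": int(cfg.seed)}

    # ---- simulate -------------------------------------------------------
    log.info("[sim] generating clone tree and reads")
    truth = sim.simulate_clone_tree(cfg.sim)
    cells, cells_meta = sim.simulate_cells(truth, cfg.sim)
    bulks = sim.simulate_bulk(truth, cfg.sim)
    annotations = sim.simulate_annotations(truth, cfg.sim)
    sim.write_fixture(truth, cells, cells_meta, bulks,
                      os.path.join(out_dir, "sim"), annotations=annotations)

    # ---- single-cell genotyping ----------------------------------------
    log.info("[scgeno] QC and consensus genotyping")
    kept, dropped = scgeno.qc_cells(cells, cfg.filter,
                                    n_target_sites=len(truth.snv_catalog))
    matrix = scgeno.build_genotype_matrix(cells, kept, cfg.filter)
    n_called = len(matrix.snvs)
    matrix = scgeno.filter_min_cells(matrix, cfg.filter)
    matrix = scgeno.filter_clustered(matrix, cfg.filter)
    normal_cells = cells_meta.loc[cells_meta["tissue"] == "normal", "cell_id"]
    germline = scgeno.germline_from_normals(matrix, list(normal_cells))
    matrix = scgeno.filter_germline(matrix, germline)
    removals = matrix.removals_table()
    mat_out = matrix.df.copy()
    mat_out.index.name = "cell_id"
    sio.write_tsv(mat_out, os.path.join(out_dir, "genotype_matrix.tsv"),
                  index=True)
    sio.write_tsv(removals, os.path.join(out_dir, "removals.tsv"))
    freqs = scgeno.mutation_frequencies(matrix).rename_axis("snv_key")
    sio.write_tsv(freqs.reset_index(), os.path.join(out_dir, "frequencies.tsv"))
    summary.update({
        "n_cells_total": int(cells_meta.shape[0]),
        "n_cells_kept": len(kept),
        "cells_dropped": {r.cell_id: r.reason for r in dropped.itertuples()},
        "n_snvs_called": n_called,
        "n_snvs_retained": len(matrix.snvs),
        "removals_by_reason":
            removals["reason"].value_counts().sort_index().to_dict(),
    })

    # ---- bulk concordance ----------------------------------------------
    log.info("[bulkcmp] bulk consensus filtering and concordance")
    sample = sorted(bulks)[0]
    bulk = bulks[sample]
    targets = sio.read_bed(os.path.join(out_dir, "sim", "targets.bed"))
    called = bulk[(bulk["vaf"].fillna(0) >= cfg.concordance.caller_min_vaf)
                  & (bulk["alt_depth"] >= cfg.concordance.caller_min_alt)]
    bulk_filtered = bulkcmp.filter_bulk_variants(
        called, called, targets, min_depth=cfg.concordance.min_bulk_depth)
    categories = bulkcmp.classify_snvs(matrix, bulk_filtered)
    categories = bulkcmp.rescue_low_maf(
        categories, bulk,
        min_support=cfg.concordance.low_maf_min_support,
        low_maf_ceiling=cfg.concordance.low_maf_ceiling)
    sio.write_tsv(categories, os.path.join(out_dir, "snv_categories.tsv"))
    r, n_pairs = bulkcmp.concordance_correlation(categories)
    purity = bulkcmp.estimate_purity(bulk_filtered)
    pct = bulkcmp.category_percentages(categories)
    summary.update({
        "category_percentages": {k: _round(v) for k, v in pct.items()},
        "n_low_maf": int(categories["low_maf"].sum()),
        "concordance_r": _round(r),
        "concordance_n": n_pairs,
        "purity_estimate": _round(purity),
    })

    # ---- clone discovery ------------------------------------------------
    log.info("[clones] distances, clustering, MDS")
    dist = clones.pairwise_cell_distance(matrix, cfg.clones.min_support)
    labels, _ = clones.hierarchical_cluster(dist, cfg.clones.k)
    coords = clones.classical_mds(dist, cfg.clones.mds_dims)
    snv_clusters = clones.cluster_snvs(matrix, cfg.clones.snv_k,
                                       cfg.clones.min_support)
    tissues = cells_meta.set_index("cell_id")["tissue"]
    true_clones = cells_meta.set_index("cell_id")["clone"]
    ari = adjusted_rand_score(true_clones.reindex(labels.index), labels)
    sil = (silhouette_score(coords.to_numpy(),
                            tissues.reindex(coords.index))
           if tissues.reindex(coords.index).nunique() > 1 else float("nan"))
    assign_out = pd.DataFrame({
        "cell_id": labels.index, "cluster": labels.to_numpy(),
        "tissue": tissues.reindex(labels.index).to_numpy(),
    })
    sio.write_tsv(dist.d.rename_axis("cell_id"),
                  os.path.join(out_dir, "distances.tsv"), index=True)
    sio.write_tsv(assign_out, os.path.join(out_dir, "clone_assignment.tsv"))
    sio.write_tsv(coords.rename_axis("cell_id").reset_index(),
                  os.path.join(out_dir, "mds_coords.tsv"))
    sio.write_tsv(snv_clusters, os.path.join(out_dir, "snv_clusters.tsv"))
    summary.update({
        "n_clusters": int(labels.nunique()),
        "ari_vs_truth": _round(float(ari)),
        "mds_silhouette_true_tissues": _round(float(sil)),
        "n_snv_clusters": int(snv_clusters["snv_cluster"].nunique()),
    })

    # ---- lineage --------------------------------------------------------
    log.info("[lineage] clone genotypes and NJ tree")
    tissue_of_cluster = majority_tissue(labels, tissues)
    tumour_clusters = [c for c, t in tissue_of_cluster.items() if t != "normal"]
    cluster_names = labels.astype(str).map(lambda c: f"C{c}")
    tumour_cells = labels.index[labels.astype(str).isin(tumour_clusters)]
    tree_newick = None
    if len(tumour_clusters) >= 1 and len(tumour_cells) > 0:
        sub_matrix = scgeno.GenotypeMatrix(matrix.df.loc[tumour_cells])
        clone_geno, _ = lineage.infer_clone_genotypes(
            sub_matrix, cluster_names.loc[tumour_cells],
            cfg.lineage.error_model())
        geno_out = clone_geno.copy()
        geno_out.index.name = "clone"
        sio.write_tsv(geno_out, os.path.join(out_dir, "clone_genotypes.tsv"),
                      index=True)
        if len(clone_geno) >= 1:
            ct = lineage.build_tree(clone_geno, merge_duplicates=True)
            tree_newick = lineage.write_newick(ct)
            with open(os.path.join(out_dir, "tree.nwk"), "w") as fh:
                fh.write(tree_newick + "\n")
            tissue_map = {f"C{c}": tissue_of_cluster[c]
                          for c in tissue_of_cluster}
            branch_sites = lineage.annotate_clone_specific_sites(ct, tissue_map)
            sio.write_tsv(branch_sites, os.path.join(out_dir,
                                                     "branch_sites.tsv"))
            summary["branch_site_labels"] = \
                branch_sites["label"].value_counts().sort_index().to_dict()
    summary["tree_newick"] = tree_newick

    # ---- clone-specific genes ------------------------------------------
    log.info("[genesel] clone-group-specific mutated genes")
    groups = {f"C{c}": ("exclude" if t == "normal" else
                        "metastatic_clones" if t == "metastatic"
                        else "primary_clones")
              for c, t in tissue_of_cluster.items()}
    have_both = ({"metastatic_clones", "primary_clones"}
                 <= set(groups.values()))
    selected_genes: list[str] = []
    if have_both:
        gene_table = genesel.gene_mutation_table(
            matrix, cluster_names, annotations, groups)
        try:
            results = genesel.test_clone_specific_genes(
                gene_table, cfg.genes.fdr_threshold, cfg.genes.lfc_threshold,
                cfg.genes.min_cells_mutated)
        except ValueError:
            results = None
        if results is not None:
            results = genesel.flag_high_risk(
                results, annotations, cfg.genes.sift_threshold,
                cfg.genes.polyphen_threshold)
            sio.write_tsv(results, os.path.join(out_dir, "gene_tests.tsv"))
            selected_genes = sorted(results.loc[results["selected"], "gene"])
            summary["n_genes_tested"] = int(len(results))
            summary["n_high_risk_selected"] = int(
                (results["selected"] & results["high_risk"]).sum())
    summary["selected_genes"] = selected_genes

    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
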