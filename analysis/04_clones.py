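#!/usr/bin/env python
"""Discover the cell-population structure: Jaccard-complement distances over
co-observed sites, average-linkage clustering at the known clone count, a
2-D classical MDS map, and SNV co-occurrence clusters.

Reads results/analysis/; writes clone_assignment.tsv, mds_coords.tsv,
distances.tsv and snv_clusters.tsv.
"""

import pathlib

import pandas as pd
from sklearn.metrics import adjusted_rand_score, silhouette_score

from scwes_clones import clones
from scwes_clones import io as sio
from scwes_clones.scgeno import GenotypeMatrix

ROOT = pathlib.Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "analysis"
K = 4      # generative clone count (normal + 3 tumour clones)


def main() -> None:
    matrix = GenotypeMatrix(sio.read_tsv(str(OUT / "genotype_matrix.tsv"),
                                         index_col=0))
    meta = sio.read_tsv(str(OUT / "sim" / "truth_cells.tsv")).set_index(
        "cell_id")
    dist = clones.pairwise_cell_distance(matrix)
    labels, _ = clones.hierarchical_cluster(dist, k=K)
    coords = clones.classical_mds(dist, dims=2)
    snv_clusters = clones.cluster_snvs(matrix, k="auto")

    sio.write_tsv(dist.d.rename_axis("cell_id"), str(OUT / "distances.tsv"),
                  index=True)
    assign = pd.DataFrame({
        "cell_id": labels.index, "cluster": labels.to_numpy(),
        "tissue": meta["tissue"].reindex(labels.index).to_numpy(),
    })
    sio.write_tsv(assign, str(OUT / "clone_assignment.tsv"))
    sio.write_tsv(coords.rename_axis("cell_id").reset_index(),
                  str(OUT / "mds_coords.tsv"))
    sio.write_tsv(snv_clusters, str(OUT / "snv_clusters.tsv"))

    truth = meta["clone"].reindex(labels.index)
    ari = adjusted_rand_score(truth, labels)
    sil = silhouette_score(coords.to_numpy(), truth)
    comp = clones.tissue_composition(labels, meta["tissue"])
    print(f"{labels.nunique()} cell populations "
          f"(ARI vs true clones = {ari:.3f})")
    print("tissue composition per population:")
    print(comp.to_string())
    print(f"MDS silhouette of true clones in 2-D = {sil:.3f}")
    print(f"{snv_clusters['snv_cluster'].nunique()} SNV co-occurrence "
          f"clusters over {len(snv_clusters)} SNVs")


if __name__ == "__main__":
    main()
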