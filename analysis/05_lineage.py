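#!/usr/bin/env python
"""Reconstruct the clone lineage: maximum-likelihood consensus genotypes per
cell population under the alpha = 0.002 / beta = 0.2 error model, a
neighbor-joining tree rooted at an all-reference outgroup, and per-branch
acquired mutations split into trunk / primary / metastatic.

Reads results/analysis/; writes clone_genotypes.tsv, tree.nwk and
branch_sites.tsv.
"""

import pathlib

import pandas as pd

from scwes_clones import io as sio
from scwes_clones import lineage
from scwes_clones.pipeline import majority_tissue
from scwes_clones.scgeno import GenotypeMatrix

ROOT = pathlib.Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "analysis"


def main() -> None:
    matrix = GenotypeMatrix(sio.read_tsv(str(OUT / "genotype_matrix.tsv"),
                                         index_col=0))
    assign = sio.read_tsv(str(OUT / "clone_assignment.tsv"))
    labels = assign.set_index("cell_id")["cluster"]
    tissues = assign.set_index("cell_id")["tissue"]
    tissue_of = majority_tissue(labels, tissues)
    tumour = [c for c, t in tissue_of.items() if t != "normal"]
    cells = labels.index[labels.astype(str).isin(tumour)]

    names = labels.astype(str).map(lambda c: f"C{c}")
    sub = GenotypeMatrix(matrix.df.loc[cells])
    geno, _ = lineage.infer_clone_genotypes(sub, names.loc[cells],
                                            lineage.ErrorModel())
    out_geno = geno.copy()
    out_geno.index.name = "clone"
    sio.write_tsv(out_geno, str(OUT / "clone_genotypes.tsv"), index=True)

    ct = lineage.build_tree(geno, merge_duplicates=True)
    newick = lineage.write_newick(ct)
    (OUT / "tree.nwk").write_text(newick + "\n")
    tissue_map = {f"C{c}": t for c, t in tissue_of.items()}
    branch_sites = lineage.annotate_clone_specific_sites(ct, tissue_map)
    sio.write_tsv(branch_sites, str(OUT / "branch_sites.tsv"))

    print(f"tumour clone populations: {sorted(geno.index)}")
    print(f"lineage: {newick}")
    counts = branch_sites["label"].value_counts().to_dict()
    print(f"acquired mutations by branch label: {counts}")


if __name__ == "__main__":
    main()
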