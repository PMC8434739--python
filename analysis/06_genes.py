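#!/usr/bin/env python
"""Identify metastatic-clone-specific mutated genes: per-gene mutated-cell
counts in metastatic vs primary populations, uncorrected chi-squared test
(Fisher fallback), Benjamini-Hochberg FDR < 0.05 with |log2 fold| > 1, and
the SIFT < 0.05 / PolyPhen > 0.85 high-risk flag.

Reads results/analysis/; writes gene_tests.tsv.
"""

import pathlib

from scwes_clones import genesel
from scwes_clones import io as sio
from scwes_clones.pipeline import majority_tissue
from scwes_clones.scgeno import GenotypeMatrix

ROOT = pathlib.Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "analysis"


def main() -> None:
    matrix = GenotypeMatrix(sio.read_tsv(str(OUT / "genotype_matrix.tsv"),
                                         index_col=0))
    assign = sio.read_tsv(str(OUT / "clone_assignment.tsv"))
    ann = sio.read_tsv(str(OUT / "sim" / "annotations.tsv"))
    labels = assign.set_index("cell_id")["cluster"]
    tissues = assign.set_index("cell_id")["tissue"]
    groups = {c: ("exclude" if t == "normal" else
                  "metastatic_clones" if t == "metastatic"
                  else "primary_clones")
              for c, t in majority_tissue(labels, tissues).items()}

    table = genesel.gene_mutation_table(matrix, labels, ann, groups)
    res = genesel.test_clone_specific_genes(table)
    res = genesel.flag_high_risk(res, ann)
    sio.write_tsv(res, str(OUT / "gene_tests.tsv"))

    sel = res[res["selected"]]
    print(f"{len(res)} genes tested; {len(sel)} clone-group specific "
          f"(FDR < 0.05, |log2 fold| > 1)")
    if len(sel):
        cols = ["gene", "p_value", "fdr", "log2_fold_change", "direction",
                "high_risk"]
        print(sel[cols].to_string(index=False))
    print(f"high-risk among selected: "
          f"{int((sel['high_risk']).sum())}")


if __name__ == "__main__":
    main()
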