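#!/usr/bin/env python
"""QC the simulated cells (>= 75% coverage, >= 10x mean depth) and build the
ternary genotype matrix with the depth-stratified consensus rule, then apply
the three site filters: fewer than 3 mutant cells, 10-bp clustered regions,
and germline sites (augmented from normal-tissue cells).

Reads results/analysis/sim/, writes matrix + removals + frequencies under
results/analysis/.
"""

import pathlib

import pandas as pd

from scwes_clones import io as sio
from scwes_clones import scgeno

ROOT = pathlib.Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "analysis"


def main() -> None:
    cells = sio.read_cells_tsv(str(OUT / "sim" / "cells.tsv"))
    meta = sio.read_tsv(str(OUT / "sim" / "truth_cells.tsv"))
    cfg = scgeno.FilterConfig()
    kept, dropped = scgeno.qc_cells(cells, cfg)
    m = scgeno.build_genotype_matrix(cells, kept, cfg)
    n_called = len(m.snvs)
    m = scgeno.filter_min_cells(m, cfg)
    m = scgeno.filter_clustered(m, cfg)
    normals = meta.loc[meta["tissue"] == "normal", "cell_id"]
    germline = scgeno.germline_from_normals(m, list(normals))
    m = scgeno.filter_germline(m, germline)

    mat = m.df.copy()
    mat.index.name = "cell_id"
    sio.write_tsv(mat, str(OUT / "genotype_matrix.tsv"), index=True)
    sio.write_tsv(m.removals_table(), str(OUT / "removals.tsv"))
    freqs = scgeno.mutation_frequencies(m).rename_axis("snv_key")
    sio.write_tsv(freqs.reset_index(), str(OUT / "frequencies.tsv"))

    reasons = m.removals_table()["reason"].value_counts().to_dict()
    print(f"cells: {len(kept)} kept, {len(dropped)} dropped")
    print(f"SNVs: {n_called} called, {len(m.snvs)} retained "
          f"(removed by reason: {reasons})")
    burden = (m.df == 1.0).sum(axis=1)
    by_tissue = burden.groupby(
        meta.set_index("cell_id")["tissue"].reindex(burden.index)).median()
    print("median per-cell mutation burden by tissue:")
    print(by_tissue.to_string())


if __name__ == "__main__":
    main()
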