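"""Small constructed datasets used by tests and worked examples."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import make_key
from .scgeno import GenotypeMatrix


def toy_filter_fixture() -> tuple[GenotypeMatrix, set[str]]:
    """A 20-cell x 30-SNV ternary matrix exercising all three site filters.

    Contents, by construction:

    * 19 clean SNVs (chr1, 1 kb apart), each mutant in >= 3 cells;
    * 4 SNVs mutant in fewer than 3 cells (chr2) -> min_cells removals;
    * 2 SNV pairs within 10 bp on chr3 (each member mutant in >= 3 cells)
      -> 4 clustered removals;
    * 3 germline sites (chr1, isolated, high prevalence) -> 3 germline
      removals, given the returned germline key set.

    Sprinkled NA entries imitate low-coverage sites. Expected removal count:
    4 + 4 + 3 = 11, leaving 19 columns.
    """
    n_cells = 20
    cells = [f"cell{i:02d}" for i in range(n_cells)]
    rng = np.random.default_rng(7)
    cols: dict[str, np.ndarray] = {}

    def column(n_mut: int, na_slots: tuple[int, ...] = ()) -> np.ndarray:
        col = np.zeros(n_cells)
        mut = rng.choice(n_cells, size=n_mut, replace=False)
        col[mut] = 1.0
        for i in na_slots:
            if col[i] != 1.0:
                col[i] = np.nan
        return col

    for i in range(19):
        key = make_key("chr1", 1000 + 1000 * i, "A", "T")
        cols[key] = column(3 + i % 5, na_slots=(i % n_cells,))
    for i, n_mut in enumerate([2, 2, 1, 1]):
        key = make_key("chr2", 1000 + 1000 * i, "C", "G")
        cols[key] = column(n_mut, na_slots=((i + 3) % n_cells,))
    for pos in (100_000, 100_005, 200_000, 200_008):
        key = make_key("chr3", pos, "G", "A")
        cols[key] = column(4)
    germline = set()
    for pos in (50_000_000, 60_000_000, 70_000_000):
        key = make_key("chr1", pos, "T", "C")
        cols[key] = column(15)
        germline.add(key)

    df = pd.DataFrame(cols, index=cells)
    return GenotypeMatrix(df), germline
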