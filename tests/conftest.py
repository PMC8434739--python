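import numpy as np
import pandas as pd
import pytest

from scwes_clones import scgeno, sim


@pytest.fixture(scope="session")
def default_cfg() -> sim.SimConfig:
    return sim.SimConfig(seed=42)


@pytest.fixture(scope="session")
def default_truth(default_cfg):
    return sim.simulate_clone_tree(default_cfg)


@pytest.fixture(scope="session")
def default_cells(default_truth, default_cfg):
    return sim.simulate_cells(default_truth, default_cfg)


@pytest.fixture(scope="session")
def filtered_matrix(default_truth, default_cells):
    cells, _ = default_cells
    fcfg = scgeno.FilterConfig()
    kept, _ = scgeno.qc_cells(cells, fcfg,
                              n_target_sites=len(default_truth.snv_catalog))
    m = scgeno.build_genotype_matrix(cells, kept, fcfg)
    m = scgeno.filter_min_cells(m, fcfg)
    return scgeno.filter_clustered(m, fcfg)


def matrix_from_values(values, cells=None, snvs=None) -> scgeno.GenotypeMatrix:
    """Build a GenotypeMatrix from a plain nested list (None = NA)."""
    arr = np.array([[np.nan if v is None else float(v) for v in row]
                    for row in values])
    cells = cells or [f"cell{i}" for i in range(arr.shape[0])]
    snvs = snvs or [f"chr1:{1000 * (j + 1)}:A:T" for j in range(arr.shape[1])]
    return scgeno.GenotypeMatrix(pd.DataFrame(arr, index=cells, columns=snvs))
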