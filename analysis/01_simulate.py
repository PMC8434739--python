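#!/usr/bin/env python
"""Generate the study's synthetic cohort: a clone tree (normal root, primary
and metastatic tumour clones), single-cell read counts with allelic dropout
(beta = 0.2) and amplification false positives (alpha = 0.002), a matched
purity-weighted bulk sample, and a functional annotation table.

Writes the fixture under results/analysis/sim/.
"""

import argparse
import pathlib

from scwes_clones import sim

ROOT = pathlib.Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    args = ap.parse_args()

    cfg = sim.SimConfig(seed=args.seed)
    truth = sim.simulate_clone_tree(cfg)
    cells, meta = sim.simulate_cells(truth, cfg)
    bulks = sim.simulate_bulk(truth, cfg)
    ann = sim.simulate_annotations(truth, cfg)
    out = ROOT / "results" / "analysis" / "sim"
    sim.write_fixture(truth, cells, meta, bulks, str(out), annotations=ann)

    n_clonal = len(truth.clonal_keys())
    print(f"clone tree: {truth.parent}")
    print(f"tissues:    {truth.clone_labels}")
    print(f"{len(meta)} cells, {n_clonal} clonal SNVs "
          f"(+{len(truth.snv_catalog) - n_clonal} normal-background sites), "
          f"1 bulk sample at purity {cfg.purity}")
    print(f"fixture written to {out}")


if __name__ == "__main__":
    main()
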