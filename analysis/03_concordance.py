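#!/usr/bin/env python
"""Compare the single-cell SNV profile against the matched bulk sample:
classify every SNV as common / bulk-specific / single-cell-specific, rescue
sc-specific SNVs with sub-caller-sensitivity bulk read support (low-MAF),
correlate single-cell mutation frequency with bulk MAF, and estimate purity.

Reads results/analysis/{sim,genotype_matrix.tsv}; writes snv_categories.tsv,
concordance.tsv and purity.tsv.
"""

import pathlib

import pandas as pd

from scwes_clones import bulkcmp
from scwes_clones import io as sio
from scwes_clones.scgeno import GenotypeMatrix

ROOT = pathlib.Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "analysis"

CALLER_MIN_VAF = 0.05     # emulated somatic-caller sensitivity on sim bulk
CALLER_MIN_ALT = 4


def main() -> None:
    matrix = GenotypeMatrix(sio.read_tsv(str(OUT / "genotype_matrix.tsv"),
                                         index_col=0))
    bulk = sio.read_bulk_vcf(str(OUT / "sim" / "bulk_T.vcf"), sample_id="T")
    targets = sio.read_bed(str(OUT / "sim" / "targets.bed"))
    called = bulk[(bulk["vaf"].fillna(0) >= CALLER_MIN_VAF)
                  & (bulk["alt_depth"] >= CALLER_MIN_ALT)]
    filtered = bulkcmp.filter_bulk_variants(called, called, targets)
    cats = bulkcmp.classify_snvs(matrix, filtered)
    cats = bulkcmp.rescue_low_maf(cats, bulk)
    sio.write_tsv(cats, str(OUT / "snv_categories.tsv"))

    r, n = bulkcmp.concordance_correlation(cats)
    purity = bulkcmp.estimate_purity(filtered)
    pd.DataFrame([{"r": r, "n": n}]).to_csv(OUT / "concordance.tsv",
                                            sep="\t", index=False)
    pd.DataFrame([{"purity": purity}]).to_csv(OUT / "purity.tsv",
                                              sep="\t", index=False)

    pct = bulkcmp.category_percentages(cats).round(2)
    print("SNV categories (% of union):")
    print(pct.to_string())
    print(f"low-MAF rescued sc-specific SNVs: {int(cats['low_maf'].sum())}")
    print(f"frequency/MAF Pearson r = {r:.3f} over {n} SNVs")
    print(f"purity estimate (2 x clonal median VAF) = {purity:.3f}")


if __name__ == "__main__":
    main()
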