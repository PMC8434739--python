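"""Readers and writers for the plain-text formats used throughout the pipeline.

Tabular artifacts are TSV with headers and ``NA`` for missing values. Bulk
variants travel as minimal single-sample VCF (read back through pysam).
Site identity is always the 1-based VCF-convention tuple (chrom, pos, ref, alt),
serialised as the string key ``chrom:pos:ref:alt``.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
import pysam

NA_REP = "NA"

CELL_COLUMNS = ["cell_id", "chrom", "pos", "ref", "alt", "depth", "alt_depth"]


def make_key(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{int(pos)}:{ref}:{alt}"


def split_key(key: str) -> tuple[str, int, str, str]:
    chrom, pos, ref, alt = key.split(":")
    return chrom, int(pos), ref, alt


def key_frame(keys: Iterable[str]) -> pd.DataFrame:
    """Expand string site keys into a (chrom, pos, ref, alt) frame."""
    rows = [split_key(k) for k in keys]
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"], index=list(keys))


def write_tsv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep=NA_REP)


def read_tsv(path: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA_REP], keep_default_na=False,
                       **kwargs)


def write_cells_tsv(cells: pd.DataFrame, path: str) -> None:
    write_tsv(cells[CELL_COLUMNS], path)


def read_cells_tsv(path: str) -> pd.DataFrame:
    df = read_tsv(path, dtype={"chrom": str, "ref": str, "alt": str})
    missing = set(CELL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_bulk_vcf(bulk: pd.DataFrame, path: str, sample: str = "BULK") -> None:
    """Write a minimal but conformant single-sample VCF (GT:DP:AD)."""
    contigs = sorted(bulk["chrom"].unique())
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths (ref,alt)">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample}\n")
        ordered = bulk.sort_values(["chrom", "pos"], kind="mergesort")
        for row in ordered.itertuples(index=False):
            depth = int(row.depth)
            alt_depth = int(row.alt_depth)
            fh.write(f"{row.chrom}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t.\t"
                     f"PASS\t.\tGT:DP:AD\t"
                     f"0/1:{depth}:{depth - alt_depth},{alt_depth}\n")


def read_bulk_vcf(path: str, sample_id: str | None = None) -> pd.DataFrame:
    """Read a single-sample VCF with DP/AD into a bulk variant table."""
    rows = []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        if not samples:
            raise ValueError(f"{path}: VCF has no sample column")
        sm = samples[0]
        for rec in vf:
            fmt = rec.samples[sm]
            depth = fmt.get("DP")
            ad = fmt.get("AD")
            alt_depth = int(ad[1]) if ad is not None and len(ad) > 1 else 0
            for alt in rec.alts or ():
                rows.append((rec.chrom, rec.pos, rec.ref, alt,
                             int(depth) if depth is not None else 0, alt_depth))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                     "depth", "alt_depth"])
    df["vaf"] = df["alt_depth"] / df["depth"].where(df["depth"] > 0)
    df["sample_id"] = sample_id if sample_id is not None else os.path.basename(path)
    return df


def read_bed(path: str) -> pd.DataFrame:
    """Half-open, 0-based target intervals (chrom, start, end)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={0: str})
    return df


def write_bed(df: pd.DataFrame, path: str) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_germline_sites(path: str) -> set[str]:
    """Germline site keys from a VCF or a TSV with chrom/pos/ref/alt columns."""
    if path.endswith(".vcf") or path.endswith(".vcf.gz"):
        df = read_bulk_vcf(path)
    else:
        df = read_tsv(path, dtype={"chrom": str})
    return {make_key(r.chrom, r.pos, r.ref, r.alt)
            for r in df.itertuples(index=False)}
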