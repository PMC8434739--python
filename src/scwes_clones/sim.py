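"""Synthetic single-cell and bulk exome data with known clonal ground truth.

The generator emulates the structure of a metastatic solid tumour profiled by
single-cell whole-exome sequencing after multiple-displacement amplification:

* a rooted clone tree whose root is an all-reference "normal" clone, with
  somatic SNVs distributed over the edges (a perfect phylogeny by
  construction), and non-root clones tagged primary or metastatic;
* per-cell, per-site read counts with negative-binomial depth heterogeneity,
  allelic dropout (a true mutant site amplifies only its reference allele)
  at rate beta = 0.2 and false-positive noise at rate alpha = 0.002, a
  standard error regime for MDA single-cell variant data;
* normal cells carrying a handful of private mutations (Poisson, default
  mean 3), mirroring the near-zero somatic burden of normal tissue;
* matched bulk samples as purity-weighted mixtures of the tumour clones.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import io as sio

__all__ = [
    "SimConfig",
    "CloneTruth",
    "rng_for",
    "simulate_clone_tree",
    "simulate_cells",
    "simulate_bulk",
    "simulate_annotations",
    "write_fixture",
    "truth_newick",
]

_BASES = np.array(list("ACGT"))

DEFAULT_WINDOWS = {
    "chr1": (10_000, 30_000_000),
    "chr2": (10_000, 30_000_000),
    "chr3": (10_000, 30_000_000),
}


def rng_for(seed: int, stage: int) -> np.random.Generator:
    """Independent, reproducible stream for a pipeline stage."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                        spawn_key=(int(stage),)))


@dataclass
class SimConfig:
    """Study conditions for the generator.

    ``ado_rate`` (beta) and ``fp_rate`` (alpha) default to 0.2 and 0.002,
    the error rates conventionally assumed for MDA single-cell tree
    inference.
    ``mean_depth`` defaults to 80x, the order of the per-cell target depth in
    high-depth single-cell exomes; ``depth_dispersion`` is the negative
    binomial shape (smaller = more MDA-like overdispersion).
    """

    n_clones: int = 4                       # including the normal root
    n_snvs: int = 200
    n_cells_per_clone: int = 15
    ado_rate: float = 0.2                   # beta: P(observe ref | true mut)
    fp_rate: float = 0.002                  # alpha: P(observe alt | true ref)
    mean_depth: float = 80.0
    depth_dispersion: float = 3.0
    het_vaf: float = 0.5                    # diploid heterozygous, no CNA
    purity: float = 1.0
    bulk_mean_depth: float = 300.0
    clone_fractions: dict | None = None     # sample -> simplex over tumour clones
    missing_rate: float = 0.1
    normal_private_rate: float = 3.0        # Poisson mean of normal-cell mutations
    cluster_fraction: float = 0.02          # SNVs planted within 10 bp of another
    lowq_cell_fraction: float = 0.0         # cells with collapsed depth (QC bait)
    lowq_depth_factor: float = 0.05
    cells_per_clone: list | None = None     # per-clone override of n_cells_per_clone
    chrom_windows: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "ado_rate": self.ado_rate, "fp_rate": self.fp_rate,
            "missing_rate": self.missing_rate, "purity": self.purity,
            "cluster_fraction": self.cluster_fraction,
            "lowq_cell_fraction": self.lowq_cell_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"sim.{name} must be in [0, 1], got {p}")
        if not 0.0 < self.het_vaf <= 1.0:
            raise ValueError(f"sim.het_vaf must be in (0, 1], got {self.het_vaf}")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ValueError("sim.mean_depth and sim.depth_dispersion must be > 0")
        if self.n_clones < 2:
            raise ValueError("sim.n_clones must be >= 2")
        if self.clone_fractions is not None:
            for sample, frac in self.clone_fractions.items():
                frac = np.asarray(frac, dtype=float)
                if abs(frac.sum() - 1.0) > 1e-9:
                    raise ValueError(
                        f"sim.clone_fractions[{sample!r}] must sum to 1")
                if (frac < 0).any():
                    raise ValueError(
                        f"sim.clone_fractions[{sample!r}] must be non-negative")
        if self.cells_per_clone is not None and \
                len(self.cells_per_clone) != self.n_clones:
            raise ValueError("sim.cells_per_clone must have n_clones entries")


@dataclass
class CloneTruth:
    """Ground-truth clonal structure: tree, SNV catalogue, clone genotypes.

    The catalogue distinguishes clonal SNVs (``clonal`` flag set; each sits
    on exactly one tree edge) from a background pool reserved for the sparse
    private mutations of normal cells; background columns are reference in
    every clone, so the perfect-phylogeny structure is unaffected.
    """

    clones: list                 # clone ids, clones[0] == "normal" (root)
    parent: dict                 # child clone -> parent clone (root absent)
    snv_catalog: pd.DataFrame    # key-indexed: chrom, pos, ref, alt, clonal
    branch_assignment: dict      # clonal snv key -> child clone of its edge
    clone_genotypes: pd.DataFrame  # clones x keys, int 0/1
    clone_labels: dict           # clone -> {normal, primary, metastatic}

    @property
    def root(self) -> str:
        return self.clones[0]

    def tumour_clones(self) -> list:
        return [c for c in self.clones if self.clone_labels[c] != "normal"]

    def clonal_keys(self) -> list:
        return list(self.snv_catalog.index[self.snv_catalog["clonal"]])


def _n_normal_cells(cfg: SimConfig) -> int:
    if cfg.cells_per_clone is not None:
        return int(cfg.cells_per_clone[0])
    return int(cfg.n_cells_per_clone)


def _background_pool_size(cfg: SimConfig) -> int:
    if cfg.normal_private_rate <= 0:
        return 0
    expect = cfg.normal_private_rate * _n_normal_cells(cfg)
    return int(math.ceil(2 * expect)) + 8


def _draw_positions(rng, cfg: SimConfig, n_background: int) -> pd.DataFrame:
    n_total = cfg.n_snvs + n_background
    chroms = list(cfg.chrom_windows)
    chrom_of = rng.choice(len(chroms), size=n_total)
    taken: dict[str, list[int]] = {c: [] for c in chroms}
    rows = []
    for i in range(n_total):
        chrom = chroms[chrom_of[i]]
        lo, hi = cfg.chrom_windows[chrom]
        while True:
            pos = int(rng.integers(lo, hi))
            if all(abs(pos - q) > 10 for q in taken[chrom]):
                break
        taken[chrom].append(pos)
        rows.append([chrom, pos])
    # plant a fraction of the clonal sites within 10 bp of another clonal
    # site to exercise the clustered-site filter downstream
    n_clustered = int(round(cfg.cluster_fraction * cfg.n_snvs))
    if n_clustered and cfg.n_snvs >= 2:
        movable = set(rng.choice(cfg.n_snvs, size=n_clustered, replace=False))
        for i in movable:
            j = int(rng.integers(cfg.n_snvs))
            while j == i or j in movable:
                j = int(rng.integers(cfg.n_snvs))
            rows[i][0] = rows[j][0]
            rows[i][1] = rows[j][1] + int(rng.integers(1, 11))
    df = pd.DataFrame(rows, columns=["chrom", "pos"])
    ref_idx = rng.integers(0, 4, size=n_total)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_total)) % 4
    df["ref"] = _BASES[ref_idx]
    df["alt"] = _BASES[alt_idx]
    df["clonal"] = np.arange(n_total) < cfg.n_snvs
    df.index = [sio.make_key(r.chrom, r.pos, r.ref, r.alt)
                for r in df.itertuples(index=False)]
    if df.index.has_duplicates:   # astronomically unlikely; redraw
        return _draw_positions(rng, cfg, n_background)
    return df


def simulate_clone_tree(config: SimConfig) -> CloneTruth:
    """Random rooted clone tree with SNVs multinomially spread over edges.

    The tree is a uniform random recursive tree: clone k attaches to a
    uniformly chosen earlier clone. Every edge receives at least one SNV.
    Non-root clones are tagged primary (first half) / metastatic (second half).
    """
    config.validate()
    n_edges = config.n_clones - 1
    if config.n_snvs < n_edges:
        raise ValueError(
            f"n_snvs={config.n_snvs} < n_edges={n_edges}: "
            "cannot give every branch a marker")
    rng = rng_for(config.seed, 1)
    clones = ["normal"] + [f"clone{i}" for i in range(1, config.n_clones)]
    parent = {clones[i]: clones[int(rng.integers(i))]
              for i in range(1, config.n_clones)}

    catalog = _draw_positions(rng, config, _background_pool_size(config))
    clonal_keys = catalog.index[catalog["clonal"].to_numpy()]

    counts = np.ones(n_edges, dtype=int)
    extra = config.n_snvs - n_edges
    if extra > 0:
        counts += rng.multinomial(extra, np.full(n_edges, 1.0 / n_edges))
    order = rng.permutation(config.n_snvs)
    branch_assignment = {}
    start = 0
    for edge_child, cnt in zip(clones[1:], counts):
        for idx in order[start:start + cnt]:
            branch_assignment[clonal_keys[idx]] = edge_child
        start += cnt

    geno = pd.DataFrame(0, index=clones, columns=catalog.index, dtype=int)
    for c in clones[1:]:
        edge_keys = [k for k, e in branch_assignment.items() if e == c]
        geno.loc[c] = geno.loc[parent[c]]
        geno.loc[c, edge_keys] = 1

    n_tumour = config.n_clones - 1
    labels = {"normal": "normal"}
    for i, c in enumerate(clones[1:]):
        labels[c] = "primary" if i < math.ceil(n_tumour / 2) else "metastatic"
    return CloneTruth(clones=clones, parent=parent, snv_catalog=catalog,
                      branch_assignment=branch_assignment,
                      clone_genotypes=geno, clone_labels=labels)


def simulate_cells(truth: CloneTruth, config: SimConfig
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell read counts and cell metadata (true clone / tissue labels).

    Returns ``(cells, cells_meta)``: a tidy read table with one row per
    cell x catalogue site (missing sites carry depth 0), and the evaluation-only
    truth labels.
    """
    if truth.snv_catalog.empty or not truth.clones:
        raise ValueError("empty clone truth")
    config.validate()
    rng = rng_for(config.seed, 2)
    n_per = (list(config.cells_per_clone) if config.cells_per_clone is not None
             else [config.n_cells_per_clone] * len(truth.clones))
    cell_ids, cell_clone = [], []
    for clone, n in zip(truth.clones, n_per):
        for i in range(int(n)):
            cell_ids.append(f"{clone}_c{i:03d}")
            cell_clone.append(clone)
    n_cells, n_snvs = len(cell_ids), len(truth.snv_catalog)

    geno = truth.clone_genotypes.loc[cell_clone].to_numpy()  # cells x snvs
    geno = geno.copy()
    # normal cells: a few private mutations, drawn from the reserved
    # background pool so they stay unique to (at most a few) cells
    pool = np.flatnonzero(~truth.snv_catalog["clonal"].to_numpy())
    if config.normal_private_rate > 0 and len(pool):
        shuffled = rng.permutation(pool)
        cursor = 0
        for i, clone in enumerate(cell_clone):
            if truth.clone_labels[clone] != "normal":
                continue
            k = int(rng.poisson(config.normal_private_rate))
            for _ in range(k):
                geno[i, shuffled[cursor % len(shuffled)]] = 1
                cursor += 1

    mean_depth = np.full(n_cells, config.mean_depth)
    if config.lowq_cell_fraction > 0:
        n_lowq = int(round(config.lowq_cell_fraction * n_cells))
        lowq = rng.choice(n_cells, size=n_lowq, replace=False)
        mean_depth[lowq] *= config.lowq_depth_factor

    r = config.depth_dispersion
    p_nb = r / (r + mean_depth)                       # mean = r(1-p)/p
    depth = rng.negative_binomial(r, p_nb[:, None], size=(n_cells, n_snvs))
    depth[rng.random((n_cells, n_snvs)) < config.missing_rate] = 0

    dropout = rng.random((n_cells, n_snvs)) < config.ado_rate
    p_alt = np.where((geno == 1) & ~dropout, config.het_vaf, config.fp_rate)
    alt = rng.binomial(depth, p_alt)

    cat = truth.snv_catalog
    cells = pd.DataFrame({
        "cell_id": np.repeat(cell_ids, n_snvs),
        "chrom": np.tile(cat["chrom"].to_numpy(), n_cells),
        "pos": np.tile(cat["pos"].to_numpy(), n_cells),
        "ref": np.tile(cat["ref"].to_numpy(), n_cells),
        "alt": np.tile(cat["alt"].to_numpy(), n_cells),
        "depth": depth.ravel(),
        "alt_depth": alt.ravel(),
    })
    meta = pd.DataFrame({
        "cell_id": cell_ids,
        "clone": cell_clone,
        "tissue": [truth.clone_labels[c] for c in cell_clone],
    })
    return cells, meta


def default_fractions(truth: CloneTruth) -> dict:
    tum = truth.tumour_clones()
    return {"T": np.full(len(tum), 1.0 / len(tum))}


def simulate_bulk(truth: CloneTruth, config: SimConfig) -> dict[str, pd.DataFrame]:
    """Bulk variant tables as purity-weighted clone mixtures, one per sample."""
    config.validate()
    rng = rng_for(config.seed, 3)
    tum = truth.tumour_clones()
    fractions = config.clone_fractions or default_fractions(truth)
    out = {}
    for sample, frac in fractions.items():
        frac = np.asarray(frac, dtype=float)
        if len(frac) != len(tum):
            raise ValueError(
                f"clone_fractions[{sample!r}] has {len(frac)} entries "
                f"for {len(tum)} tumour clones")
        g = truth.clone_genotypes.loc[tum].to_numpy()     # tumour clones x snvs
        evaf = config.purity * config.het_vaf * (frac @ g)
        r = config.depth_dispersion
        p_nb = r / (r + config.bulk_mean_depth)
        depth = rng.negative_binomial(r, p_nb, size=len(evaf))
        alt = rng.binomial(depth, evaf)
        cat = truth.snv_catalog
        df = pd.DataFrame({
            "sample_id": sample,
            "chrom": cat["chrom"].to_numpy(),
            "pos": cat["pos"].to_numpy(),
            "ref": cat["ref"].to_numpy(),
            "alt": cat["alt"].to_numpy(),
            "depth": depth,
            "alt_depth": alt,
            "expected_vaf": evaf,
        })
        df["vaf"] = df["alt_depth"] / df["depth"].where(df["depth"] > 0)
        out[sample] = df
    return out


def simulate_annotations(truth: CloneTruth, config: SimConfig,
                         snvs_per_gene: int = 3) -> pd.DataFrame:
    """Functional annotation table (gene, consequence, SIFT, PolyPhen).

    Stands in for an upstream annotator's output: catalogue SNVs are grouped
    into synthetic genes, most calls nonsynonymous, with uniform functional
    impact scores (a few missing) so that the high-risk flag has both
    outcomes to exercise.
    """
    rng = rng_for(config.seed, 4)
    keys = list(truth.snv_catalog.index)
    n_genes = math.ceil(len(keys) / snvs_per_gene)
    gene_of = np.repeat([f"GENE{i + 1:04d}" for i in range(n_genes)],
                        snvs_per_gene)[:len(keys)]
    consequence = rng.choice(["nonsynonymous", "synonymous", "other"],
                             p=[0.75, 0.20, 0.05], size=len(keys))
    sift = rng.random(len(keys))
    polyphen = rng.random(len(keys))
    sift[rng.random(len(keys)) < 0.05] = np.nan
    polyphen[rng.random(len(keys)) < 0.05] = np.nan
    return pd.DataFrame({
        "snv_key": keys, "gene": gene_of, "consequence": consequence,
        "sift_score": np.round(sift, 4), "polyphen_score": np.round(polyphen, 4),
    })


def _newick_node(truth: CloneTruth, node: str, children: dict) -> str:
    kids = children.get(node, [])
    label = node
    length = sum(1 for e in truth.branch_assignment.values() if e == node)
    suffix = label if node == truth.root else f"{label}:{length}"
    if not kids:
        return suffix
    inner = ",".join(_newick_node(truth, k, children) for k in kids)
    return f"({inner}){suffix}"


def truth_newick(truth: CloneTruth) -> str:
    children: dict[str, list] = {}
    for child, par in truth.parent.items():
        children.setdefault(par, []).append(child)
    for v in children.values():
        v.sort()
    return _newick_node(truth, truth.root, children) + ";"


def write_fixture(truth: CloneTruth, cells: pd.DataFrame, cells_meta: pd.DataFrame,
                  bulks: dict[str, pd.DataFrame], out_dir: str,
                  annotations: pd.DataFrame | None = None) -> dict[str, str]:
    """Serialise a complete synthetic dataset; round-trips through io readers."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    def _p(name):
        paths[name] = os.path.join(out_dir, name)
        return paths[name]

    sio.write_cells_tsv(cells, _p("cells.tsv"))
    sio.write_tsv(cells_meta, _p("truth_cells.tsv"))
    truth_geno = truth.clone_genotypes.copy()
    truth_geno.index.name = "clone"
    sio.write_tsv(truth_geno, _p("truth_genotypes.tsv"), index=True)
    with open(_p("truth_tree.nwk"), "w") as fh:
        fh.write(truth_newick(truth) + "\n")
    for sample, bulk in bulks.items():
        sio.write_bulk_vcf(bulk, _p(f"bulk_{sample}.vcf"), sample=sample)
    targets = pd.DataFrame(
        [(c, lo - 1, hi + 100) for c, (lo, hi) in truth_windows(truth).items()],
        columns=["chrom", "start", "end"])
    sio.write_bed(targets, _p("targets.bed"))
    if annotations is not None:
        sio.write_tsv(annotations, _p("annotations.tsv"))
    return paths


def truth_windows(truth: CloneTruth) -> dict[str, tuple[int, int]]:
    g = truth.snv_catalog.groupby("chrom")["pos"]
    return {c: (int(lo), int(hi)) for c, lo, hi in
            zip(g.min().index, g.min(), g.max())}


def noiseless(config: SimConfig) -> SimConfig:
    """The error-free, high-depth limit used by recovery tests.

    Depth must grow with the error rates going to zero: at moderate depth
    the 10-20x stratum of the consensus rule (>= 10 alt reads) hides true
    heterozygous mutations even from perfect reads.
    """
    return replace(config, ado_rate=0.0, fp_rate=0.0, missing_rate=0.0,
                   normal_private_rate=0.0, cluster_fraction=0.0,
                   mean_depth=10_000.0)
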