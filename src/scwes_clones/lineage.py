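"""Clone consensus genotypes under an error model, and the clone lineage tree.

Per clone and SNV, the consensus genotype maximises the likelihood of the
observed non-missing single-cell calls under a two-parameter error model:
alpha = P(observe mutant | true reference), the amplification false-positive
rate, and beta = P(observe reference | true mutant), the allelic dropout
rate. With k cells observed mutant and n observed reference,

    L(g=1) = k log(1 - beta) + n log(beta)
    L(g=0) = k log(alpha)    + n log(1 - alpha)

and ties resolve to reference. The clone lineage is a neighbor-joining tree
on pairwise Hamming distances between clone genotype vectors, with an
all-reference outgroup taxon as the root; per-branch acquired mutations come
from Fitch parsimony assignment of internal states (ambiguities resolved
toward reference on the downward pass).
"""

from __future__ import annotations

import io as _pyio
import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Phylo
from Bio.Phylo.BaseTree import Clade, Tree
from Bio.Phylo.TreeConstruction import DistanceMatrix as _BioDM
from Bio.Phylo.TreeConstruction import DistanceTreeConstructor
from scipy.special import xlogy

__all__ = [
    "ErrorModel",
    "CloneTree",
    "infer_clone_genotypes",
    "build_tree",
    "annotate_clone_specific_sites",
    "write_newick",
    "parse_newick",
    "tree_splits",
    "parent_map_splits",
    "robinson_foulds",
]

ROOT = "root"


@dataclass
class ErrorModel:
    alpha: float = 0.002     # false positive: observe 1 given true 0
    beta: float = 0.2        # allelic dropout: observe 0 given true 1

    def __post_init__(self):
        for name, v in (("alpha", self.alpha), ("beta", self.beta)):
            if not 0.0 <= v < 0.5:
                raise ValueError(f"{name} must be in [0, 0.5), got {v}")


def infer_clone_genotypes(m, assignment: pd.Series, em: ErrorModel | None = None
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Maximum-likelihood binary consensus genotype per clone x SNV.

    ``assignment`` maps cell id -> clone label; every clone needs at least
    one cell. Returns (genotypes, all_na_flags); SNVs with no observation in
    a clone are called reference and flagged.
    """
    em = em or ErrorModel()
    assignment = assignment.reindex(m.df.index)
    if assignment.isna().any():
        missing = list(m.df.index[assignment.isna()])
        raise ValueError(f"cells without clone assignment: {missing}")
    genos, flags = {}, {}
    for clone, cells in assignment.groupby(assignment).groups.items():
        sub = m.df.loc[list(cells)].to_numpy(dtype=float)
        if sub.shape[0] == 0:
            raise ValueError(f"clone {clone!r} has no cells")
        k = np.nansum(sub == 1.0, axis=0).astype(float)
        n = np.nansum(sub == 0.0, axis=0).astype(float)
        # xlogy handles the k=0 / n=0 corners (0 * log 0 := 0) and makes the
        # alpha=0 / beta=0 noiseless limits exact (-inf for impossible data)
        with np.errstate(divide="ignore"):
            l1 = xlogy(k, 1.0 - em.beta) + xlogy(n, em.beta)
            l0 = xlogy(k, em.alpha) + xlogy(n, 1.0 - em.alpha)
        genos[clone] = (l1 > l0).astype(int)     # ties -> reference
        flags[clone] = (k + n) == 0
    geno = pd.DataFrame(genos, index=m.df.columns).T.sort_index()
    flag = pd.DataFrame(flags, index=m.df.columns).T.sort_index()
    return geno, flag


@dataclass
class CloneTree:
    tree: Tree                         # rooted at the all-reference outgroup
    genotypes: pd.DataFrame            # taxa x SNVs, includes the root row
    node_states: dict = field(default_factory=dict)   # clade name -> 0/1 vector
    branch_sites: pd.DataFrame | None = None          # branch, snv_key (acquired)
    merged: dict = field(default_factory=dict)        # duplicate -> representative


def _hamming_matrix(geno: pd.DataFrame) -> pd.DataFrame:
    x = geno.to_numpy(dtype=float)
    d = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    return pd.DataFrame(d, index=geno.index, columns=geno.index)


def _fitch(tree: Tree, leaf_geno: pd.DataFrame) -> dict[str, np.ndarray]:
    """Binary Fitch parsimony; returns a 0/1 state vector per named node.

    Encoding: 1 = {0}, 2 = {1}, 3 = {0, 1}. Downward pass prefers the parent
    state when admissible, otherwise the smaller state (reference).
    """
    sets: dict[int, np.ndarray] = {}

    def up(clade) -> np.ndarray:
        if clade.is_terminal():
            s = np.where(leaf_geno.loc[clade.name].to_numpy() == 1, 2, 1)
        else:
            s = None
            for child in clade.clades:
                cs = up(child)
                if s is None:
                    s = cs
                else:
                    inter = s & cs
                    s = np.where(inter > 0, inter, s | cs)
        sets[id(clade)] = s
        return s

    up(tree.root)
    states: dict[str, np.ndarray] = {}

    def down(clade, parent_state):
        s = sets[id(clade)]
        if parent_state is None:
            state = np.where(s & 1, 0, 1)          # ambiguity -> reference
        else:
            pbit = np.where(parent_state == 1, 2, 1)
            state = np.where(s & pbit, parent_state, np.where(s & 1, 0, 1))
        states[clade.name] = state.astype(int)
        for child in clade.clades:
            down(child, state)

    down(tree.root, None)
    return states


def build_tree(clone_genotypes: pd.DataFrame, include_root: bool = True,
               merge_duplicates: bool = False) -> CloneTree:
    """Neighbor-joining lineage over clone genotype vectors.

    The all-reference outgroup taxon ``root`` is appended (unless present)
    and the tree is rooted on it. Duplicate genotype rows raise unless
    ``merge_duplicates``, in which case later duplicates are merged into the
    first and recorded.
    """
    geno = clone_genotypes.copy().astype(int)
    if include_root and ROOT not in geno.index:
        geno.loc[ROOT] = 0
        geno = geno.loc[[ROOT] + [i for i in geno.index if i != ROOT]]
    merged: dict[str, str] = {}
    rows = {}
    for name, row in geno.iterrows():
        key = tuple(row)
        if key in rows:
            if not merge_duplicates:
                raise ValueError(
                    f"duplicate clone genotypes: {rows[key]!r} and {name!r}")
            merged[name] = rows[key]
            warnings.warn(f"merging clone {name!r} into {rows[key]!r} "
                          "(identical genotypes)", stacklevel=2)
        else:
            rows[key] = name
    geno = geno.loc[[rows[k] for k in rows]]
    names = list(geno.index)
    if len(names) < 2:
        raise ValueError("need at least 2 distinct taxa (clones + root)")

    if len(names) == 2:
        other = [n for n in names if n != ROOT][0]
        dist = float(_hamming_matrix(geno).loc[ROOT, other])
        tree = Phylo.read(
            _pyio.StringIO(f"({ROOT}:0,{other}:{dist});"), "newick")
        tree.root_with_outgroup(ROOT)
    else:
        dm = _hamming_matrix(geno)
        lower = [[float(dm.iloc[i, j]) for j in range(i + 1)]
                 for i in range(len(names))]
        bio_dm = _BioDM(names, lower)
        tree = DistanceTreeConstructor().nj(bio_dm)
        tree.root_with_outgroup(ROOT)
        for clade in tree.find_clades():
            if clade.branch_length is not None and clade.branch_length < 0:
                clade.branch_length = 0.0

    counter = itertools.count(1)
    for clade in tree.find_clades():
        if not clade.name:
            clade.name = f"node{next(counter)}"
        clade.confidence = None

    states = _fitch(tree, geno)
    acquired = []
    keys = np.asarray(geno.columns)

    def walk(clade, parent_state):
        state = states[clade.name]
        if parent_state is not None:
            gained = keys[(parent_state == 0) & (state == 1)]
            acquired.extend((clade.name, k) for k in gained)
        for child in clade.clades:
            walk(child, state)

    walk(tree.root, None)
    branch_sites = pd.DataFrame(acquired, columns=["branch", "snv_key"])
    return CloneTree(tree=tree, genotypes=geno, node_states=states,
                     branch_sites=branch_sites, merged=merged)


def branch_hamming(ct: CloneTree) -> pd.Series:
    """Hamming distance between parent and child Fitch states per branch."""
    out = {}

    def walk(clade, parent_state):
        state = ct.node_states[clade.name]
        if parent_state is not None:
            out[clade.name] = int(np.abs(parent_state - state).sum())
        for child in clade.clades:
            walk(child, state)

    walk(ct.tree.root, None)
    return pd.Series(out, name="hamming")


def annotate_clone_specific_sites(ct: CloneTree, tissue_of: dict[str, str]
                                  ) -> pd.DataFrame:
    """Label each acquired SNV trunk / primary / metastatic / unlabeled.

    A branch whose descendant tumour clones are *all* tumour clones carries
    trunk mutations; a branch whose descendant tumour clones share a single
    tissue inherits that tissue; anything else stays unlabeled.
    """
    tumour = {c for c, t in tissue_of.items() if t not in ("normal",)}
    desc_of = {}
    for clade in ct.tree.find_clades():
        leaves = {t.name for t in clade.get_terminals()}
        desc_of[clade.name] = (leaves - {ROOT}) & tumour
    labels = {}
    for name, desc in desc_of.items():
        if desc == tumour and tumour:
            labels[name] = "trunk"
        else:
            tissues = {tissue_of[c] for c in desc}
            labels[name] = tissues.pop() if len(tissues) == 1 else "unlabeled"
    if ct.branch_sites is None or ct.branch_sites.empty:
        return pd.DataFrame(columns=["branch", "snv_key", "label"])
    out = ct.branch_sites.copy()
    out["label"] = [labels.get(b, "unlabeled") for b in out["branch"]]
    return out


def write_newick(ct: CloneTree) -> str:
    buf = _pyio.StringIO()
    Phylo.write(ct.tree, buf, "newick")
    return buf.getvalue().strip()


def parse_newick(text: str) -> Tree:
    return Phylo.read(_pyio.StringIO(text), "newick")


def tree_splits(tree: Tree, root_taxon: str = ROOT,
                collapse_tol: float = 1e-9) -> set[frozenset]:
    """Nontrivial unrooted bipartitions, each encoded as the side that does
    not contain the outgroup taxon. Internal edges of (near-)zero length are
    collapsed first, so a force-resolved polytomy contributes no split."""
    taxa = {t.name for t in tree.get_terminals()}
    n = len(taxa)
    splits = set()
    for clade in tree.find_clades():
        if clade.is_terminal():
            continue
        if clade.branch_length is not None and \
                abs(clade.branch_length) <= collapse_tol:
            continue
        side = {t.name for t in clade.get_terminals()}
        if root_taxon in side:
            side = taxa - side
        if 2 <= len(side) <= n - 2:
            splits.add(frozenset(side))
    return splits


def parent_map_splits(parent: dict[str, str], root: str,
                      taxa: set[str] | None = None) -> set[frozenset]:
    """Bipartitions induced by a clone tree given as a child -> parent map.

    Each clone is treated as a pendant leaf attached at its node; the
    outgroup side contains the root. ``taxa`` restricts to a clone subset.
    """
    nodes = set(parent) | {root}
    taxa = set(taxa) if taxa is not None else nodes - {root}
    children: dict[str, set] = {}
    for child, par in parent.items():
        children.setdefault(par, set()).add(child)

    def desc(node):
        out = {node}
        for ch in children.get(node, ()):
            out |= desc(ch)
        return out

    n = len(taxa) + 1    # + outgroup
    splits = set()
    for child in parent:
        side = frozenset(desc(child) & taxa)
        if 2 <= len(side) <= n - 2:
            splits.add(side)
    return splits


def robinson_foulds(splits_a: set[frozenset], splits_b: set[frozenset]) -> int:
    return len(splits_a ^ splits_b)
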