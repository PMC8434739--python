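"""Error-model consensus genotypes, NJ lineage reconstruction, Fitch branch
annotation and Newick round-trips."""

import io as pyio
import itertools
import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from conftest import matrix_from_values
from scwes_clones import evaluation, lineage, scgeno, sim


def _xlog(count, p):
    if count == 0:
        return 0.0
    if p == 0:
        return -math.inf
    return count * math.log(p)


def loglik(k, n, alpha, beta):
    l1 = _xlog(k, 1 - beta) + _xlog(n, beta)
    l0 = _xlog(k, alpha) + _xlog(n, 1 - alpha)
    return l1, l0


def oracle_call(k, n, alpha, beta):
    l1, l0 = loglik(k, n, alpha, beta)
    return 1 if l1 > l0 else 0


def infer_single(k, n, alpha=0.002, beta=0.2):
    values = [[1.0]] * k + [[0.0]] * n + [[None]] * 2
    m = matrix_from_values(values)
    assign = pd.Series("c", index=m.df.index)
    geno, _ = lineage.infer_clone_genotypes(
        m, assign, lineage.ErrorModel(alpha, beta))
    return int(geno.iloc[0, 0])


class TestInferCloneGenotypes:
    def test_unanimous_mutant(self):
        assert infer_single(5, 0) == 1

    def test_single_stray_mutant_called_reference(self):
        # L(1) = log 0.8 + 9 log 0.2 ~ -14.71 ; L(0) = log 0.002 + 9 log 0.998
        # ~ -6.23 -> reference
        l1, l0 = loglik(1, 9, 0.002, 0.2)
        assert l1 == pytest.approx(-14.71, abs=0.01)
        assert l0 == pytest.approx(-6.23, abs=0.01)
        assert infer_single(1, 9) == 0

    def test_dropout_tolerant_call(self):
        assert oracle_call(3, 7, 0.002, 0.2) == 1
        assert infer_single(3, 7) == 1

    def test_matches_brute_force_over_grid(self):
        for alpha, beta in [(0.002, 0.2), (0.01, 0.1), (0.05, 0.3),
                            (0.2, 0.2), (0.0, 0.2), (0.002, 0.0)]:
            em = lineage.ErrorModel(alpha, beta)
            for k, n in itertools.product(range(0, 13), range(0, 13)):
                values = [[1.0]] * k + [[0.0]] * n
                if not values:
                    continue
                m = matrix_from_values(values)
                geno, _ = lineage.infer_clone_genotypes(
                    m, pd.Series("c", index=m.df.index), em)
                assert int(geno.iloc[0, 0]) == oracle_call(k, n, alpha, beta), \
                    (k, n, alpha, beta)

    def test_equal_error_rates_reduce_to_majority(self):
        em = lineage.ErrorModel(0.1, 0.1)
        for k, n in itertools.product(range(0, 9), range(0, 9)):
            if k + n == 0:
                continue
            values = [[1.0]] * k + [[0.0]] * n
            m = matrix_from_values(values)
            geno, _ = lineage.infer_clone_genotypes(
                m, pd.Series("c", index=m.df.index), em)
            assert int(geno.iloc[0, 0]) == (1 if k > n else 0)  # ties -> 0

    def test_all_na_called_reference_and_flagged(self):
        m = matrix_from_values([[None, 1], [None, 1]])
        geno, flags = lineage.infer_clone_genotypes(
            m, pd.Series("c", index=m.df.index), lineage.ErrorModel())
        assert int(geno.iloc[0, 0]) == 0
        assert bool(flags.iloc[0, 0])
        assert not bool(flags.iloc[0, 1])

    def test_unassigned_cell_raises(self):
        m = matrix_from_values([[1], [1]])
        with pytest.raises(ValueError, match="without clone assignment"):
            lineage.infer_clone_genotypes(
                m, pd.Series({"cell0": "c"}), lineage.ErrorModel())

    def test_parameter_recovery_at_study_error_rates(self):
        cfg = sim.SimConfig(seed=15, n_clones=4, n_snvs=200,
                            n_cells_per_clone=20)
        truth = sim.simulate_clone_tree(cfg)
        cells, meta = sim.simulate_cells(truth, cfg)
        fcfg = scgeno.FilterConfig()
        kept, _ = scgeno.qc_cells(cells, fcfg,
                                  n_target_sites=len(truth.snv_catalog))
        m = scgeno.build_genotype_matrix(cells, kept, fcfg)
        m = scgeno.filter_clustered(scgeno.filter_min_cells(m))
        assign = meta.set_index("cell_id")["clone"].reindex(m.df.index)
        geno, _ = lineage.infer_clone_genotypes(m, assign,
                                                lineage.ErrorModel())
        want = truth.clone_genotypes.loc[geno.index, geno.columns]
        agree = (geno.to_numpy() == want.to_numpy()).mean()
        assert agree >= 0.99


class TestErrorModel:
    @pytest.mark.parametrize("alpha,beta", [(-0.1, 0.2), (0.5, 0.2),
                                            (0.002, 0.7)])
    def test_rates_out_of_range_raise(self, alpha, beta):
        with pytest.raises(ValueError):
            lineage.ErrorModel(alpha, beta)


def two_clone_genotypes():
    keys = [f"chr1:{1000 * (i + 1)}:A:T" for i in range(20)]
    geno = pd.DataFrame(0, index=["c1", "c2"], columns=keys, dtype=int)
    geno.loc["c1", keys[:10]] = 1           # 10 shared trunk
    geno.loc["c2", keys[:10]] = 1
    geno.loc["c1", keys[10:15]] = 1         # 5 private each
    geno.loc["c2", keys[15:20]] = 1
    return geno, keys


class TestBuildTree:
    def test_two_clones_with_trunk_exact_nj_lengths(self):
        geno, _ = two_clone_genotypes()
        ct = lineage.build_tree(geno)
        lengths = {c.name: c.branch_length
                   for c in ct.tree.find_clades() if c.branch_length}
        assert lengths["c1"] == pytest.approx(5.0)
        assert lengths["c2"] == pytest.approx(5.0)
        inner = [v for k, v in lengths.items()
                 if k not in ("c1", "c2", "root")]
        assert sum(inner) == pytest.approx(10.0)
        assert lineage.tree_splits(ct.tree) == set()   # 3 taxa: none nontrivial

    def test_trunk_sites_acquired_on_shared_branch(self):
        geno, keys = two_clone_genotypes()
        ct = lineage.build_tree(geno)
        by_branch = ct.branch_sites.groupby("branch")["snv_key"].apply(set)
        assert any(s == set(keys[:10]) for s in by_branch)  # trunk together
        assert by_branch["c1"] == set(keys[10:15])
        assert by_branch["c2"] == set(keys[15:20])

    def test_single_clone_plus_root(self):
        keys = [f"chr1:{1000 * (i + 1)}:A:T" for i in range(12)]
        geno = pd.DataFrame([[1] * 12], index=["c1"], columns=keys)
        ct = lineage.build_tree(geno)
        nwk = lineage.write_newick(ct)
        assert "c1" in nwk and "root" in nwk
        lengths = {c.name: c.branch_length
                   for c in ct.tree.find_clades() if c.branch_length}
        assert sum(lengths.values()) == pytest.approx(12.0)

    def test_duplicate_genotypes_raise_or_merge(self):
        keys = [f"chr1:{1000 * (i + 1)}:A:T" for i in range(4)]
        geno = pd.DataFrame([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]],
                            index=["a", "b", "c"], columns=keys)
        with pytest.raises(ValueError, match="duplicate"):
            lineage.build_tree(geno)
        with pytest.warns(UserWarning, match="merging"):
            ct = lineage.build_tree(geno, merge_duplicates=True)
        assert ct.merged == {"b": "a"}
        assert {t.name for t in ct.tree.get_terminals()} == {"root", "a", "c"}

    def test_nj_consistent_on_additive_perfect_phylogeny(self):
        cfg = sim.SimConfig(seed=19, n_clones=6, n_snvs=120,
                            normal_private_rate=0.0)
        truth = sim.simulate_clone_tree(cfg)
        geno = truth.clone_genotypes.drop(index="normal")
        ct = lineage.build_tree(geno.loc[:, (geno != 0).any()])
        inferred = lineage.tree_splits(ct.tree)
        expected = lineage.parent_map_splits(
            truth.parent, "normal", taxa=set(geno.index))
        assert lineage.robinson_foulds(inferred, expected) == 0

    def test_noiseless_simulation_recovery(self):
        out = evaluation.genotype_recovery(42, noiseless=True)
        assert out["agreement_pct"] == 100.0
        assert out["rf_distance"] == 0


class TestAnnotateCloneSpecificSites:
    def test_trunk_tissue_and_mixed_labels(self):
        keys = [f"chr1:{1000 * (i + 1)}:A:T" for i in range(12)]
        geno = pd.DataFrame(0, index=["p1", "m1", "m2"], columns=keys,
                            dtype=int)
        geno.loc[:, keys[:4]] = 1                   # trunk: all tumour clones
        geno.loc[["m1", "m2"], keys[4:8]] = 1       # metastatic branch
        geno.loc["m1", keys[8:10]] = 1              # private metastatic
        geno.loc["p1", keys[10:12]] = 1             # private primary
        ct = lineage.build_tree(geno)
        tissue = {"p1": "primary", "m1": "metastatic", "m2": "metastatic"}
        out = lineage.annotate_clone_specific_sites(ct, tissue).set_index(
            "snv_key")
        assert set(out.loc[keys[:4], "label"]) == {"trunk"}
        assert set(out.loc[keys[4:10], "label"]) == {"metastatic"}
        assert set(out.loc[keys[10:12], "label"]) == {"primary"}

    def test_mixed_descendants_unlabeled(self):
        keys = [f"chr1:{1000 * (i + 1)}:A:T" for i in range(9)]
        geno = pd.DataFrame(0, index=["p1", "m1", "x1"], columns=keys,
                            dtype=int)
        geno.loc[["p1", "m1"], keys[:3]] = 1    # shared by mixed-tissue pair
        geno.loc["p1", keys[3:5]] = 1
        geno.loc["m1", keys[5:7]] = 1
        geno.loc["x1", keys[7:9]] = 1
        ct = lineage.build_tree(geno)
        tissue = {"p1": "primary", "m1": "metastatic", "x1": "primary"}
        out = lineage.annotate_clone_specific_sites(ct, tissue).set_index(
            "snv_key")
        assert set(out.loc[keys[:3], "label"]) == {"unlabeled"}


class TestNewick:
    def test_round_trip_topology_and_lengths(self):
        geno, _ = two_clone_genotypes()
        ct = lineage.build_tree(geno)
        text = lineage.write_newick(ct)
        back = lineage.parse_newick(text)
        assert {t.name for t in back.get_terminals()} == \
            {t.name for t in ct.tree.get_terminals()}
        assert back.total_branch_length() == pytest.approx(
            ct.tree.total_branch_length())

    def test_parseable_by_independent_parser(self):
        geno, _ = two_clone_genotypes()
        text = lineage.write_newick(lineage.build_tree(geno))
        tree = dendropy.Tree.get(data=text, schema="newick")
        assert {t.taxon.label for t in tree.leaf_node_iter()} == \
            {"root", "c1", "c2"}


def pendant_leaf_newick(parent: dict, root: str) -> str:
    """Clone tree (clones may be internal) as a leaf tree: every clone node
    gets a zero-length pendant leaf carrying its name; the root's leaf is
    the outgroup taxon ``root``."""
    children: dict[str, list] = {}
    for child, par in parent.items():
        children.setdefault(par, []).append(child)

    def rec(node):
        leaf = "root" if node == root else node
        kids = [rec(k) for k in sorted(children.get(node, []))]
        return "(" + ",".join(kids + [f"{leaf}:0.0"]) + "):1.0"

    return rec(root)[:-4] + ";"


def test_rf_distance_matches_dendropy_on_small_case():
    """The split-based RF routine agrees with dendropy's bipartition count."""
    cfg = sim.SimConfig(seed=23, n_clones=6, n_snvs=100,
                        normal_private_rate=0.0)
    truth = sim.simulate_clone_tree(cfg)
    geno = truth.clone_genotypes.drop(index="normal")
    ct = lineage.build_tree(geno.loc[:, (geno != 0).any()])
    nwk1 = lineage.write_newick(ct)
    nwk2 = pendant_leaf_newick(truth.parent, "normal")
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=nwk1, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=nwk2, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    for e in list(t1.preorder_edge_iter()):   # collapse force-resolved edges
        if e.length is not None and e.length <= 1e-9 and \
                e.head_node.is_internal() and e.tail_node is not None:
            e.collapse()
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    dp = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
    mine = lineage.robinson_foulds(
        lineage.tree_splits(ct.tree),
        lineage.parent_map_splits(truth.parent, "normal",
                                  taxa=set(geno.index)))
    assert mine == dp


def test_rf_distance_nonzero_case_matches_dendropy():
    nwk_a = "((a:1,b:1):1,(c:1,d:1):1,root:1);"
    nwk_b = "((a:1,c:1):1,(b:1,d:1):1,root:1);"
    tns = dendropy.TaxonNamespace()
    t_a = dendropy.Tree.get(data=nwk_a, schema="newick", taxon_namespace=tns)
    t_b = dendropy.Tree.get(data=nwk_b, schema="newick", taxon_namespace=tns)
    t_a.encode_bipartitions()
    t_b.encode_bipartitions()
    dp = dendropy.calculate.treecompare.symmetric_difference(t_a, t_b)
    mine = lineage.robinson_foulds(
        lineage.tree_splits(lineage.parse_newick(nwk_a)),
        lineage.tree_splits(lineage.parse_newick(nwk_b)))
    assert mine == dp == 4
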