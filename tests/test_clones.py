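"""Missing-data-aware distances, hierarchical populations, classical MDS and
SNV co-occurrence clusters."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import matrix_from_values
from scwes_clones import clones, scgeno, sim
from scwes_clones.io import make_key


class TestPairwiseDistance:
    def test_identical_profiles_distance_zero(self):
        m = matrix_from_values([[1, 0, 1], [1, 0, 1]])
        d = clones.pairwise_cell_distance(m, min_support=1)
        assert d.d.iloc[0, 1] == 0.0

    def test_disjoint_profiles_distance_one(self):
        m = matrix_from_values([[1, 0], [0, 1]])
        d = clones.pairwise_cell_distance(m, min_support=1)
        assert d.d.iloc[0, 1] == 1.0

    def test_hand_enumerated_na_case(self):
        m = matrix_from_values([[1, 1, None], [1, 0, 1]])
        d = clones.pairwise_cell_distance(m, min_support=1)
        # co-observed sites 1,2: both-mutant 1, either-mutant 2 -> d = 0.5
        assert d.d.iloc[0, 1] == pytest.approx(0.5)
        assert d.support.iloc[0, 1] == 2

    def test_mutationless_pair_distance_zero(self):
        m = matrix_from_values([[0, 0], [0, 0], [1, 1]])
        d = clones.pairwise_cell_distance(m, min_support=1)
        assert d.d.iloc[0, 1] == 0.0

    def test_axioms_on_simulated_matrix(self, filtered_matrix):
        d = clones.pairwise_cell_distance(filtered_matrix).d.to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= 0).all() and (d <= 1).all()

    def test_triangle_inequality_on_random_instances(self):
        rng = np.random.default_rng(4)
        vals = rng.choice([0.0, 1.0], size=(12, 40))
        m = matrix_from_values(vals.tolist())
        d = clones.pairwise_cell_distance(m, min_support=1).d.to_numpy()
        for i, j, k in itertools.permutations(range(12), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_low_support_pairs_imputed_and_flagged(self):
        m = matrix_from_values([[1, None, None, None],
                                [None, 1, 0, 0],
                                [None, 1, 0, 1],
                                [None, 0, 1, 1]])
        d = clones.pairwise_cell_distance(m, min_support=2)
        assert d.imputed.iloc[0, 1]
        defined = d.d.to_numpy()[~d.imputed.to_numpy()
                                 & ~np.eye(4, dtype=bool)]
        assert d.d.iloc[0, 1] == pytest.approx(defined.mean())

    def test_cell_with_no_observations_raises(self):
        m = matrix_from_values([[None, None], [1, 0]])
        with pytest.raises(ValueError, match="no observed"):
            clones.pairwise_cell_distance(m)


def small_two_clone_matrix(n_per=6, n_snvs=12):
    rows, names = [], []
    for c in range(n_per):
        rows.append([1] * (n_snvs // 2) + [0] * (n_snvs // 2))
        names.append(f"a{c}")
    for c in range(n_per):
        rows.append([0] * (n_snvs // 2) + [1] * (n_snvs // 2))
        names.append(f"b{c}")
    return matrix_from_values(rows, cells=names)


class TestHierarchicalCluster:
    def test_two_noiseless_clones_auto_k(self):
        m = small_two_clone_matrix()
        d = clones.pairwise_cell_distance(m, min_support=1)
        labels, _ = clones.hierarchical_cluster(d, k="auto")
        assert labels.nunique() == 2
        truth = [c[0] for c in labels.index]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_one_single_cluster(self):
        m = small_two_clone_matrix()
        d = clones.pairwise_cell_distance(m, min_support=1)
        labels, _ = clones.hierarchical_cluster(d, k=1)
        assert labels.nunique() == 1

    def test_k_exceeding_cells_raises(self):
        m = small_two_clone_matrix(n_per=2)
        d = clones.pairwise_cell_distance(m, min_support=1)
        with pytest.raises(ValueError, match="exceeds"):
            clones.hierarchical_cluster(d, k=10)

    def test_three_tissue_populations_recovered(self):
        # normal + one primary + one metastatic clone; auto-k must find the
        # three populations, each dominated by a single tissue
        cfg = sim.SimConfig(seed=21, n_clones=3, n_snvs=150,
                            n_cells_per_clone=15)
        truth = sim.simulate_clone_tree(cfg)
        cells, meta = sim.simulate_cells(truth, cfg)
        fcfg = scgeno.FilterConfig()
        kept, _ = scgeno.qc_cells(cells, fcfg,
                                  n_target_sites=len(truth.snv_catalog))
        m = scgeno.build_genotype_matrix(cells, kept, fcfg)
        m = scgeno.filter_clustered(scgeno.filter_min_cells(m))
        d = clones.pairwise_cell_distance(m)
        labels, _ = clones.hierarchical_cluster(d, k="auto")
        assert labels.nunique() == 3
        tissues = meta.set_index("cell_id")["tissue"]
        comp = clones.tissue_composition(labels, tissues)
        purity = comp.max(axis=1) / comp.sum(axis=1)
        assert (purity >= 0.9).all()

    def test_label_invariance_under_cell_permutation(self, filtered_matrix):
        d = clones.pairwise_cell_distance(filtered_matrix)
        labels, _ = clones.hierarchical_cluster(d, k=4)
        rng = np.random.default_rng(1)
        perm = rng.permutation(filtered_matrix.df.index.to_numpy())
        m2 = scgeno.GenotypeMatrix(filtered_matrix.df.loc[perm])
        d2 = clones.pairwise_cell_distance(m2)
        labels2, _ = clones.hierarchical_cluster(d2, k=4)
        joint = pd.DataFrame({"a": labels, "b": labels2.reindex(labels.index)})
        assert adjusted_rand_score(joint["a"], joint["b"]) == 1.0


class TestClassicalMds:
    def test_equilateral_triangle(self):
        d = pd.DataFrame(1.0 - np.eye(3), index=list("abc"),
                         columns=list("abc"))
        coords = clones.classical_mds(d, dims=2).to_numpy()
        dists = [np.linalg.norm(coords[i] - coords[j])
                 for i, j in [(0, 1), (0, 2), (1, 2)]]
        assert np.allclose(dists, dists[0])

    def test_exact_on_euclidean_distances(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(8, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        d = pd.DataFrame(d, index=range(8), columns=range(8))
        coords = clones.classical_mds(d, dims=2).to_numpy()
        back = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        assert np.allclose(back, d.to_numpy(), atol=1e-9)

    def test_duplicate_points_identical_coordinates(self):
        m = matrix_from_values([[1, 0, 1], [1, 0, 1], [0, 1, 0], [0, 1, 1]])
        d = clones.pairwise_cell_distance(m, min_support=1)
        coords = clones.classical_mds(d)
        assert np.allclose(coords.iloc[0], coords.iloc[1])

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        d = pd.DataFrame(d)
        c1 = clones.classical_mds(d)
        c2 = clones.classical_mds(d.copy())
        pd.testing.assert_frame_equal(c1, c2)
        for axis in c1.columns:
            col = c1[axis].to_numpy()
            assert col[np.argmax(np.abs(col))] >= 0

    def test_warns_on_strongly_non_euclidean_input(self):
        d = 1.0 - np.eye(4)
        d[0, 1] = d[1, 0] = 3.0      # triangle violation -> indefinite B
        with pytest.warns(UserWarning, match="Euclidean"):
            clones.classical_mds(pd.DataFrame(d))


def star_truth(n_tumour=4, snvs_per_edge=12) -> sim.CloneTruth:
    """Constructed star phylogeny: every tumour clone hangs off the root."""
    clones_ = ["normal"] + [f"clone{i}" for i in range(1, n_tumour + 1)]
    parent = {c: "normal" for c in clones_[1:]}
    keys, assignment = [], {}
    for i, c in enumerate(clones_[1:]):
        for j in range(snvs_per_edge):
            key = make_key("chr1", 10_000 * (i * snvs_per_edge + j + 1),
                           "A", "T")
            keys.append(key)
            assignment[key] = c
    catalog = pd.DataFrame(
        [(k.split(":")[0], int(k.split(":")[1]), "A", "T", True)
         for k in keys],
        columns=["chrom", "pos", "ref", "alt", "clonal"], index=keys)
    geno = pd.DataFrame(0, index=clones_, columns=keys, dtype=int)
    for k, c in assignment.items():
        geno.loc[c, k] = 1
    labels = {"normal": "normal"}
    for i, c in enumerate(clones_[1:]):
        labels[c] = "primary" if i < 2 else "metastatic"
    return sim.CloneTruth(clones=clones_, parent=parent, snv_catalog=catalog,
                          branch_assignment=assignment, clone_genotypes=geno,
                          clone_labels=labels)


class TestClusterSnvs:
    def test_identical_presence_sets_share_cluster(self):
        m = matrix_from_values([[1, 1, 0], [1, 1, 0], [1, 1, 0], [0, 0, 1],
                                [0, 0, 1], [0, 0, 1]])
        out = clones.cluster_snvs(m, k=2, min_support=1)
        by_key = out.set_index("snv_key")["snv_cluster"]
        assert by_key.iloc[0] == by_key.iloc[1] != by_key.iloc[2]

    def test_fewer_than_two_snvs_raises(self):
        m = matrix_from_values([[1], [1]])
        with pytest.raises(ValueError, match="2 SNVs"):
            clones.cluster_snvs(m)

    def test_recovers_branch_structure_of_star_truth(self):
        truth = star_truth()
        cfg = sim.SimConfig(seed=17, n_clones=5, n_snvs=48,
                            n_cells_per_clone=15, normal_private_rate=0.0)
        cells, _ = sim.simulate_cells(truth, cfg)
        fcfg = scgeno.FilterConfig()
        kept, _ = scgeno.qc_cells(cells, fcfg,
                                  n_target_sites=len(truth.snv_catalog))
        m = scgeno.build_genotype_matrix(cells, kept, fcfg)
        m = scgeno.filter_min_cells(m)
        out = clones.cluster_snvs(m, k="auto")
        assert out["snv_cluster"].nunique() == 4
        branch = [truth.branch_assignment[k] for k in out["snv_key"]]
        assert adjusted_rand_score(branch, out["snv_cluster"]) >= 0.9

    def test_trunk_cluster_prevalence_spans_all_tumour_cells(self):
        # chain truth: a trunk edge shared by both tumour clones
        keys = [make_key("chr1", 1000 * (i + 1), "A", "T") for i in range(12)]
        trunk, private = keys[:6], keys[6:]
        rows = []
        for _ in range(10):       # clone A: trunk only
            rows.append([1] * 6 + [0] * 6)
        for _ in range(10):       # clone B: trunk + private
            rows.append([1] * 12)
        for _ in range(5):        # normal cells
            rows.append([0] * 12)
        m = matrix_from_values(rows, snvs=keys)
        out = clones.cluster_snvs(m, k=2, min_support=1).set_index("snv_key")
        trunk_clusters = out.loc[trunk, "snv_cluster"].unique()
        assert len(trunk_clusters) == 1
        row = out.loc[trunk[0]]
        assert row["cluster_prevalence_min"] == pytest.approx(100 * 20 / 25)
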