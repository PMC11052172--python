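import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from enteroassembly import simulate as sim
from enteroassembly.io import AsvTable, read_tree
from enteroassembly.nullmodels import (CommunityAssemblyModel, beta_mntd,
                                       beta_nti, classify_pair, env_distance,
                                       mantel, partition_processes,
                                       raup_crick_bray, _null_community)


def _rel(df):
    return AsvTable(df.div(df.sum(axis=1), axis=0))


class TestBetaMntd:
    def test_identical_communities_zero(self, newick_three_taxa):
        tree = read_tree(newick_three_taxa)
        df = pd.DataFrame([[0.3, 0.3, 0.4]] * 2, index=["s1", "s2"],
                          columns=["A", "B", "C"])
        assert beta_mntd(_rel(df), tree).iloc[0, 1] == pytest.approx(0.0)

    def test_hand_computed_example(self, newick_three_taxa):
        # s1 = {A: .5, B: .5}, s2 = {C: 1}; every nearest-taxon distance is 4
        tree = read_tree(newick_three_taxa)
        df = pd.DataFrame([[0.5, 0.5, 0.0], [0.0, 0.0, 1.0]],
                          index=["s1", "s2"], columns=["A", "B", "C"])
        assert beta_mntd(_rel(df), tree).iloc[0, 1] == pytest.approx(4.0)

    def test_branch_length_scaling_is_linear(self):
        tree1 = read_tree("((A:1,B:1):1,C:2);")
        tree3 = read_tree("((A:3,B:3):3,C:6);")
        df = pd.DataFrame([[0.7, 0.3, 0.0], [0.1, 0.0, 0.9]],
                          index=["s1", "s2"], columns=["A", "B", "C"])
        v1 = beta_mntd(_rel(df), tree1).iloc[0, 1]
        v3 = beta_mntd(_rel(df), tree3).iloc[0, 1]
        assert v3 == pytest.approx(3 * v1)

    def test_taxon_missing_from_tree_rejected(self, newick_three_taxa):
        tree = read_tree(newick_three_taxa)
        df = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["s1", "s2"],
                          columns=["A", "Z"])
        with pytest.raises(KeyError):
            beta_mntd(_rel(df), tree)


class TestBetaNti:
    def test_seed_determinism_bitwise(self):
        table, _ = sim.simulate_neutral(8, 60, 1000, Nm=500.0, seed=0)
        tree = sim.simulate_tree(60, seed=1)
        a = beta_nti(table, tree, n_rand=49, seed=5)
        b = beta_nti(table, tree, n_rand=49, seed=5)
        assert a.equals(b)

    def test_branch_scaling_invariance_with_shared_seed(self):
        table, _ = sim.simulate_neutral(8, 60, 1000, Nm=500.0, seed=0)
        tree = sim.simulate_tree(60, seed=1)
        from enteroassembly.io import patristic_distance_matrix
        D = patristic_distance_matrix(tree, table.taxon_ids)
        a = beta_nti(table, D, n_rand=49, seed=5)
        b = beta_nti(table, D * 7.0, n_rand=49, seed=5)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_signal_free_data_standard_normal_null(self):
        pooled = []
        for seed in range(2):
            table, _ = sim.simulate_neutral(16, 150, 3000, Nm=1000.0, seed=seed)
            tree = sim.simulate_tree(150, seed + 100)  # independent of abundances
            z = beta_nti(table, tree, n_rand=99, seed=seed).to_numpy()
            pooled.append(z[np.triu_indices(16, 1)])
        pooled = np.concatenate(pooled)
        assert abs(pooled.mean()) < 0.3
        assert 0.7 <= pooled.std() <= 1.3

    def test_symmetry_and_zero_diagonal(self):
        table, _ = sim.simulate_neutral(6, 40, 500, Nm=200.0, seed=3)
        tree = sim.simulate_tree(40, seed=4)
        z = beta_nti(table, tree, n_rand=29, seed=0).to_numpy()
        np.testing.assert_allclose(z, z.T)
        np.testing.assert_allclose(np.diag(z), 0)


class TestRaupCrick:
    def test_identical_samples_score_minus_one(self):
        row = [50, 30, 10, 5, 5]
        df = pd.DataFrame([row, row], index=["s1", "s2"], columns=list("abcde"))
        rc = raup_crick_bray(AsvTable(df), n_rand=199, seed=0)
        assert rc.iloc[0, 1] <= -0.9

    def test_null_process_data_centered(self):
        # observed communities drawn by the RC null process itself ->
        # RC approximately uniform on [-1, 1], centered at 0
        rng = np.random.default_rng(0)
        t = 80
        occ_w = rng.random(t) + 0.05
        ab_w = rng.dirichlet(np.ones(t) * 0.3)
        vals = []
        for seed in range(3):
            rng2 = np.random.default_rng(seed + 10)
            x = np.array([_null_community(rng2, 30, 500, occ_w, ab_w)
                          for _ in range(12)])
            table = AsvTable(pd.DataFrame(x, index=[f"s{i}" for i in range(12)],
                                          columns=[f"t{j}" for j in range(t)]))
            rc = raup_crick_bray(table, n_rand=99, seed=seed)
            vals.append(rc.to_numpy()[np.triu_indices(12, 1)])
        vals = np.concatenate(vals)
        assert abs(vals.mean()) < 0.3

    def test_bounds_and_symmetry(self):
        table, _ = sim.simulate_neutral(8, 60, 800, Nm=300.0, seed=1)
        rc = raup_crick_bray(table, n_rand=49, seed=2).to_numpy()
        assert (np.abs(rc) <= 1).all()
        np.testing.assert_allclose(rc, rc.T)

    def test_null_preserves_richness_and_total(self):
        rng = np.random.default_rng(5)
        occ_w = rng.random(40) + 0.01
        ab_w = rng.dirichlet(np.ones(40))
        null = _null_community(rng, richness=12, total=300, occ_w=occ_w, ab_w=ab_w)
        assert (null > 0).sum() == 12
        assert null.sum() == 300

    def test_zero_richness_sample_rejected(self):
        df = pd.DataFrame([[0, 0], [1, 2]], index=["s1", "s2"], columns=["a", "b"])
        with pytest.raises(ValueError, match="s1"):
            raup_crick_bray(AsvTable(df))


class TestPartition:
    @pytest.mark.parametrize("bnti, rc, expected", [
        (-2.5, 0.1, "homogeneous_selection"),
        (2.5, 0.1, "variable_selection"),
        (0.5, 0.2, "drift"),
        (0.5, -0.99, "homogenizing_dispersal"),
        (0.5, 0.99, "dispersal_limitation"),
        (2.0, 0.99, "dispersal_limitation"),   # |bNTI| <= 2 inclusive
        (-2.0, -0.99, "homogenizing_dispersal"),
    ])
    def test_classification_rules(self, bnti, rc, expected):
        assert classify_pair(bnti, rc) == expected

    def test_every_pair_labeled_and_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        n = 10
        ids = [f"s{i}" for i in range(n)]
        z = rng.normal(0, 3, (n, n))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        rc = np.clip((rng.random((n, n)) - 0.5) * 2, -1, 1)
        rc = (rc + rc.T) / 2
        np.fill_diagonal(rc, 0)
        pairs, part = partition_processes(pd.DataFrame(z, ids, ids),
                                          pd.DataFrame(rc, ids, ids))
        assert len(pairs) == n * (n - 1) // 2
        assert sum(part.fractions.values()) == pytest.approx(1.0, abs=1e-12)
        assert sum(part.counts.values()) == part.n_pairs

    def test_label_mismatch_rejected(self):
        a = pd.DataFrame(np.zeros((3, 3)), list("abc"), list("abc"))
        b = pd.DataFrame(np.zeros((3, 3)), list("abd"), list("abd"))
        with pytest.raises(ValueError):
            partition_processes(a, b)


class TestMantel:
    def _random_dm(self, rng, n=20):
        pts = rng.random((n, 3))
        ids = [f"s{i}" for i in range(n)]
        return pd.DataFrame(squareform(pdist(pts)), index=ids, columns=ids)

    def test_self_correlation_r_one_minimal_p(self):
        rng = np.random.default_rng(0)
        a = self._random_dm(rng)
        res = mantel(a, a, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_affine_invariance_pearson(self):
        rng = np.random.default_rng(1)
        a = self._random_dm(rng)
        b = 2 * a + 3
        np.fill_diagonal(b.values, 0)
        assert mantel(a, b, n_perm=99, seed=0).statistic == pytest.approx(1.0)

    def test_matches_skbio_statistic(self):
        import skbio.stats.distance as sksd
        from skbio import DistanceMatrix

        rng = np.random.default_rng(2)
        a, b = self._random_dm(rng), self._random_dm(rng)
        ours = mantel(a, b, n_perm=9, seed=0).statistic
        theirs = float(sksd.mantel(DistanceMatrix(a.values, list(a.index)),
                                   DistanceMatrix(b.values, list(b.index)),
                                   permutations=0)[0])
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_spearman_method_rank_invariance(self):
        rng = np.random.default_rng(3)
        a = self._random_dm(rng)
        b = a ** 3  # monotone transform
        np.fill_diagonal(b.values, 0)
        assert mantel(a, b, method="spearman", n_perm=9,
                      seed=0).statistic == pytest.approx(1.0)

    def test_label_mismatch_and_small_n_rejected(self):
        rng = np.random.default_rng(4)
        a = self._random_dm(rng)
        b = self._random_dm(rng)
        b.index = b.columns = [f"x{i}" for i in range(20)]
        with pytest.raises(ValueError):
            mantel(a, b)
        with pytest.raises(ValueError):
            mantel(a.iloc[:3, :3], a.iloc[:3, :3])


class TestEnvDistance:
    def test_altitude_example(self):
        meta = pd.DataFrame({"altitude": [120.0, 120.0, 838.0]},
                            index=["s1", "s2", "s3"])
        d = env_distance(meta, "altitude")
        assert d.loc["s1", "s2"] == 0
        assert d.loc["s1", "s3"] == pytest.approx(718.0)

    def test_constant_column_all_zero(self):
        meta = pd.DataFrame({"bmi": [1.0] * 4}, index=list("abcd"))
        assert (env_distance(meta, "bmi").to_numpy() == 0).all()

    def test_scaling(self):
        rng = np.random.default_rng(0)
        meta = pd.DataFrame({"v": rng.random(5)}, index=list("abcde"))
        np.testing.assert_allclose(env_distance(meta * 3, "v"),
                                   3 * env_distance(meta, "v"))

    def test_missing_value_listed(self):
        meta = pd.DataFrame({"v": [1.0, np.nan]}, index=["s1", "s2"])
        with pytest.raises(ValueError, match="s2"):
            env_distance(meta, "v")


class TestAssemblyModel:
    def test_end_to_end_neutral_is_mostly_stochastic(self):
        table, _ = sim.simulate_neutral(12, 150, 2000, Nm=1000.0, seed=0)
        tree = sim.simulate_tree(150, seed=50)
        res = CommunityAssemblyModel(table, tree).fit(n_rand=99, seed=0)
        f = res.partition.fractions
        stochastic = (f["drift"] + f["dispersal_limitation"]
                      + f["homogenizing_dispersal"])
        assert stochastic >= 0.6
        assert "Assembly process partition" in res.summary()
        assert len(res.pairs) == 12 * 11 // 2
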