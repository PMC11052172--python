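import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from enteroassembly.diversity import (anosim, benjamini_hochberg, bray_curtis,
                                      compare_taxa, pcoa, rank_sum_test,
                                      shannon, simpson)
from enteroassembly.io import AsvTable


class TestAlphaDiversity:
    @pytest.mark.parametrize("counts, expected", [
        (np.ones(10), np.log(10)),
        ((7, 0, 0), 0.0),
        ((1, 1, 2), 1.5 * np.log(2)),
    ])
    def test_shannon_closed_forms(self, counts, expected):
        assert shannon(counts) == pytest.approx(expected)

    @pytest.mark.parametrize("counts, expected", [
        ((5,), 0.0),
        ((3, 3), 0.5),
        ((1, 1, 2), 0.625),
    ])
    def test_simpson_closed_forms(self, counts, expected):
        assert simpson(counts) == pytest.approx(expected)

    def test_shannon_bounded_by_log_richness(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(1, 50, size=rng.integers(2, 20))
            assert shannon(x) <= np.log(len(x)) + 1e-12

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0])
        with pytest.raises(ValueError):
            simpson([0, 0])

    def test_inverse_simpson_flag(self):
        assert simpson((3, 3), inverse=True) == pytest.approx(2.0)


class TestBrayCurtis:
    def test_closed_forms(self):
        t = AsvTable(pd.DataFrame([[6, 2], [2, 2], [6, 2], [0, 5]],
                                  index=list("wxyz"), columns=["a", "b"]))
        dm = bray_curtis(t)
        assert dm["w", "x"] == pytest.approx(1 / 3)
        assert dm["w", "y"] == 0.0
        # disjoint support: w has mass only where z has none after removing b?
        t2 = AsvTable(pd.DataFrame([[3, 0], [0, 7]], index=["u", "v"],
                                   columns=["a", "b"]))
        assert bray_curtis(t2)["u", "v"] == pytest.approx(1.0)

    def test_range_and_symmetry_random_tables(self):
        rng = np.random.default_rng(1)
        t = AsvTable(pd.DataFrame(rng.integers(0, 50, (10, 8)) + 1))
        d = bray_curtis(t).data
        assert np.allclose(d, d.T)
        assert (d >= 0).all() and (d <= 1).all()
        assert np.allclose(np.diag(d), 0)


class TestPcoa:
    def test_collinear_points_single_axis(self):
        d = np.abs(np.subtract.outer([0.0, 1.0, 2.0], [0.0, 1.0, 2.0]))
        res = pcoa(DistanceMatrix(d, ids=list("abc")))
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(15, 4))
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix(d, ids=[str(i) for i in range(15)]))
        coords = res.coordinates.to_numpy()[:, res.eigenvalues > 1e-12]
        np.testing.assert_allclose(squareform(pdist(coords)), d, atol=1e-9)

    def test_duplicate_samples_identical_coordinates(self):
        pts = np.array([[0.0, 0], [0, 0], [3, 4]])
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix(d, ids=list("abc")))
        np.testing.assert_allclose(res.coordinates.loc["a"], res.coordinates.loc["b"],
                                   atol=1e-12)


class TestAnosim:
    def test_perfect_separation_gives_r_one(self, two_blob_distance):
        dm, labels = two_blob_distance
        res = anosim(dm, labels, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_matches_skbio_statistic(self, two_blob_distance):
        import skbio.stats.distance as sksd

        dm, labels = two_blob_distance
        ours = anosim(dm, labels, n_perm=9, seed=0).statistic
        theirs = float(sksd.anosim(dm, grouping=labels,
                                   permutations=0)["test statistic"])
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_seed_determinism(self, two_blob_distance):
        dm, labels = two_blob_distance
        a = anosim(dm, labels, n_perm=199, seed=11)
        b = anosim(dm, labels, n_perm=199, seed=11)
        assert a.p_value == b.p_value

    def test_rank_invariance_to_monotone_transform(self, two_blob_distance):
        dm, labels = two_blob_distance
        transformed = DistanceMatrix(np.sqrt(dm.data), ids=dm.ids)
        assert anosim(dm, labels, n_perm=9, seed=0).statistic == pytest.approx(
            anosim(transformed, labels, n_perm=9, seed=0).statistic)

    def test_singleton_group_rejected(self, two_blob_distance):
        dm, _ = two_blob_distance
        with pytest.raises(ValueError, match="singleton"):
            anosim(dm, np.array([0] + [1] * 11), n_perm=9, seed=0)

    def test_null_calibration(self):
        # random labels vs distances: rejection rate near alpha
        rng = np.random.default_rng(8)
        rejections = 0
        reps = 200
        for rep in range(reps):
            pts = rng.normal(size=(16, 3))
            dm = DistanceMatrix(squareform(pdist(pts)),
                                ids=[str(i) for i in range(16)])
            labels = rng.permutation([0] * 8 + [1] * 8)
            if anosim(dm, labels, n_perm=99, seed=rep).p_value <= 0.05:
                rejections += 1
        assert abs(rejections / reps - 0.05) < 0.05


class TestRankSum:
    def test_identical_multisets_exact_p_one(self):
        res = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_enumerated_example(self):
        # all 20 assignments of {1..6} into two triples: U=0 has one-sided
        # probability 1/20, two-sided p = 0.1
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)

    def test_symmetry(self):
        a = rank_sum_test([1, 5, 9, 11], [2, 3, 4, 8])
        b = rank_sum_test([2, 3, 4, 8], [1, 5, 9, 11])
        assert a.p_value == pytest.approx(b.p_value)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1, 2])

    def test_large_sample_branch_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(0.5, 1, size=25)
        ours = rank_sum_test(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert ours.p_value == pytest.approx(ref.pvalue)


class TestCompareTaxa:
    def test_bh_closed_form(self):
        np.testing.assert_allclose(benjamini_hochberg([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_identical_taxon_adjusted_p_one(self):
        rng = np.random.default_rng(0)
        rest = rng.dirichlet(np.ones(2), size=12) * 0.8
        x = np.column_stack([np.full(12, 0.2), rest])  # constant first taxon
        t = AsvTable(pd.DataFrame(x, index=[f"s{i}" for i in range(12)],
                                  columns=["const", "b", "c"]))
        labels = pd.Series([0] * 6 + [1] * 6, index=t.sample_ids)
        out = compare_taxa(t, labels)
        assert out.loc["const", "q_value"] == pytest.approx(1.0)

    def test_injected_enrichment_detected(self):
        from enteroassembly import simulate as sim
        from enteroassembly.io import relative_abundance

        detected = 0
        for seed in range(5):
            table, truth = sim.simulate_enterotype_mixture(60, 100, 5000, seed=seed)
            rel = relative_abundance(table)
            out = compare_taxa(rel, truth.labels, fdr_alpha=0.05)
            # t0001 is the dominance-block taxon boosted in cluster 0
            row = out.loc["t0001"]
            detected += bool(row["significant"] and row["enriched_in"] == "0")
        assert detected >= 4
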