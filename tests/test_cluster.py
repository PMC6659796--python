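"""Clustering stage: variance filter, scaling, UPGMA, gap statistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from kinarray import cluster as cl
from kinarray.datatypes import PeptideMatrix, ValidationError
from oracles import upgma_oracle


def _matrix(values: np.ndarray, stage="collapsed") -> PeptideMatrix:
    n_p, n_s = values.shape
    return PeptideMatrix(
        data=pd.DataFrame(
            values,
            index=pd.Index([f"p{i}" for i in range(n_p)], name="peptide_id"),
            columns=[f"s{i}" for i in range(n_s)],
        ),
        stage=stage,
    )


class TestVarianceFilter:
    def test_toy_sd_ratios(self, rng):
        # per-peptide sds approximately 10, 2, 1.6, 0.1
        sds = [10.0, 2.0, 1.6, 0.1]
        vals = np.array([rng.normal(0, s, 200) for s in sds])
        out = cl.variance_filter(_matrix(np.abs(vals)), threshold=0.15)
        assert list(out.data.index) == ["p0", "p1", "p2"]

    def test_max_sd_peptide_always_retained(self, rng):
        vals = np.abs(rng.normal(0, 1, (30, 40)))
        m = _matrix(vals)
        top = m.data.std(axis=1, ddof=1).idxmax()
        for thr in (0.0, 0.5, 1.0):
            assert top in cl.variance_filter(m, threshold=thr).data.index

    def test_zero_threshold_keeps_all(self, rng):
        m = _matrix(np.abs(rng.normal(size=(10, 8))))
        assert cl.variance_filter(m, threshold=0.0).data.shape == m.data.shape

    def test_retention_monotone_in_threshold(self, rng):
        m = _matrix(np.abs(rng.normal(size=(50, 20))))
        sizes = [len(cl.variance_filter(m, t).data) for t in (0.0, 0.15, 0.25, 0.6)]
        assert sizes == sorted(sizes, reverse=True)

    def test_all_constant_matrix_is_error(self):
        m = _matrix(np.ones((5, 6)))
        with pytest.raises(ValidationError, match="sigma_max"):
            cl.variance_filter(m)

    def test_stricter_threshold_keeps_fewer_peptides_on_cohort(self, preprocessed):
        collapsed, _ = preprocessed
        n_015 = len(cl.variance_filter(collapsed, 0.15).data)
        n_025 = len(cl.variance_filter(collapsed, 0.25).data)
        assert n_025 < n_015


class TestScaleFeatures:
    def test_rows_are_zero_mean_unit_sd(self, rng):
        m = _matrix(np.abs(rng.lognormal(size=(12, 9))), stage="filtered")
        out = cl.scale_features(m)
        np.testing.assert_allclose(out.data.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.data.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_no_log_preserves_ranks(self, rng):
        vals = np.abs(rng.normal(size=(6, 7)))
        out = cl.scale_features(_matrix(vals, stage="filtered"), log_transform=False)
        for i in range(6):
            assert (np.argsort(out.data.iloc[i]) == np.argsort(vals[i])).all()

    def test_scaling_twice_is_idempotent(self, rng):
        m = _matrix(np.abs(rng.lognormal(size=(10, 15))), stage="filtered")
        once = cl.scale_features(m, log_transform=False)
        twice = cl.scale_features(once, log_transform=False)
        np.testing.assert_allclose(once.data.to_numpy(), twice.data.to_numpy(), atol=1e-12)

    def test_zero_variance_rows_dropped_with_warning(self, caplog):
        vals = np.vstack([np.ones(5), np.arange(5.0)])
        with caplog.at_level("WARNING"):
            out = cl.scale_features(_matrix(vals, stage="filtered"), log_transform=False)
        assert len(out.data) == 1


class TestHierarchicalCluster:
    def test_three_collinear_points_hand_merges(self):
        x = np.array([[0.0], [1.0], [10.0]])
        z = cl.hierarchical_cluster(x)
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}
        assert z[0, 2] == pytest.approx(1.0)
        assert z[1, 2] == pytest.approx((9.0 + 10.0) / 2)

    def test_duplicate_sample_merges_first_at_zero(self, rng):
        pts = rng.normal(size=(5, 3))
        pts[3] = pts[1]
        z = cl.hierarchical_cluster(pts)
        assert z[0, 2] == pytest.approx(0.0)
        assert {int(z[0, 0]), int(z[0, 1])} == {1, 3}

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_matches_brute_force_upgma_oracle(self, n, rng):
        for _ in range(6):
            pts = rng.normal(size=(n, 3))
            z = cl.hierarchical_cluster(pts)
            expected = upgma_oracle(pts)
            for row, (a, b, d, size) in zip(z, expected):
                assert {int(row[0]), int(row[1])} == {a, b}
                assert row[2] == pytest.approx(d)
                assert int(row[3]) == size


class TestCutTree:
    def test_extreme_k_values(self, rng):
        pts = rng.normal(size=(6, 2))
        z = cl.hierarchical_cluster(pts)
        assert (cl.cut_tree(z, 1) == 1).all()
        assert sorted(cl.cut_tree(z, 6)) == [1, 2, 3, 4, 5, 6]

    def test_labels_partition_and_first_member_numbering(self, rng):
        pts = rng.normal(size=(9, 2))
        z = cl.hierarchical_cluster(pts)
        for k in range(1, 10):
            labels = cl.cut_tree(z, k)
            assert len(np.unique(labels)) == k
            firsts = [np.argmax(labels == c) for c in range(1, k + 1)]
            assert firsts == sorted(firsts)

    def test_out_of_range_k_is_error(self, rng):
        z = cl.hierarchical_cluster(rng.normal(size=(4, 2)))
        with pytest.raises(ValidationError, match="out of range"):
            cl.cut_tree(z, 5)


class TestWithinDispersion:
    def test_singletons_give_zero(self, rng):
        pts = rng.normal(size=(5, 2))
        assert cl.within_dispersion(pts, np.arange(5)) == pytest.approx(0.0)

    def test_pair_closed_form(self):
        pts = np.array([[0.0, 0.0], [3.0, 4.0]])  # distance 5
        assert cl.within_dispersion(pts, np.array([1, 1])) == pytest.approx(25.0 / 2)

    def test_equals_pairwise_distance_formula(self, rng):
        pts = rng.normal(size=(20, 4))
        labels = rng.integers(0, 3, size=20)
        expected = 0.0
        for c in np.unique(labels):
            sub = pts[labels == c]
            d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1)
            # D_r = d2.sum() already counts each unordered pair twice
            expected += d2.sum() / (2 * len(sub))
        assert cl.within_dispersion(pts, labels) == pytest.approx(expected)

    @given(st.integers(0, 10))
    def test_nested_partitions_never_increase_dispersion(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(12, 3))
        z = cl.hierarchical_cluster(pts)
        w = [cl.within_dispersion(pts, cl.cut_tree(z, k)) for k in range(1, 12)]
        assert all(w[i] >= w[i + 1] - 1e-9 for i in range(len(w) - 1))


class TestGapStatistic:
    def test_two_separated_blobs_select_two(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            blob1 = rng.normal(0.0, 1.0, size=(20, 2))
            blob2 = rng.normal(10.0, 1.0, size=(20, 2))
            pts = np.vstack([blob1, blob2])
            k_hat, _, _, _ = cl.gap_statistic(pts, k_max=5, B=50, seed=seed)
            hits += k_hat == 2
        assert hits >= 0.95 * 50

    def test_single_blob_selects_one(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            pts = rng.normal(size=(40, 2))
            k_hat, _, _, _ = cl.gap_statistic(pts, k_max=5, B=50, seed=seed)
            hits += k_hat == 1
        assert hits >= 0.80 * 50

    def test_curve_shapes_and_positive_spread(self, rng):
        pts = rng.normal(size=(15, 3))
        k_hat, gap, s, log_w = cl.gap_statistic(pts, k_max=6, B=30, seed=0)
        assert len(gap) == len(s) == len(log_w) == 6
        assert (s > 0).all()
        assert 1 <= k_hat <= 6

    def test_too_few_samples_is_error(self):
        with pytest.raises(ValidationError):
            cl.gap_statistic(np.zeros((2, 3)), k_max=1)


class TestRunClustering:
    def test_default_cohort_recovers_two_clusters(self, cluster_outcome, default_cohort):
        _, _, _, truth = default_cohort
        assert cluster_outcome.k_hat == 2
        labels = cluster_outcome.labels_at()
        truth_labels = pd.Series(truth.labels).loc[labels.index]
        assert adjusted_rand_score(truth_labels, labels) >= 0.9

    def test_sample_permutation_permutes_labels(self, preprocessed):
        collapsed, _ = preprocessed
        groups = collapsed.sample_groups
        aml = [s for s in collapsed.samples if groups[s] == "AML"]
        m = collapsed.restrict_samples(aml)
        rng = np.random.default_rng(5)
        perm = [aml[i] for i in rng.permutation(len(aml))]
        m_p = PeptideMatrix(data=m.data[perm], stage=m.stage, sample_groups=m.sample_groups)
        res = cl.run_clustering(m, seed=1)
        res_p = cl.run_clustering(m_p, seed=1)
        a = res.labels_at()
        b = res_p.labels_at().loc[a.index]
        assert adjusted_rand_score(a, b) == pytest.approx(1.0)
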