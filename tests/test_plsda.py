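"""NIPALS PLS-DA: fit, prediction, VIP, cross-validation, permutation."""

import numpy as np
import pytest

import milknmr as m
from milknmr.chemometrics import _segment_assignment, normalize_norcont, plsda_cv


def gaussian_cohort(n=12, p=30, shift=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n, p))
    X[:n, :3] += shift
    return X, ["a"] * n + ["b"] * n


class TestFit:
    def test_exact_fit_when_y_linear_in_one_column(self):
        """One latent variable fits Y exactly when the class indicator is a
        column of X and the remaining columns carry no class signal."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(16, 5))
        labels = ["a"] * 8 + ["b"] * 8
        y = np.array([1.0 if l == "a" else 0.0 for l in labels])
        yc = y - y.mean()
        for j in (0, 1, 3, 4):  # strip incidental correlation with the label
            X[:, j] -= yc * (X[:, j] @ yc) / (yc @ yc)
        X[:, 2] = y
        res = m.PLSDA(X, labels, n_components=1, scale=None).fit()
        assert res.r2y >= 0.999

    def test_scores_orthogonal(self, p_bucket_matrix):
        res = m.PLSDA(p_bucket_matrix, p_bucket_matrix.class_labels,
                      n_components=3).fit()
        T = res.x_scores
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() <= 1e-8 * np.abs(np.diag(G)).max()

    def test_weights_unit_norm(self, p_bucket_matrix):
        res = m.PLSDA(p_bucket_matrix, p_bucket_matrix.class_labels,
                      n_components=3).fit()
        assert np.allclose(np.linalg.norm(res.weights, axis=0), 1.0)

    def test_matches_reference_pls_implementation(self):
        """Scores, loadings and predictions agree with scikit-learn's PLS
        (independent NIPALS route) to machine precision."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, labels = gaussian_cohort(seed=3)
        mine = m.PLSDA(X, labels, n_components=3, scale=None).fit()
        Y = np.zeros((len(labels), 2))
        Y[np.arange(len(labels)), [0 if l == "a" else 1 for l in labels]] = 1
        ref = sklearn.PLSRegression(n_components=3, scale=False).fit(X, Y)
        for a in range(3):
            c = np.corrcoef(mine.x_scores[:, a], ref.x_scores_[:, a])[0, 1]
            assert abs(c) == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(mine.decision_values(X), ref.predict(X), atol=1e-10)

    def test_well_separated_cohort_classifies_training_set(self):
        X, labels = gaussian_cohort()
        res = m.PLSDA(X, labels, n_components=2).fit()
        assert res.predict(X) == labels

    def test_null_labels_give_small_r2y(self):
        # with n >> p a single component cannot overfit random labels
        rng = np.random.default_rng(9)
        X = rng.normal(size=(60, 5))
        labels = ["a"] * 30 + ["b"] * 30
        res = m.PLSDA(X, labels, n_components=1).fit()
        assert res.r2y < 0.3

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            m.PLSDA(np.ones((4, 3)), ["a"] * 4)

    def test_summary_mentions_fit(self, p_bucket_matrix):
        res = m.PLSDA(p_bucket_matrix, p_bucket_matrix.class_labels).fit()
        s = res.summary()
        assert "R2Y" in s and "conventional" in s


class TestVip:
    def test_normalization_identity(self, p_bucket_matrix):
        """Mean squared VIP equals one."""
        res = m.PLSDA(p_bucket_matrix, p_bucket_matrix.class_labels,
                      n_components=2).fit()
        v = res.vip()
        assert np.mean(v ** 2) == pytest.approx(1.0, abs=1e-8)

    def test_single_informative_column_has_max_vip(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(24, 20))
        labels = ["a"] * 12 + ["b"] * 12
        X[:12, 7] += 5.0
        res = m.PLSDA(X, labels, n_components=2).fit()
        assert int(np.argmax(res.vip())) == 7

    def test_marker_buckets_rank_high(self, marker_bucket_matrix):
        """With the preset class differences planted, the quantification
        marker buckets (allylic 2.02, bis-allylic 2.77/2.81, caproleic
        5.80, CLA ct 6.28) all rank in the top 5% of 631 VIP scores."""
        nc = normalize_norcont(marker_bucket_matrix)
        res = m.PLSDA(nc.to_array(), nc.class_labels, n_components=2).fit()
        v = res.vip()
        centers = nc.centers
        order = np.argsort(v)[::-1]
        rank = np.empty_like(order)
        rank[order] = np.arange(1, v.size + 1)
        for marker in (2.025, 2.775, 2.815, 5.805, 6.285):
            j = int(np.argmin(np.abs(centers - marker)))
            assert rank[j] <= int(0.05 * v.size), (marker, rank[j])
            assert v[j] > 1.0


class TestCrossValidation:
    def test_separable_cohort_predicts_perfectly(self):
        X, labels = gaussian_cohort(n=10, shift=6.0, seed=7)
        rep = plsda_cv(X, labels, n_segments=7, n_components=2)
        assert rep.pct_correct == 100.0
        assert rep.q2 > 0.5
        assert rep.fisher_p == pytest.approx(
            m.fisher_exact_2x2([[10, 0], [0, 10]]), rel=1e-9)

    def test_random_labels_give_non_positive_q2_on_average(self):
        rng = np.random.default_rng(11)
        q2s = []
        for seed in range(6):
            X = np.random.default_rng(seed).normal(size=(24, 30))
            labels = list(rng.permutation(["a"] * 12 + ["b"] * 12))
            q2s.append(plsda_cv(X, labels, n_segments=6, n_components=2).q2)
        assert np.mean(q2s) <= 0.0

    def test_leave_one_out_boundary(self):
        X, labels = gaussian_cohort(n=5, shift=6.0, seed=8)
        rep = plsda_cv(X, labels, n_segments=len(labels), n_components=1)
        assert rep.n_segments == len(labels)
        assert rep.pct_correct == 100.0

    def test_replicate_groups_never_straddle_folds(self):
        labels = ["a"] * 6 + ["b"] * 6
        groups = ["g0", "g0", "g1", "g1", "g2", "g2",
                  "h0", "h0", "h1", "h1", "h2", "h2"]
        seg = _segment_assignment(labels, 3, groups=groups)
        for g in set(groups):
            segs = {s for s, gg in zip(seg, groups) if gg == g}
            assert len(segs) == 1

    def test_segment_holding_entire_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 4))
        labels = ["a", "a", "b", "b", "b", "b"]
        groups = ["g1", "g1", "g2", "g3", "g4", "g5"]
        with pytest.raises(ValueError, match="entire class"):
            plsda_cv(X, labels, n_segments=2, n_components=1, groups=groups)


class TestPermutation:
    def test_separable_cohort_validates(self, marker_bucket_matrix):
        """On a class-separable cohort the permuted models underperform and
        the Q2 regression intercept is negative."""
        nc = normalize_norcont(marker_bucket_matrix)
        res = m.PLSDA(nc.to_array(), nc.class_labels, n_components=2).fit()
        perm = res.permutation_test(n_permutations=30, seed=2)
        assert perm.q2_intercept < 0
        assert perm.valid
        assert perm.n_permutations == 30

    def test_null_data_not_validated(self, null_matrix):
        nc = normalize_norcont(null_matrix)
        res = m.PLSDA(nc.to_array(), nc.class_labels, n_components=2).fit()
        perm = res.permutation_test(n_permutations=25, seed=3)
        assert np.mean(perm.q2_permuted) <= 0.0
        assert not perm.valid

    def test_default_iteration_count_is_100(self):
        import inspect
        from milknmr.chemometrics import permutation_test
        assert inspect.signature(permutation_test).parameters[
            "n_permutations"].default == 100

    def test_too_few_permutations_rejected(self):
        X, labels = gaussian_cohort(n=4)
        with pytest.raises(ValueError):
            m.permutation_test(X, labels, n_permutations=5)
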