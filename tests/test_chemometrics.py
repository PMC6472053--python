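"""Scaling, normalization, PCA and the auxiliary statistics."""

import numpy as np
import pytest
from scipy import stats

import milknmr as m
from milknmr.chemometrics import methyl_bucket_mask, pareto_scale, pca


class TestNorCont:
    def test_methyl_sum_three_leaves_row_unchanged(self):
        import pandas as pd
        centers = np.round(m.bucket(m.simulate_spectrum(
            m.FattyAcidProfile.organic(), m.AcquisitionParams(noise_sd=0))).centers, 4)
        mask = methyl_bucket_mask(centers)
        row = np.ones(centers.size)
        row[mask] = 3.0 / mask.sum()
        bm = m.BucketMatrix(pd.DataFrame([row, row], columns=centers), ["a", "b"])
        out = m.normalize_norcont(bm)
        assert np.allclose(out.to_array(), bm.to_array())
        assert out.normalization_tag == "NorCont"

    def test_lipid_scale_invariance_exact_without_reference(self):
        """With no reference signal, NorCont rows of a doubled-lipid
        duplicate are identical to machine precision."""
        params = m.AcquisitionParams(noise_sd=0.0, reference_area=0.0)
        prof = m.FattyAcidProfile.organic()
        s1 = m.simulate_spectrum(prof, params, lipid_scale=1.0)
        s2 = m.simulate_spectrum(prof, params, lipid_scale=2.0)
        bm = m.BucketMatrix.from_spectra([s1, s2], ["a", "a"])
        out = m.normalize_norcont(bm).to_array()
        assert np.allclose(out[0], out[1], rtol=1e-9, atol=1e-12)

    def test_lipid_scale_invariance_with_reference_masked(self, quiet_params):
        """With the fixed-amount reference present, invariance holds on the
        lipid buckets (the reference region is masked by construction)."""
        prof = m.FattyAcidProfile.organic()
        s1 = m.simulate_spectrum(prof, quiet_params, lipid_scale=1.0)
        s2 = m.simulate_spectrum(prof, quiet_params, lipid_scale=2.0)
        bm = m.BucketMatrix.from_spectra([s1, s2], ["a", "a"])
        out = m.normalize_norcont(bm).to_array()
        # residual deviation is the reference Lorentzian tail just outside
        # the masked region; lipid buckets agree to <1e-4 relative
        assert np.abs(out[0] - out[1]).max() < 1e-3
        big = out[0] > 1e-2
        assert np.allclose(out[0][big], out[1][big], rtol=1e-4)

    def test_norcont_shrinks_fat_subgroup_distance(self, p_cohort):
        """The 1.5%/3% fat split dominates UNor distances and is removed
        by the total-methyl normalization."""
        spectra, labels, _ = p_cohort
        bm = m.BucketMatrix.from_spectra(spectra, labels)
        conv = [i for i, l in enumerate(labels) if l == "conventional"]
        a, b = conv[:8], conv[8:]  # scale-2 vs scale-1 subgroups

        def subgroup_distance(X):
            return np.linalg.norm(X[a].mean(axis=0) - X[b].mean(axis=0))

        d_unor = subgroup_distance(bm.to_array())
        d_norcont = subgroup_distance(m.normalize_norcont(bm).to_array())
        assert d_norcont < 0.05 * d_unor

    def test_zero_methyl_sum_names_sample(self):
        import pandas as pd
        centers = np.round(np.arange(0.035, 6.345, 0.01), 4)
        X = np.zeros((2, centers.size))
        X[0] = 1.0
        bm = m.BucketMatrix(pd.DataFrame(X, index=["ok", "empty"], columns=centers),
                            ["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            m.normalize_norcont(bm)


class TestParetoScale:
    def test_constant_column_maps_to_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 4.0], [1.0, 6.0]])
        Xs, _, _ = pareto_scale(X)
        assert np.all(Xs[:, 0] == 0)

    def test_two_point_column(self):
        Xs, _, _ = pareto_scale(np.array([[0.0], [2.0]]))
        # mean 1, sd sqrt(2), sqrt(sd) = 2**(1/4)
        assert Xs[:, 0] == pytest.approx([-0.8409, 0.8409], abs=1e-4)

    def test_columns_centered(self):
        rng = np.random.default_rng(0)
        Xs, _, _ = pareto_scale(rng.normal(size=(13, 7)))
        assert np.allclose(Xs.mean(axis=0), 0.0, atol=1e-12)

    def test_milder_than_unit_variance(self):
        """Pareto leaves high-variance columns larger than UV scaling would."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 2)) * np.array([10.0, 0.1])
        Xs, _, sds = pareto_scale(X)
        assert Xs[:, 0].std(ddof=1) > Xs[:, 1].std(ddof=1)


class TestPCA:
    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 8)) @ rng.normal(size=(8, 8))
        res = pca(X)
        evals = np.linalg.eigvalsh(np.cov(X, rowvar=False, ddof=1))[::-1]
        got = res.explained_variance_pct
        want = 100 * evals / evals.sum()
        assert np.allclose(got, want, atol=1e-8)

    def test_full_rank_variance_sums_to_100(self):
        rng = np.random.default_rng(3)
        res = pca(rng.normal(size=(10, 4)))
        assert res.explained_variance_pct.sum() == pytest.approx(100.0)

    def test_rank_one_data(self):
        t = np.linspace(-1, 1, 12)[:, None]
        X = t @ np.array([[1.0, -2.0, 0.5]])
        res = pca(X, n_components=2)
        assert res.explained_variance_pct[0] == pytest.approx(100.0, abs=1e-8)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            pca(np.ones((1, 5)))


class TestFisherExact:
    def test_perfect_separation_14_16(self):
        """Perfect prediction of 14 vs 16 samples: p = 1/C(30,14)."""
        p = m.fisher_exact_2x2([[14, 0], [0, 16]])
        assert p == pytest.approx(6.9e-9, rel=0.01)
        assert p == pytest.approx(1 / 145422675, rel=1e-12)

    def test_no_association(self):
        assert m.fisher_exact_2x2([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_five_five_enumeration(self):
        assert m.fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_matches_scipy_for_all_small_margins(self):
        """Exhaustive agreement with an independent implementation over
        every 2x2 table with total n <= 20 and positive margins."""
        for n in range(2, 21):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        if (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0):
                            continue
                        t = [[a, b], [c, d]]
                        want = stats.fisher_exact(t).pvalue
                        assert m.fisher_exact_2x2(t) == pytest.approx(
                            want, rel=1e-9), t

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            m.fisher_exact_2x2([[1.5, 0], [0, 1]])
        with pytest.raises(ValueError):
            m.fisher_exact_2x2([[-1, 1], [1, 1]])
        with pytest.raises(ValueError):
            m.fisher_exact_2x2([[0, 0], [1, 1]])


class TestHotelling:
    def test_identical_scores_flag_nothing(self):
        assert not m.hotelling_outliers(np.ones((6, 2))).any()

    def test_planted_extreme_sample_flagged(self):
        rng = np.random.default_rng(4)
        Z = rng.normal(size=(20, 2))
        Z[7] = [10.0, -10.0]
        flags = m.hotelling_outliers(Z, alpha=0.05)
        assert flags[7]
        assert flags.sum() <= 2

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(5)
        Z = rng.normal(size=(15, 2))
        f1 = m.hotelling_outliers(Z)
        f2 = m.hotelling_outliers(Z * np.array([-1.0, 1.0]))
        assert np.array_equal(f1, f2)

    def test_singular_covariance_rejected(self):
        Z = np.ones((6, 2))
        Z[:, 0] = np.arange(6.0)  # column 2 constant but scores not all equal
        with pytest.raises(ValueError, match="singular"):
            m.hotelling_outliers(Z)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            m.hotelling_outliers(np.ones((2, 1)))


class TestMarkerTtest:
    def test_identical_groups(self):
        t, p = m.marker_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_constant_identical_groups(self):
        assert m.marker_ttest([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)

    def test_pooled_closed_form(self):
        t, p = m.marker_ttest([1, 2, 3], [4, 5, 6], equal_var=True)
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0214, abs=2e-4)

    def test_planted_cla_difference_detected(self, marker_cohort):
        """Organic vs conventional CLA ct differs at n = 20 per class."""
        spectra, labels, _ = marker_cohort
        cla = np.array([m.pct_cla_ct(m.extract_integral_set(s)) for s in spectra])
        labs = np.array(labels)
        t, p = m.marker_ttest(cla[labs == "organic"], cla[labs == "conventional"])
        assert p < 0.05

    def test_short_group_rejected(self):
        with pytest.raises(ValueError):
            m.marker_ttest([1.0], [1.0, 2.0])
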