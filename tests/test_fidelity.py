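"""Statistical validation battery: univariate tests, PCA/T², OPLS-DA, surfaces."""

import json

import numpy as np
import pytest
from scipy import stats

from fermgan.fidelity import (
    brown_forsythe_means,
    fidelity_report,
    hotelling_t2_limit,
    kruskal_wallis,
    normality_tests,
    opls_da,
    pca,
    remove_t2_outliers,
    surface_fit,
    welch_test,
)
from fermgan.table import DegenerateFeatureError, FeatureTable


def _table(values, labels=None):
    values = np.asarray(values, float)
    if labels is None:
        labels = np.ones(len(values), int)
    return FeatureTable(values, labels)


class TestWelch:
    def test_textbook_value(self):
        r = welch_test([1, 2, 3, 4], [2, 4, 6])
        # means 2.5 vs 4, s² 5/3 vs 4 -> t = -1.5/sqrt(5/12 + 4/3)
        assert abs(r.statistic) == pytest.approx(1.1339, abs=1e-4)
        assert r.group_sizes == (4, 3)

    def test_identical_samples(self):
        r = welch_test([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_hand_formula(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, rng.integers(3, 30))
        b = rng.normal(0.3, 2, rng.integers(3, 30))
        r = welch_test(a, b)
        sa, sb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
        df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
        assert r.statistic == pytest.approx(t, abs=1e-9)
        assert r.p_value == pytest.approx(2 * stats.t.sf(abs(t), df), abs=1e-9)

    def test_zero_variance_equal_means(self):
        r = welch_test([3.0, 3.0], [3.0, 3.0, 3.0])
        assert (r.statistic, r.p_value) == (0.0, 1.0)

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError):
            welch_test([3.0, 3.0], [4.0, 4.0])

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            welch_test([1.0], [1.0, 2.0])


class TestBrownForsythe:
    def test_identical_groups_give_zero_statistic(self):
        r = brown_forsythe_means([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_reduces_to_anova_for_equal_variance_equal_n(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=12)
        b = a + 1.7  # exactly equal sample variances, equal n
        r = brown_forsythe_means(a, b)
        f, p = stats.f_oneway(a, b)
        assert r.statistic == pytest.approx(f, rel=1e-9)
        assert r.p_value == pytest.approx(p, abs=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_hand_formula(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = rng.normal(0, 1, rng.integers(4, 25))
        b = rng.normal(0.5, 3, rng.integers(4, 25))
        r = brown_forsythe_means(a, b)
        na, nb = a.size, b.size
        N = na + nb
        grand = (na * a.mean() + nb * b.mean()) / N
        num = na * (a.mean() - grand) ** 2 + nb * (b.mean() - grand) ** 2
        wa = (1 - na / N) * a.var(ddof=1)
        wb = (1 - nb / N) * b.var(ddof=1)
        f_star = num / (wa + wb)
        ca, cb = wa / (wa + wb), wb / (wa + wb)
        df = 1.0 / (ca**2 / (na - 1) + cb**2 / (nb - 1))
        assert r.statistic == pytest.approx(f_star, rel=1e-10)
        assert r.p_value == pytest.approx(stats.f.sf(f_star, 1, df), abs=1e-12)

    def test_type_one_error_calibrated_under_unequal_variances(self):
        # the scenario classical ANOVA gets wrong and Brown-Forsythe fixes
        rng = np.random.default_rng(7)
        n_reps, alpha = 2000, 0.05
        rejections = 0
        for _ in range(n_reps):
            a = rng.normal(0, 1, 8)
            b = rng.normal(0, 4, 24)
            if brown_forsythe_means(a, b).p_value < alpha:
                rejections += 1
        assert 0.03 < rejections / n_reps < 0.07


class TestKruskalWallis:
    def test_textbook_value(self):
        r = kruskal_wallis([1.0, 2.0], [3.0, 4.0])
        # H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2 = 0.6 * 4
        assert r.statistic == pytest.approx(2.4, abs=1e-12)

    def test_all_tied_convention(self):
        r = kruskal_wallis([5.0, 5.0], [5.0, 5.0, 5.0])
        assert (r.statistic, r.p_value) == (0.0, 1.0)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 5, 15).astype(float)
        b = rng.integers(0, 5, 12).astype(float)
        r = kruskal_wallis(a, b)
        h, p = stats.kruskal(a, b)
        assert r.statistic == pytest.approx(h, rel=1e-12)
        assert r.p_value == pytest.approx(p, rel=1e-12)

    def test_permutation_null_calibration(self):
        rng = np.random.default_rng(2)
        pooled = rng.normal(size=20)
        n_reps, alpha = 2000, 0.05
        rejections = 0
        for _ in range(n_reps):
            perm = rng.permutation(pooled)
            if kruskal_wallis(perm[:10], perm[10:]).p_value < alpha:
                rejections += 1
        assert 0.02 < rejections / n_reps < 0.08


class TestNormality:
    def test_accepts_gaussian_columns(self):
        rng = np.random.default_rng(3)
        p_values = []
        for _ in range(25):
            t = _table(rng.normal(size=(5000, 4)) + [1, 2, 3, 4])
            p_values += [r.p_value for r in normality_tests(t)]
        # 200 p-values (KS + SW on 4 features x 25 tables), each ~U(0,1)
        assert np.mean(np.array(p_values) > 0.05) >= 0.90

    def test_rejects_uniform_columns(self):
        rng = np.random.default_rng(4)
        t = _table(rng.uniform(size=(500, 4)))
        for r in normality_tests(t):
            if r.test == "kolmogorov_smirnov":
                assert r.p_value < 0.01

    def test_constant_feature_named(self):
        values = np.random.default_rng(5).normal(size=(30, 4))
        values[:, 2] = 1.5
        with pytest.raises(DegenerateFeatureError, match="dose"):
            normality_tests(_table(values))

    def test_both_tests_reported_per_feature(self, design20):
        results = normality_tests(design20)
        assert len(results) == 8
        assert {r.test for r in results} == {"kolmogorov_smirnov", "shapiro_wilk"}


class TestPca:
    def test_perfectly_correlated_features_give_single_component(self):
        x = np.linspace(-1, 1, 15)
        res = pca(np.column_stack([x, 2 * x]), n_components=1)
        np.testing.assert_allclose(res.explained_variance_ratio, [1.0, 0.0], atol=1e-12)

    def test_variance_fractions_sum_to_one(self, design20):
        res = pca(design20, n_components=2)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-12)
        assert (np.diff(res.explained_variance_ratio) <= 1e-12).all()

    def test_toy_scores_up_to_sign(self):
        res = pca(np.array([[-1.0, 0.0], [0.0, 0.0], [1.0, 0.0]]), 1, scaling="center-only")
        s = res.scores[:, 0]
        np.testing.assert_allclose(np.sort(s), [-1.0, 0.0, 1.0], atol=1e-12)

    def test_matches_sklearn(self, design20):
        from sklearn.decomposition import PCA

        res = pca(design20, n_components=2, scaling="center-only")
        ref = PCA(n_components=4).fit(design20.values)
        np.testing.assert_allclose(
            res.explained_variance_ratio, ref.explained_variance_ratio_, atol=1e-10
        )
        ref_scores = ref.transform(design20.values)[:, :2]
        for a in range(2):
            sign = np.sign(res.scores[0, a] * ref_scores[0, a]) or 1.0
            np.testing.assert_allclose(res.scores[:, a], sign * ref_scores[:, a], atol=1e-9)

    def test_t2_definition(self, design20):
        res = pca(design20, n_components=2)
        lam = res.scores.var(axis=0, ddof=1)
        np.testing.assert_allclose(res.t2, (res.scores**2 / lam).sum(axis=1), atol=1e-9)

    def test_t2_limit_formula(self):
        expected = 2 * 19 * 21 / (20 * 18) * stats.f.ppf(0.95, 2, 18)
        assert hotelling_t2_limit(20, 2) == pytest.approx(expected, rel=1e-12)

    def test_constant_feature_rejected_under_autoscaling(self):
        values = np.random.default_rng(6).normal(size=(10, 4))
        values[:, 1] = 0.0
        with pytest.raises(DegenerateFeatureError):
            pca(values)


class TestOutlierRemoval:
    def _planted(self):
        rng = np.random.default_rng(8)
        values = rng.normal(0, 1, size=(20, 4))
        values = np.vstack([values, np.full((1, 4), 10.0)])
        return _table(values)

    def test_planted_outlier_flagged_and_removed(self):
        t = self._planted()
        res = pca(t, n_components=2)
        filtered, refit, removed = remove_t2_outliers(res, t)
        assert list(removed) == [20]
        assert len(filtered) == 20

    def test_second_pass_is_stable(self):
        t = self._planted()
        filtered, refit, _ = remove_t2_outliers(pca(t, 2), t)
        filtered2, _, removed2 = remove_t2_outliers(refit, filtered)
        # the refit may flag at most a borderline inlier, never most rows
        assert removed2.size <= 1

    def test_clean_data_untouched(self):
        # points near a circle: nearly equal T2, all below the 95% limit
        theta = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        rng = np.random.default_rng(9)
        values = np.column_stack(
            [np.cos(theta), np.sin(theta), rng.normal(0, 0.01, 24), rng.normal(0, 0.01, 24)]
        )
        t = _table(values)
        res = pca(t, n_components=2)
        filtered, _, removed = remove_t2_outliers(res, t)
        assert removed.size == 0
        np.testing.assert_array_equal(filtered.values, t.values)


class TestOplsDa:
    def _labelled(self, seed=10, n=40):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 4))
        X[:, 0] += 2.0 * y
        return X, y

    def test_zero_orthogonal_components_is_pls1_direction(self):
        from sklearn.cross_decomposition import PLSRegression

        X, y = self._labelled()
        res = opls_da(X, y, n_orthogonal=0)
        ref = PLSRegression(n_components=1, scale=True).fit(X, y.astype(float))
        t_ref = ref.x_scores_[:, 0]
        corr = np.corrcoef(res.t_pred, t_ref)[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-8)

    def test_scores_are_orthogonal(self):
        X, y = self._labelled(seed=11)
        res = opls_da(X, y, n_orthogonal=2)
        for k in range(res.t_orth.shape[1]):
            cos = res.t_pred @ res.t_orth[:, k]
            cos /= np.linalg.norm(res.t_pred) * np.linalg.norm(res.t_orth[:, k])
            assert abs(cos) < 1e-8

    def test_separable_case_loads_on_informative_feature(self):
        rng = np.random.default_rng(12)
        y = np.repeat([0, 1], 20)
        X = rng.normal(0, 0.2, size=(40, 4))
        X[:, 0] += 5.0 * y
        res = opls_da(X, y, n_orthogonal=1)
        w = res.w_pred / np.linalg.norm(res.w_pred)
        assert abs(w[0]) > 0.95
        assert res.r2y > 0.9

    def test_r2x_components_are_valid_fractions(self, design20, synthetic200):
        pooled = design20.concat(synthetic200)
        labels = np.concatenate([np.ones(20), np.zeros(200)])
        res = opls_da(pooled.values, labels, n_orthogonal=1)
        assert (res.r2x_components >= 0).all()
        assert res.r2x_cum <= 1.0 + 1e-12
        assert res.r2x_cum == pytest.approx(res.r2x_components.sum())

    def test_single_class_rejected(self):
        X = np.random.default_rng(13).normal(size=(10, 4))
        with pytest.raises(ValueError):
            opls_da(X, np.ones(10))


class TestSurfaceFit:
    def _quadratic_table(self, rng):
        time = rng.uniform(24, 72, 25)
        temp = rng.uniform(25, 45, 25)
        dose = rng.uniform(0, 3, 25)
        z = 1.0 + 2.0 * temp - 1.0 * time + 0.5 * temp**2
        return _table(np.column_stack([time, temp, dose, z]))

    def test_exact_recovery_of_planted_coefficients(self):
        t = self._quadratic_table(np.random.default_rng(14))
        fit = surface_fit(t)
        np.testing.assert_allclose(fit.coefficients, [1.0, 2.0, -1.0, 0.5, 0.0, 0.0], atol=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-10)

    def test_constant_response(self):
        rng = np.random.default_rng(15)
        values = np.column_stack(
            [rng.uniform(24, 72, 12), rng.uniform(25, 45, 12), rng.uniform(0, 3, 12), np.full(12, 4.0)]
        )
        fit = surface_fit(_table(values))
        np.testing.assert_allclose(fit.coefficients, [4.0, 0, 0, 0, 0, 0], atol=1e-8)

    def test_full_model_never_fits_worse_than_reduced(self):
        rng = np.random.default_rng(16)
        t = self._quadratic_table(rng)
        noisy = t.values.copy()
        noisy[:, 3] += rng.normal(0, 5.0, len(t))
        t = _table(noisy)
        fit = surface_fit(t)
        x, y, z = t.column("temperature"), t.column("time"), t.column("alcohol")
        reduced = np.column_stack([np.ones_like(x), x, y, x * x, y * y])  # no xy term
        beta, _, _, _ = np.linalg.lstsq(reduced, z, rcond=None)
        rss_reduced = float(((reduced @ beta - z) ** 2).sum())
        assert fit.rss <= rss_reduced + 1e-9

    def test_collinear_design_rejected(self):
        values = np.column_stack([np.full(10, 48.0), np.full(10, 35.0), np.zeros(10), np.ones(10)])
        with pytest.raises(np.linalg.LinAlgError):
            surface_fit(_table(values))


class TestFidelityReport:
    def test_split_half_real_data_passes_battery(self, design20):
        """Two halves of the same campaign must look statistically identical."""
        passed = 0
        for seed in range(10):
            perm = np.random.default_rng(seed).permutation(20)
            rep = fidelity_report(design20.take(perm[:10]), design20.take(perm[10:]))
            passed += rep.all_two_sample_pass
        assert passed >= 9

    def test_planted_alcohol_shift_detected(self, design20):
        perm = np.random.default_rng(21).permutation(20)
        a, b = design20.take(perm[:10]), design20.take(perm[10:])
        shifted = b.values.copy()
        shifted[:, 3] += 5.0
        rep = fidelity_report(a, _table(shifted, b.labels))
        assert rep.passes["welch:alcohol"] is False
        welch_alcohol = [t for t in rep.two_sample if t.test == "welch" and t.feature == "alcohol"]
        assert welch_alcohol[0].p_value < 0.01

    def test_report_shape_and_json_round_trip(self, design20, synthetic200):
        rep = fidelity_report(design20, synthetic200)
        assert len(rep.two_sample) == 12  # 3 tests x 4 features
        assert set(rep.passes) == {
            f"{t}:{f}"
            for t in ("welch", "brown_forsythe", "kruskal_wallis")
            for f in ("time", "temperature", "dose", "alcohol")
        }
        payload = json.loads(rep.to_json())
        assert json.loads(json.dumps(payload)) == payload
        assert payload["alpha"] == 0.05
        assert len(payload["two_sample"]) == 12
        assert "r2x_cum" in payload["opls"]

    def test_summary_text_lists_every_test(self, design20, synthetic200):
        text = fidelity_report(design20, synthetic200).summary()
        for token in ("welch", "brown_forsythe", "kruskal_wallis", "OPLS-DA", "verdict"):
            assert token in text
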