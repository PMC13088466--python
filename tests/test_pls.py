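"""Orthogonal-scores PLS1: fit, LOOCV selection, VIP, prediction, grid search."""

import warnings

import numpy as np
import pytest

from rootspec import (
    InvalidInputError,
    PreprocSpec,
    SpectrumTable,
    fit_pls,
    grid_search,
    load_model,
    loocv_select,
    predict,
    save_model,
    vip_scores,
)


def lstsq_predictions(X, y):
    """Minimum-norm least-squares oracle for centred data."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    return y.mean() + Xc @ beta


class TestFitPLS:
    def test_univariate_equals_ols_line(self, rng):
        x = rng.random(30)
        y = 2.5 * x + 0.3 + 0.01 * rng.standard_normal(30)
        model = fit_pls(x[:, None], y, n_lv=1)
        slope, intercept = np.polyfit(x, y, 1)
        pred = model.linear_predict(x[:, None])
        np.testing.assert_allclose(pred, slope * x + intercept, atol=1e-10)

    def test_full_rank_equals_least_squares_oracle(self, rng):
        """With n_lv = rank(X), training predictions match min-norm LS."""
        X = rng.random((25, 6))
        y = rng.random(25)
        model = fit_pls(X, y, n_lv=6)
        np.testing.assert_allclose(
            model.linear_predict(X), lstsq_predictions(X, y), atol=1e-8
        )

    def test_full_rank_equivalence_on_100_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(8, 20))
            b = int(rng.integers(1, min(n - 1, 6)))
            X = rng.random((n, b))
            y = rng.random(n)
            model = fit_pls(X, y, n_lv=b)
            np.testing.assert_allclose(
                model.linear_predict(X), lstsq_predictions(X, y), atol=1e-8
            )

    def test_matches_sklearn_pls(self, rng):
        """Independent cross-check against scikit-learn's NIPALS PLS."""
        from sklearn.cross_decomposition import PLSRegression

        X = rng.random((40, 12))
        y = X @ rng.random(12) + 0.05 * rng.standard_normal(40)
        for a in (1, 3, 5):
            ours = fit_pls(X, y, n_lv=a)
            ref = PLSRegression(n_components=a, scale=False).fit(X, y)
            np.testing.assert_allclose(
                ours.linear_predict(X), ref.predict(X).ravel(), atol=1e-8
            )

    def test_constant_target_predicts_mean(self, rng):
        X = rng.random((10, 4))
        y = np.full(10, 3.3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_pls(X, y, n_lv=2)
        np.testing.assert_allclose(model.coefficients, 0.0, atol=1e-12)
        np.testing.assert_allclose(model.linear_predict(X), 3.3)

    def test_rank_deficiency_warns_and_reduces(self, rng):
        x = rng.random(12)
        X = np.column_stack([x, 2 * x, 3 * x])  # rank 1
        y = x + 0.01 * rng.standard_normal(12)
        with pytest.warns(UserWarning, match="rank deficiency"):
            model = fit_pls(X, y, n_lv=3)
        assert model.n_lv < 3


class TestVIP:
    def test_single_band_vip_is_one(self, rng):
        x = rng.random(20)
        model = fit_pls(x[:, None], x + rng.standard_normal(20) * 0.1, n_lv=1)
        np.testing.assert_allclose(model.vip, [1.0])

    def test_mean_square_is_one_for_any_fit(self, rng):
        for _ in range(10):
            X = rng.random((30, 15))
            y = rng.random(30)
            model = fit_pls(X, y, n_lv=4)
            assert np.mean(model.vip**2) == pytest.approx(1.0, abs=1e-8)

    def test_informative_band_gets_top_score(self):
        """y depends on one band among 50 independent ones (20 seeds)."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.random((60, 50))
            j_star = int(rng.integers(0, 50))
            y = 3.0 * X[:, j_star] + 0.05 * rng.standard_normal(60)
            model = fit_pls(X, y, n_lv=2)
            hits += int(np.argmax(model.vip) == j_star)
        assert hits == 20

    def test_degenerate_model_rejected(self, rng):
        X = rng.random((10, 4))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_pls(X, np.full(10, 1.0), n_lv=1)
        with pytest.raises(InvalidInputError):
            vip_scores(model)


class TestLOOCV:
    def test_two_factor_signal_selects_few_lvs(self, rng):
        """Exact rank-2 relation: RMSECV collapses by 2 LVs."""
        scores = rng.standard_normal((40, 2))
        loadings = rng.random((2, 20))
        X = scores @ loadings
        y = scores @ np.array([1.0, -0.5]) + 1e-6 * rng.standard_normal(40)
        cv = loocv_select(X, y, max_lv=8)
        assert cv.selected_lv <= 3
        assert cv.rmsecv_by_lv[1] < 1e-3

    def test_pure_noise_selects_small_models(self):
        """Median selected LV over 50 seeds stays small for noise targets."""
        chosen = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.random((25, 10))
            y = rng.standard_normal(25)
            chosen.append(loocv_select(X, y, max_lv=8).selected_lv)
        assert np.median(chosen) <= 3

    def test_tiny_sample_caps_lv_at_one(self, rng):
        X = rng.random((3, 5))
        y = rng.random(3)
        cv = loocv_select(X, y, max_lv=16)
        assert len(cv.rmsecv_by_lv) == 1
        assert cv.selected_lv == 1

    def test_too_small_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            loocv_select(rng.random((2, 4)), rng.random(2))


class TestPredict:
    def test_sqrt_back_transform_clips_negatives(self, rng):
        X = rng.random((20, 3))
        y = np.linspace(0, 1, 20)
        model = fit_pls(X, y, n_lv=2, y_transform="sqrt")
        # force a negative sqrt-space prediction via an extreme query
        model.coefficients = np.array([-10.0, 0.0, 0.0])
        out = predict(model, np.array([[5.0, 0.0, 0.0]]))
        assert out[0] == 0.0

    def test_duplicate_rows_identical_outputs(self, rng):
        X = rng.random((15, 4))
        model = fit_pls(X, rng.random(15), n_lv=2)
        q = rng.random((1, 4))
        out = predict(model, np.vstack([q, q]))
        assert out[0] == out[1]

    def test_band_mismatch_rejected(self, rng):
        model = fit_pls(rng.random((10, 4)), rng.random(10), n_lv=1)
        with pytest.raises(InvalidInputError, match="band mismatch"):
            predict(model, rng.random((2, 5)))

    def test_noiseless_self_consistency(self, rng):
        """Fit on clean spectra recovers the training targets (R2 >= 0.99)."""
        from rootspec.evaluation import r_squared

        d = np.linspace(0.01, 0.3, 50)
        bands = np.exp(-np.outer(d, np.linspace(0.5, 3.0, 12)))
        y = d**2
        table = SpectrumTable(X=bands, wavelengths_nm=np.linspace(450, 950, 12), y=y)
        cv = loocv_select(bands, np.sqrt(y), max_lv=8)
        model = fit_pls(bands, np.sqrt(y), cv.selected_lv, y_transform="sqrt")
        assert r_squared(y, predict(model, bands)) >= 0.99

    def test_model_json_round_trip(self, tmp_path, rng):
        X = rng.random((20, 6))
        model = fit_pls(X, rng.random(20), n_lv=3,
                        preproc=PreprocSpec(layer3="snv"),
                        wavelengths_nm=np.linspace(450, 950, 6))
        path = str(tmp_path / "m.json")
        save_model(model, path)
        back = load_model(path)
        q = rng.random((4, 6))
        np.testing.assert_allclose(predict(back, q), predict(model, q), atol=1e-12)


class TestGridSearch:
    def _scatter_table(self, seed, n=40, b=30):
        """Spectra = common density-driven shape + strong affine scatter."""
        rng = np.random.default_rng(seed)
        d = rng.uniform(0.05, 1.0, n)
        lam = np.linspace(0, 1, b)
        shape = np.exp(-np.outer(d, 2 + 3 * lam))
        gain = 1.0 + 0.3 * rng.standard_normal(n)
        offset = 0.1 * rng.standard_normal(n)
        X = gain[:, None] * shape + offset[:, None] + 0.002 * rng.standard_normal((n, b))
        return SpectrumTable(X=X, wavelengths_nm=np.linspace(450, 950, b), y=d**2)

    def test_ranking_covers_all_36_specs(self):
        table = self._scatter_table(0)
        _, _, ranking = grid_search(table, max_lv=6)
        assert len(ranking) == 36

    def test_scatter_dominated_data_prefers_snv_or_msc(self):
        """Strong multiplicative scatter: layer-3 correction should win in
        at least 8 of 10 seeded replicates."""
        wins = 0
        for seed in range(10):
            model, _, _ = grid_search(self._scatter_table(seed), max_lv=6)
            wins += int(model.preproc.layer3 in ("snv", "msc"))
        assert wins >= 8

    def test_tie_breaks_to_earlier_spec(self, rng):
        """Duplicate specs: the first in enumeration order wins."""
        table = self._scatter_table(3)
        specs = [PreprocSpec(), PreprocSpec()]  # identical -> identical RMSECV
        model, cv, ranking = grid_search(table, specs=specs, max_lv=4)
        assert ranking["rmsecv"].idxmin() == 0

    def test_needs_enough_rows(self, rng):
        table = SpectrumTable(
            X=rng.random((10, 5)), wavelengths_nm=np.linspace(450, 950, 5),
            y=rng.random(10),
        )
        with pytest.raises(InvalidInputError):
            grid_search(table)
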