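"""Cost-model space, stop curves, and the CES curvature surface."""

import numpy as np
import pandas as pd
import pytest

from costevidence import cost_introspection as ci
from costevidence import synthetic_data as sd
from costevidence.cost_introspection import CESParams, CostModelSpec, ces_surface


class TestCostModelSpace:
    def test_eight_models(self):
        models = ci.enumerate_cost_models()
        assert len(models) == 8
        assert len({m.label() for m in models}) == 8

    def test_all_flags_off_is_the_constant_model(self):
        constant = CostModelSpec(False, False, False, beta0=0.7)
        values = constant.evaluate([0.8, 1.2], [0.5, 1.5])
        np.testing.assert_allclose(values, 0.7)

    def test_pure_interaction_linear_model_shape(self):
        spec = CostModelSpec(False, True, False, beta0=0.0, beta3=2.0)
        assert spec.evaluate(1.5, 2.0) == pytest.approx(2.0 * 1.5 * 2.0)

    def test_exponents_fixed_at_one_when_nonlinearity_off(self):
        with pytest.raises(ValueError):
            CostModelSpec(True, False, False, lambda1=2.0)


class TestStopProbability:
    def test_ecdf_arithmetic(self):
        table = pd.DataFrame(
            {
                "actual_difficulty": [0.8] * 5,
                "duration": [2.0, 4.0, 6.0, 1.0, 5.0],
            }
        )
        curve = ci.stop_probability(table, grid=np.array([4.0]))
        assert curve.probs[0, 0] == pytest.approx(3 / 5)

    def test_identical_durations_step_to_one(self):
        table = pd.DataFrame(
            {"actual_difficulty": [0.7] * 6, "duration": [3.0] * 6}
        )
        curve = ci.stop_probability(table, grid=np.array([2.9, 3.0, 3.1]))
        np.testing.assert_allclose(curve.probs[0], [0.0, 1.0, 1.0])

    def test_curve_ends_at_one_and_is_monotone(self, implicit_cohort):
        table = sd.to_epoch_table(implicit_cohort)
        curve = ci.stop_probability(table)
        assert np.all(np.diff(curve.probs, axis=1) >= 0)
        np.testing.assert_allclose(curve.probs[:, -1], 1.0)

    def test_large_sample_ecdf_stays_in_dkw_band(self, rng):
        from scipy import stats as sps

        n = 1000
        draws = rng.gamma(4.0, 1.5, size=n)
        table = pd.DataFrame({"actual_difficulty": 0.8, "duration": draws})
        grid = np.linspace(draws.min(), draws.max(), 50)
        curve = ci.stop_probability(table, grid=grid)
        true_cdf = sps.gamma.cdf(grid, 4.0, scale=1.5)
        band = np.sqrt(np.log(2 / 0.001) / (2 * n))  # DKW at alpha=0.001
        assert np.max(np.abs(curve.probs[0] - true_cdf)) < band

    def test_too_few_epochs_rejected(self):
        table = pd.DataFrame({"actual_difficulty": [0.8] * 3, "duration": [1, 2, 3]})
        with pytest.raises(ValueError):
            ci.stop_probability(table)


class TestFitCostModel:
    def test_noiseless_additive_ratings_recover_betas(self):
        design = sd.cost_rating_design()
        truth = sd.default_rating_truth()
        noise = sd.NoiseSpec(rating_sd=0.0, between_subject_sd=0.0, seed=0)
        table = sd.generate_cost_rating(design, truth, noise, 1)[0].table
        fitted, _ = ci.fit_cost_model(table, CostModelSpec(True, False, False))
        assert fitted.beta0 == pytest.approx(truth.beta0, abs=5e-3)
        assert fitted.beta1 == pytest.approx(truth.beta1, abs=5e-3)
        assert fitted.beta2 == pytest.approx(truth.beta2, abs=5e-3)

    def test_interaction_truth_beats_additive_on_stop_curves(self):
        truth = sd.default_stop_truth()
        curves = sd.generate_stop_probabilities(
            truth,
            [0.7, 0.8, 0.9],
            np.linspace(1, 10, 15),
            sd.NoiseSpec(rating_sd=0.03, between_subject_sd=0.0, seed=6),
            1,
        )
        _, ev_int = ci.fit_cost_model(
            curves[0], CostModelSpec(False, True, False), link="sigmoid", seed=2
        )
        _, ev_add = ci.fit_cost_model(
            curves[0], CostModelSpec(True, False, False), link="sigmoid", seed=2
        )
        assert ev_int > ev_add

    def test_degenerate_grid_rejected(self):
        table = pd.DataFrame(
            {"difficulty": [0.8] * 10, "duration": [5.0] * 10, "rating": 0.5}
        )
        with pytest.raises(ValueError):
            ci.fit_cost_model(table, CostModelSpec(True, False, False))


class TestCES:
    def test_delta_one_is_exactly_the_additive_surface(self):
        params = CESParams(alpha=0.3, delta=1.0, offset=0.2, scale=1.5)
        d = np.linspace(0.5, 1.5, 7)
        t = np.linspace(0.5, 1.5, 7)
        expected = 0.2 + 1.5 * (0.3 * d + 0.7 * t)
        np.testing.assert_allclose(ces_surface(params, d, t), expected)

    def test_iso_cost_contours_convex_only_below_delta_one(self):
        # along an iso-cost line t(d), convexity toward the origin means
        # t''(d) > 0; check the sign numerically via the implicit function
        d = np.array([0.9, 1.0, 1.1])
        for delta, convex in ((0.5, True), (1.0, False)):
            params = CESParams(alpha=0.5, delta=delta, offset=0.0, scale=1.0)
            level = ces_surface(params, 1.0, 1.0)
            t_of_d = []
            for dd in d:
                grid = np.linspace(0.3, 3.0, 4000)
                values = ces_surface(params, dd, grid)
                t_of_d.append(grid[np.argmin(np.abs(values - level))])
            curvature = t_of_d[0] - 2 * t_of_d[1] + t_of_d[2]
            if convex:
                assert curvature > 1e-4
            else:
                assert abs(curvature) < 1e-4

    def test_noiseless_additive_data_recover_delta_one(self):
        design = sd.cost_rating_design()
        noise = sd.NoiseSpec(rating_sd=0.0, between_subject_sd=0.0, seed=0)
        table = sd.generate_cost_rating(design, sd.default_rating_truth(), noise, 1)[0].table
        params = ci.fit_ces(table, link="identity", n_starts=6, seed=1)
        assert params.delta == pytest.approx(1.0, abs=0.02)
        assert params.alpha == pytest.approx(0.28 / 0.42, abs=0.02)

    def test_exchange_symmetry_at_alpha_half(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(0.7, 1.3, 60)
        t = rng.uniform(0.7, 1.3, 60)
        y = 0.1 + 0.4 * (0.5 * d**0.7 + 0.5 * t**0.7) ** (1 / 0.7)
        y = y + rng.normal(0, 0.01, 60)
        t1 = pd.DataFrame({"difficulty": d, "duration": t, "rating": y})
        t2 = pd.DataFrame({"difficulty": t, "duration": d, "rating": y})
        p1 = ci.fit_ces(t1, n_starts=6, seed=4)
        p2 = ci.fit_ces(t2, n_starts=6, seed=4)
        assert p1.delta == pytest.approx(p2.delta, rel=0.05)
        assert p1.alpha + p2.alpha == pytest.approx(1.0, abs=0.05)

    def test_bootstrap_interval_covers_truth_on_clean_data(self):
        design = sd.cost_rating_design()
        noise = sd.NoiseSpec(rating_sd=0.02, between_subject_sd=0.0, seed=9)
        table = sd.generate_cost_rating(design, sd.default_rating_truth(), noise, 1)[0].table
        params = ci.fit_ces(table, n_starts=3, seed=2, n_boot=20)
        lo, hi = params.ci["delta"]
        assert lo <= 1.0 <= hi
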