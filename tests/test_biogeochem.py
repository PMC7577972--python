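"""Regression machinery, nutrient reconstruction and calibration chain."""

import numpy as np
import pytest
from scipy import stats

from turbflux import biogeochem as bg
from turbflux import synthetic as syn

from conftest import constant_eps_config


class TestFitLinear:
    def test_exact_line_zero_width_cis(self):
        x = np.arange(5.0)
        m = bg.fit_linear(x, 2.0 * x + 1.0)
        assert m.slope == pytest.approx(2.0, abs=1e-12)
        assert m.intercept == pytest.approx(1.0, abs=1e-12)
        assert m.slope_ci == pytest.approx(0.0, abs=1e-10)
        assert m.intercept_ci == pytest.approx(0.0, abs=1e-10)

    def test_ci_matches_textbook_formula(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0.0, 10.0, 30)
        y = 1.5 * x - 2.0 + rng.normal(0.0, 0.7, 30)
        m = bg.fit_linear(x, y)
        # independent oracle: direct least-squares formulas
        n = x.size
        xbar = x.mean()
        sxx = np.sum((x - xbar) ** 2)
        slope = np.sum((x - xbar) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * xbar
        resid = y - (slope * x + intercept)
        s2 = np.sum(resid ** 2) / (n - 2)
        t = stats.t.ppf(0.975, n - 2)
        se_slope = np.sqrt(s2 / sxx)
        se_int = np.sqrt(s2 * (1.0 / n + xbar ** 2 / sxx))
        assert m.slope == pytest.approx(slope, abs=1e-10)
        assert m.slope_ci == pytest.approx(t * se_slope, abs=1e-10)
        assert m.intercept_ci == pytest.approx(t * se_int, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            bg.fit_linear([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            bg.fit_linear([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestModelRegistry:
    def test_station_override_and_default(self):
        reg = bg.published_nutrient_registry()
        m_l4 = bg.select_nutrient_model("L4", "nitrate", reg)
        assert (m_l4.slope, m_l4.intercept) == (-0.939, 24.666)
        m_l8 = bg.select_nutrient_model("L8", "nitrate", reg)
        assert (m_l8.slope, m_l8.intercept) == (-0.540, 14.077)
        m_unknown = bg.select_nutrient_model("Lxx", "phosphate", reg)
        assert (m_unknown.slope, m_unknown.intercept) == (-0.032, 0.819)

    def test_empty_registry_rejected(self):
        with pytest.raises(ValueError):
            bg.select_nutrient_model("L1", "nitrate", {})


class TestNutrientFromTheta:
    def test_pooled_values_at_20C(self):
        reg = bg.published_nutrient_registry()
        no3 = bg.nutrient_from_theta(np.array([20.0]),
                                     reg[("nitrate", "default")])
        assert no3.values[0] == pytest.approx(3.277, abs=1e-9)
        po4 = bg.nutrient_from_theta(np.array([20.0]),
                                     reg[("phosphate", "default")])
        assert po4.values[0] == pytest.approx(0.179, abs=1e-9)

    def test_cold_water_masked(self):
        reg = bg.published_nutrient_registry()
        prof = bg.nutrient_from_theta(np.array([14.0, 20.0]),
                                      reg[("nitrate", "default")])
        assert np.isnan(prof.values[0]) and prof.masked[0]
        assert np.isfinite(prof.values[1])

    def test_negative_prediction_clipped_and_flagged(self):
        model = bg.RegressionModel(-1.0, 10.0, valid_range=(None, None))
        prof = bg.nutrient_from_theta(np.array([12.0]), model)
        assert prof.values[0] == 0.0
        assert prof.clipped[0]

    def test_monotone_decreasing_in_theta(self):
        reg = bg.published_nutrient_registry()
        theta = np.linspace(15.5, 25.5, 40)  # below the zero crossing
        vals = bg.nutrient_from_theta(theta, reg[("nitrate", "default")]).values
        assert np.all(np.diff(vals) < 0)


class TestCalibrationChain:
    def test_published_coefficients(self):
        chain = bg.published_calibration_chain()
        out = bg.apply_calibration_chain(np.array([0.5, 0.0]), chain)
        # 1.11 * (1.42*0.5 + 0.10) - 0.08 and the zero-input offset
        assert out.values[0] == pytest.approx(0.8191, abs=1e-9)
        assert out.values[1] == pytest.approx(0.031, abs=1e-9)

    def test_chained_equals_composed_affine(self):
        chain = bg.published_calibration_chain()
        flu = np.linspace(0.1, 2.0, 25)
        stage1 = chain.stage1.slope * flu + chain.stage1.intercept
        two_step = chain.stage2.slope * stage1 + chain.stage2.intercept
        a, b = chain.composed()
        assert np.allclose(a * flu + b, two_step, atol=1e-12)
        assert np.allclose(bg.apply_calibration_chain(flu, chain).values,
                           two_step, atol=1e-12)

    def test_negative_chlorophyll_clipped(self):
        chain = bg.published_calibration_chain()
        out = bg.apply_calibration_chain(np.array([-0.5]), chain)
        assert out.values[0] == 0.0 and out.clipped[0]

    def test_missing_stage_rejected(self):
        chain = bg.published_calibration_chain()
        chain.stage2 = None
        with pytest.raises(ValueError):
            bg.apply_calibration_chain(np.array([0.5]), chain)


class TestFitCalibrationChain:
    def pairs(self, config, stations=range(4)):
        hydros = [syn.generate_hydro_profile(config, s) for s in stations]
        bottles = [syn.generate_bottles(config, s) for s in stations]
        return ([(h.depth, h.fluorescence) for h in hydros],
                [(h.depth, h.fluorescence_ref) for h in hydros],
                [(b.depth, b.chlorophyll) for b in bottles])

    def test_recovers_generating_coefficients_within_ci(self):
        # predictor-channel noise is kept small relative to its spread so
        # OLS attenuation stays well inside the confidence interval
        cfg = constant_eps_config(seed=21, n_stations=4, depth_max=500.0,
                                  bottle_depths=(0., 50., 100., 200., 300., 400.))
        cfg.noise_sd = dict(cfg.noise_sd, fluorescence=0.0005)
        tm, ctd, bot = self.pairs(cfg)
        chain = bg.fit_calibration_chain(tm, ctd, bot)
        (a1, b1), (a2, b2) = cfg.calibration
        assert abs(chain.stage1.slope - a1) <= chain.stage1.slope_ci
        assert abs(chain.stage2.slope - a2) <= chain.stage2.slope_ci

    def test_noise_free_exact_recovery_at_min_depth_zero(self):
        cfg = constant_eps_config(seed=22, n_stations=2, depth_max=500.0,
                                  bottle_depths=(0., 50., 100., 200., 300., 400.))
        cfg.noise_sd = dict(cfg.noise_sd, fluorescence=0.0, chl=0.0)
        tm, ctd, bot = self.pairs(cfg, stations=range(2))
        chain = bg.fit_calibration_chain(tm, ctd, bot, min_depth=0.0)
        (a1, b1), (a2, b2) = cfg.calibration
        assert chain.stage1.slope == pytest.approx(a1, rel=1e-9)
        assert chain.stage1.intercept == pytest.approx(b1, abs=1e-9)
        assert chain.stage2.slope == pytest.approx(a2, rel=1e-6)
        assert chain.stage2.intercept == pytest.approx(b2, abs=1e-6)

    def test_all_pairs_too_shallow_rejected(self):
        cfg = constant_eps_config(seed=23, n_stations=1, depth_max=300.0,
                                  bottle_depths=(0., 50.))
        tm, ctd, bot = self.pairs(cfg, stations=[0])
        with pytest.raises(ValueError, match="qualifying"):
            bg.fit_calibration_chain(tm, ctd, bot, min_depth=600.0)
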