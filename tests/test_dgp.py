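"""Data-generating process: calibrations, moments, reproducibility."""

import math

import numpy as np
import pytest
from scipy import stats

from misim import (
    CalibrationError,
    DGPConfig,
    calibrate_secondary_conditionals,
    generate_complete,
    latent_corr_for_point_biserial,
    tetrachoric_corr,
)
from misim.dgp import outcome_prevalence_given_exposure
from misim.strategies import fit_substantive


class TestLatentCorrelation:
    def test_zero_maps_to_zero(self):
        assert latent_corr_for_point_biserial(0.0, 0.5) == 0.0

    def test_closed_form_matches_monte_carlo(self):
        # closed form: r = target * sqrt(p(1-p)) / phi(z_p)
        r = latent_corr_for_point_biserial(0.4, 0.5)
        assert r == pytest.approx(0.4 * 0.5 / stats.norm.pdf(0.0), abs=1e-12)
        # independent Monte-Carlo oracle: dichotomise a latent normal with
        # correlation r and check the realised point-biserial correlation
        g = np.random.default_rng(7)
        latent = g.standard_normal(2_000_000)
        x = r * latent + math.sqrt(1 - r * r) * g.standard_normal(2_000_000)
        e = (latent > 0).astype(float)
        assert np.corrcoef(x, e)[0, 1] == pytest.approx(0.4, abs=0.003)

    def test_asymmetric_split(self):
        r = latent_corr_for_point_biserial(0.2, 0.3)
        z = stats.norm.ppf(0.7)
        implied = r * stats.norm.pdf(z) / math.sqrt(0.3 * 0.7)
        assert implied == pytest.approx(0.2, abs=1e-12)

    def test_unattainable_target_raises(self):
        with pytest.raises(CalibrationError):
            latent_corr_for_point_biserial(0.99, 0.01)


class TestSecondaryOutcomeCalibration:
    def test_independence_gives_equal_conditionals(self):
        p1, p0 = calibrate_secondary_conditionals(0.0, 0.3, 0.25)
        assert p1 == pytest.approx(0.25, abs=1e-9)
        assert p0 == pytest.approx(0.25, abs=1e-9)

    def test_perfect_concordance_equal_margins(self):
        p1, p0 = calibrate_secondary_conditionals(1.0, 0.2, 0.2)
        assert p1 == pytest.approx(1.0, abs=1e-9)
        assert p0 == pytest.approx(0.0, abs=1e-9)

    def test_default_margins_orders_conditionals(self):
        p1, p0 = calibrate_secondary_conditionals(0.49, 0.162, 0.162)
        assert p1 > p0

    def test_joint_cell_matches_latent_simulation(self):
        # Monte-Carlo oracle: dichotomise a true bivariate normal with the
        # requested latent correlation and compare the realised joint cell
        # with the one implied by the calibrated conditionals.
        rho, p_y, p_q = 0.49, 0.162, 0.162
        p1, _ = calibrate_secondary_conditionals(rho, p_y, p_q)
        g = np.random.default_rng(21)
        z1 = g.standard_normal(1_000_000)
        z2 = rho * z1 + math.sqrt(1 - rho * rho) * g.standard_normal(1_000_000)
        h = stats.norm.ppf(1 - p_y)
        k = stats.norm.ppf(1 - p_q)
        p11_mc = np.mean((z1 > h) & (z2 > k))
        assert p1 * p_y == pytest.approx(p11_mc, abs=0.002)

    def test_out_of_range_inputs_rejected(self):
        # any rho in [-1, 1] is feasible for non-degenerate margins (the
        # joint cell interpolates between the Frechet bounds), so the error
        # paths concern out-of-range arguments
        with pytest.raises(ValueError):
            calibrate_secondary_conditionals(1.5, 0.2, 0.2)
        with pytest.raises(ValueError):
            calibrate_secondary_conditionals(0.5, 0.0, 0.2)


class TestTetrachoric:
    def test_roundtrip_through_generated_data(self, big_cohort):
        rho = tetrachoric_corr(big_cohort.y, big_cohort.y_sec)
        assert rho == pytest.approx(0.49, abs=0.02)

    def test_independent_variables_near_zero(self, rng):
        y = (rng.random(200_000) < 0.3).astype(int)
        q = (rng.random(200_000) < 0.3).astype(int)
        assert tetrachoric_corr(y, q) == pytest.approx(0.0, abs=0.02)


class TestConfig:
    def test_intercept_calibration_hits_target(self, default_config):
        c = default_config
        p0 = outcome_prevalence_given_exposure(
            c.beta0, c.beta1, c.beta2, c.beta3, c.corr_xe, c.p_exposure, False
        )
        assert p0 == pytest.approx(0.091, abs=1e-9)

    def test_explicit_intercept_respected(self):
        c = DGPConfig(n=10, beta0=-1.0)
        assert c.beta0 == -1.0

    def test_secondary_margin_defaults_to_outcome_prevalence(self, default_config):
        assert default_config.p_sec_marginal == pytest.approx(
            default_config.p_y_marginal
        )
        assert default_config.p_y_marginal == pytest.approx(0.162, abs=0.001)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n": 0},
            {"p_exposure": 1.0},
            {"corr_xe": 1.0},
            {"rho_sec": 1.5},
            {"p_sec_marginal": 0.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises((ValueError, CalibrationError)):
            DGPConfig(**kwargs)

    def test_yaml_roundtrip(self, tmp_path, default_config):
        path = tmp_path / "cfg.yaml"
        default_config.to_yaml(path)
        back = DGPConfig.from_yaml(path)
        assert back.beta0 == pytest.approx(default_config.beta0)
        assert back.n == default_config.n


class TestGenerate:
    def test_same_seed_bit_identical(self, default_config):
        a = generate_complete(default_config, 5)
        b = generate_complete(default_config, 5)
        assert np.array_equal(a.x, b.x)
        assert np.array_equal(a.e, b.e)
        assert np.array_equal(a.y, b.y)
        assert np.array_equal(a.y_sec, b.y_sec)

    def test_moments_converge_to_targets(self, big_cohort):
        d = big_cohort
        assert d.e.mean() == pytest.approx(0.5, abs=0.003)
        assert np.corrcoef(d.x, d.e)[0, 1] == pytest.approx(0.4, abs=0.005)
        assert d.x.mean() == pytest.approx(0.0, abs=0.01)
        assert d.x.std() == pytest.approx(1.0, abs=0.01)
        assert d.y[d.e == 0].mean() == pytest.approx(0.091, abs=0.003)
        assert d.y[d.e == 1].mean() == pytest.approx(0.2327, abs=0.004)

    def test_no_covariate_effects_recovers_expit(self):
        cfg = DGPConfig(
            n=200_000, beta0=-1.0, beta1=0.0, beta2=0.0, beta3=0.0, corr_xe=0.0
        )
        d = generate_complete(cfg, 3)
        expected = 1 / (1 + math.exp(1.0))
        assert d.y.mean() == pytest.approx(expected, abs=0.005)

    def test_secondary_outcome_conditionally_independent(self, big_cohort):
        # within each stratum of Y, Y' must carry no association with X or E
        d = big_cohort
        df = d.to_frame()
        for y_val in (0, 1):
            sub = df[df["y"] == y_val]
            import statsmodels.api as sm

            design = np.column_stack(
                [np.ones(len(sub)), sub["x"].to_numpy(), sub["e"].to_numpy()]
            )
            res = sm.Logit(sub["y_sec"].to_numpy(), design).fit(disp=0)
            for coef, se in zip(res.params[1:], res.bse[1:]):
                assert abs(coef) < 4 * se

    def test_parameter_recovery_large_sample(self):
        cfg = DGPConfig(n=500_000, seed=99)
        d = generate_complete(cfg)
        fit = fit_substantive(d.to_frame())
        truth = {"beta1": cfg.beta1, "beta2": cfg.beta2, "beta3": cfg.beta3}
        for p, z in truth.items():
            assert abs(fit.params[p] - z) < 4 * fit.ses[p]

    def test_csv_roundtrip(self, tmp_path, default_config):
        d = generate_complete(default_config, 8)
        data_path = tmp_path / "cohort.csv"
        cfg_path = tmp_path / "cohort.yaml"
        d.to_csv(data_path, cfg_path)
        back = type(d).from_csv(data_path, cfg_path)
        np.testing.assert_allclose(back.x, d.x, rtol=1e-12)
        assert np.array_equal(back.y, d.y)
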