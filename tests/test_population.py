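"""Covariate models, random-effect sampling, residual error, baselines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icpkpd.params import ParameterError, VariabilitySpec
from icpkpd.population import (CovariateVector, apply_covariates,
                               apply_residual_error, baseline_r0,
                               individualize, sample_etas, sample_individual,
                               sample_population)


class TestCovariates:
    def test_male_ftc_central_volume(self, ftc, chains):
        """Males carry a 24.4% larger FTC central volume (99.4 + 24.3*sex)."""
        out = apply_covariates(ftc, CovariateVector(sex=1),
                               chains["FTC"].covariate_effects)
        assert out.plasma.Vc_F == pytest.approx(123.7)
        assert out.plasma.Vc_F / ftc.plasma.Vc_F - 1 == pytest.approx(0.244, abs=0.001)

    def test_hiv_ftc_formation_rate(self, ftc, chains):
        """HIV-positive subjects form FTC-TP 75.2% faster (41.6 + 31.3*hiv)."""
        out = apply_covariates(ftc, CovariateVector(hiv=1),
                               chains["FTC"].covariate_effects)
        assert out.ic.Kf == pytest.approx(72.9)
        assert out.ic.Kf / ftc.ic.Kf - 1 == pytest.approx(0.752, abs=0.001)

    def test_reference_subject_unchanged(self, ftc, chains):
        out = apply_covariates(ftc, CovariateVector(sex=0, hiv=0),
                               chains["FTC"].covariate_effects)
        assert out.plasma.Vc_F == ftc.plasma.Vc_F
        assert out.ic.Kf == ftc.ic.Kf

    def test_negative_result_rejected(self, ftc, chains):
        effects = [type(chains["FTC"].covariate_effects[0])(
            "plasma.Vc_F", "sex", -200.0)]
        with pytest.raises(ParameterError):
            apply_covariates(ftc, CovariateVector(sex=1), effects)

    def test_covariate_values_validated(self):
        with pytest.raises(ParameterError):
            CovariateVector(sex=2)


class TestIIVSampling:
    def test_zero_variance_gives_typical(self, tfv_cfg_deterministic):
        subj = sample_individual(tfv_cfg_deterministic, CovariateVector(),
                                 np.random.default_rng(0))
        assert subj.params["TFV"].plasma.CL_F == 1410.0

    def test_seed_determinism(self, tfv_cfg):
        a = sample_individual(tfv_cfg, CovariateVector(), np.random.default_rng(5))
        b = sample_individual(tfv_cfg, CovariateVector(), np.random.default_rng(5))
        assert a.etas == b.etas
        assert a.params["TFV"].plasma.CL_F == b.params["TFV"].plasma.CL_F

    def test_lognormal_median_equals_typical(self, tfv_cfg):
        """Median of exp(eta) draws is 1 within 1% at n = 1e5 (lognormal IIV
        leaves the population median at the typical value)."""
        rng = np.random.default_rng(123)
        w2 = tfv_cfg.variability.omega2["ic.Kf"]
        draws = np.exp(rng.normal(0.0, np.sqrt(w2), size=100_000))
        assert np.median(draws) == pytest.approx(1.0, rel=0.01)
        # the printed %CV convention for this variance
        assert 100 * np.sqrt(0.288) == pytest.approx(53.7, abs=0.1)

    def test_population_reproducible_and_sized(self, tfv_cfg):
        pop1 = sample_population(50, [tfv_cfg], seed=9)
        pop2 = sample_population(50, [tfv_cfg], seed=9)
        assert [s.params["TFV"].ic.Kf for s in pop1] == \
               [s.params["TFV"].ic.Kf for s in pop2]
        assert len({s.id for s in pop1}) == 50

    def test_population_covariate_mix(self, ftc_cfg):
        pop = sample_population(400, [ftc_cfg], seed=2, p_male=0.675, hiv=0)
        frac_male = np.mean([s.covariates.sex for s in pop])
        assert frac_male == pytest.approx(0.675, abs=0.08)
        assert all(s.covariates.hiv == 0 for s in pop)

    def test_individualize_applies_exp_eta(self, tfv):
        out = individualize(tfv, {"plasma.CL_F": np.log(2.0)})
        assert out.plasma.CL_F == pytest.approx(2820.0)


class TestResidualError:
    def test_zero_variance_identity(self, tfv_cfg):
        var = tfv_cfg.variability
        var.sigma2["TFV"] = 0.0
        y, clipped = apply_residual_error(100.0, "TFV", var, np.random.default_rng(0))
        assert y == 100.0 and not clipped

    def test_exponential_cv_matches_printed_value(self, tfv_cfg):
        """Plasma TFV exponential error, sigma^2 = 0.0745: the empirical CV of
        y/pred over 1e5 draws sits at the printed ~27.3%."""
        rng = np.random.default_rng(7)
        ys = np.array([apply_residual_error(1.0, "TFV", tfv_cfg.variability, rng)[0]
                       for _ in range(100_000)])
        cv = ys.std() / ys.mean()
        assert cv * 100 == pytest.approx(27.3, abs=1.0)
        # unbiased on the log scale
        assert np.mean(np.log(ys)) == pytest.approx(0.0, abs=0.005)

    def test_proportional_clips_and_flags(self):
        var = VariabilitySpec(sigma2={"TFVDP": 4.0},
                              error_model={"TFVDP": "proportional"})
        rng = np.random.default_rng(11)
        out = [apply_residual_error(10.0, "TFVDP", var, rng) for _ in range(2000)]
        clipped = [y for y, f in out if f]
        assert len(clipped) > 0
        assert all(y == 0.0 for y in clipped)
        assert min(y for y, _ in out) >= 0.0

    def test_proportional_unbiased_linear_scale(self, tfv_cfg):
        rng = np.random.default_rng(3)
        ys = np.array([apply_residual_error(50.0, "TFVDP", tfv_cfg.variability,
                                            rng)[0] for _ in range(50_000)])
        assert ys.mean() == pytest.approx(50.0, rel=0.01)

    def test_exponential_requires_positive_prediction(self, tfv_cfg):
        with pytest.raises(ValueError):
            apply_residual_error(0.0, "TFV", tfv_cfg.variability,
                                 np.random.default_rng(0))

    def test_unknown_stream(self, tfv_cfg):
        with pytest.raises(KeyError):
            apply_residual_error(1.0, "XXX", tfv_cfg.variability,
                                 np.random.default_rng(0))


class TestBaselineShrinkage:
    def test_no_iiv_collapses_to_population(self):
        assert baseline_r0(155.0, 200.0, omega2=0.0, sigma2=0.258) == 155.0

    def test_no_noise_trusts_observation(self):
        assert baseline_r0(155.0, 200.0, omega2=0.22, sigma2=0.0) == 200.0

    def test_weighted_mean_hand_arithmetic(self):
        """dATP-like inputs: weights 0.258/0.478 and 0.220/0.478."""
        got = baseline_r0(155.0, 200.0, omega2=0.220, sigma2=0.258, eta_rv=0.0)
        expect = 155.0 * (0.258 / 0.478) + 200.0 * (0.220 / 0.478)
        assert got == pytest.approx(expect, rel=1e-12)
        assert got == pytest.approx(175.71, abs=0.01)

    def test_missing_observation_falls_back(self):
        got = baseline_r0(155.0, None, omega2=0.22, sigma2=0.258, eta_rv=0.1)
        assert got == pytest.approx(155.0 * np.exp(0.1))

    def test_degenerate_variances_rejected(self):
        with pytest.raises(ValueError):
            baseline_r0(155.0, 200.0, omega2=0.0, sigma2=0.0)

    @settings(derandomize=True, max_examples=200)
    @given(pop=st.floats(10.0, 1000.0), obs=st.floats(10.0, 1000.0),
           w2=st.floats(1e-6, 3.0), s2=st.floats(1e-6, 3.0))
    def test_interpolates_between_population_and_observation(self, pop, obs, w2, s2):
        """With eta = 0 the estimate always lies between the population-only
        and observation-only limits."""
        got = baseline_r0(pop, obs, w2, s2, eta_rv=0.0)
        lo, hi = min(pop, obs), max(pop, obs)
        assert lo - 1e-9 <= got <= hi + 1e-9
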