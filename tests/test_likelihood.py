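import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import poisson

from gai import (FittedModel, FormulaSpec, ModelConfig, ParameterMapper,
                 SiteTotalSpec, SurveyData, TruthConfig, aic,
                 concentrate_site_total, fit_gai, nb_loglik,
                 poisson_concentrated_loglik, simulate_survey, summary,
                 transform_starting_values, zip_loglik)
from gai.likelihood import _dist_loglik, curve_matrix
from gai.links import ConfigurationError


def make_data(counts, occasions=None, covariates=None):
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    occ = occasions if occasions is not None else np.arange(1, counts.shape[1] + 1)
    sites = [f"s{i}" for i in range(counts.shape[0])]
    return SurveyData(sites, occ, counts, covariates)


class TestConcentration:
    @pytest.mark.parametrize("y,a,expected", [
        ([2, 4, 6], [0.2, 0.3, 0.5], 12.0),
        ([2, 4, 6], [0.1, 0.2, 0.3], 20.0),
        ([2, np.nan, 6], [0.2, 0.3, 0.5], 8 / 0.7),
    ])
    def test_scaled_site_totals(self, y, a, expected):
        assert concentrate_site_total(y, a) == pytest.approx(expected, abs=1e-5)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="no observed"):
            concentrate_site_total([np.nan, np.nan], [0.5, 0.5])

    def test_zero_curve_mass_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            concentrate_site_total([1.0, np.nan], [0.0, 1.0])


class TestPoissonProfile:
    def test_termwise_poisson_logpmf(self):
        # one site, frozen curve a = (1/3, 2/3): concentration gives N = 3,
        # lambda = (1, 2), and the kernel must match the Poisson log-pmf sum
        data = make_data([[1, 2]])
        cfg = ModelConfig(family="mixture", B=1)
        mapper = ParameterMapper(cfg, None)
        a = np.array([1 / 3, 2 / 3])
        N = concentrate_site_total([1, 2], a)
        assert N == pytest.approx(3.0)
        lam = N * a
        assert poisson.logpmf([1, 2], lam).sum() == pytest.approx(-2.30685, abs=1e-5)
        ll = _dist_loglik(
            transform_starting_values({"mu": [2.0], "sigma": 1.0, "w": [1.0]},
                                      cfg).theta,
            [3.0], data, cfg, mapper, "poisson")
        assert np.isfinite(ll)

    def test_all_zero_site_contributes_nothing(self):
        data = make_data([[0, 0, 0], [1, 2, 1]])
        cfg = ModelConfig(family="mixture", B=1)
        mapper = ParameterMapper(cfg, None)
        theta = transform_starting_values({"mu": [2.0], "sigma": 1.0, "w": [1.0]}, cfg).theta
        ll_both = poisson_concentrated_loglik(theta, data, cfg, mapper)
        ll_one = poisson_concentrated_loglik(theta, make_data([[1, 2, 1]]), cfg,
                                             ParameterMapper(cfg, None))
        assert ll_both == pytest.approx(ll_one, abs=1e-12)

    def test_profile_equals_joint_maximisation_over_totals(self):
        rng = np.random.default_rng(8)
        cfg = ModelConfig(family="mixture", B=1)
        for _ in range(10):
            S, T = rng.integers(2, 5), rng.integers(3, 8)
            counts = rng.poisson(5.0, size=(S, T)).astype(float)
            counts[rng.uniform(size=(S, T)) < 0.2] = np.nan
            counts[:, 0] = rng.poisson(5.0, S)  # keep every site observed once
            data = make_data(counts)
            mapper = ParameterMapper(cfg, None)
            theta = np.array([np.log(rng.uniform(1, T)), np.log(rng.uniform(0.5, 3))])
            profile = poisson_concentrated_loglik(theta, data, cfg, mapper)
            a = curve_matrix(theta, mapper, cfg, data.occasions, S)
            joint = 0.0
            for i in range(S):
                obs = data.observed[i]
                y, ai = counts[i, obs], a[i, obs]

                def neg(N):
                    lam = N * ai
                    return -(y * np.log(lam) - lam - gammaln(y + 1)).sum()

                res = minimize_scalar(neg, bounds=(1e-6, 10 * y.sum() / ai.sum()),
                                      method="bounded", options={"xatol": 1e-12})
                joint += -res.fun
            assert profile == pytest.approx(joint, abs=1e-8)


class TestAlternativeDistributions:
    def test_zip_with_zero_inflation_zero_equals_poisson(self):
        data = make_data([[0, 3, 5, 1], [2, 2, 0, 0]])
        cfg_zip = ModelConfig(family="mixture", B=1, distribution="zip", fix_psi=0.0)
        cfg_p = ModelConfig(family="mixture", B=1)
        mapper_zip = ParameterMapper(cfg_zip, None)
        mapper_p = ParameterMapper(cfg_p, None)
        theta = transform_starting_values({"mu": [2.5], "sigma": 1.2, "w": [1.0]},
                                          cfg_zip).theta
        N = [9.0, 4.0]
        ll_zip = zip_loglik(theta, N, data, cfg_zip, mapper_zip)
        ll_p = _dist_loglik(theta, N, data, cfg_p, mapper_p, "poisson")
        assert ll_zip == pytest.approx(ll_p, abs=1e-12)

    def test_nb_poisson_limit(self):
        data = make_data([[1, 2]])
        cfg = ModelConfig(family="mixture", B=1, distribution="nb", fix_r=1e8)
        mapper = ParameterMapper(cfg, None)
        # choose curve params, then pick N so lambda hits (1, 2) exactly
        theta = transform_starting_values({"mu": [2.0], "sigma": 1.0, "w": [1.0]},
                                          cfg).theta
        a = curve_matrix(theta, mapper, cfg, data.occasions, 1)[0]
        N = 2.0 / a[1]
        ll_nb = nb_loglik(theta, [N], data, cfg, mapper)
        ll_p = _dist_loglik(theta, [N], data, cfg, mapper, "poisson")
        assert ll_nb == pytest.approx(ll_p, abs=1e-5)

    def test_zip_zero_count_worked_value(self):
        data = make_data([[0]], occasions=[1])
        cfg = ModelConfig(family="spline", spline_df=4, distribution="zip",
                          fix_psi=0.5)
        mapper = ParameterMapper(cfg, None)
        theta = np.zeros(mapper.n_params)  # uniform curve over T=1 -> a = 1
        ll = zip_loglik(theta, [1.0], data, cfg, mapper)
        assert ll == pytest.approx(np.log(0.5 + 0.5 * np.exp(-1.0)), abs=1e-10)

    def test_invalid_dispersion_gives_minus_inf(self):
        data = make_data([[1, 2]])
        cfg = ModelConfig(family="mixture", B=1, distribution="nb", fix_r=-1.0)
        mapper = ParameterMapper(cfg, None)
        theta = transform_starting_values({"mu": [1.5], "sigma": 1.0, "w": [1.0]},
                                          cfg).theta
        assert nb_loglik(theta, [3.0], data, cfg, mapper) == -np.inf


class TestFitGai:
    def test_recovers_single_brood_truth(self, univoltine_fit, univoltine_truth):
        sp = univoltine_fit.mapper.to_natural(univoltine_fit.theta_hat)
        assert sp.mu[0, 0] == pytest.approx(univoltine_truth.mu[0], abs=0.5)
        assert sp.sigma[0, 0] == pytest.approx(univoltine_truth.sigma[0], abs=0.5)
        assert univoltine_fit.converged

    def test_loglik_at_optimum_dominates_truth(self, univoltine_survey, univoltine_fit):
        data, record = univoltine_survey
        cfg = univoltine_fit.config
        ll_truth = poisson_concentrated_loglik(np.asarray(record["theta"]), data, cfg)
        assert univoltine_fit.loglik >= ll_truth - 1e-6

    def test_nested_model_dominance(self, univoltine_survey):
        data, _ = univoltine_survey
        f1 = fit_gai(data, ModelConfig(family="mixture", B=1))
        f2 = fit_gai(data, ModelConfig(family="mixture", B=2))
        assert f2.loglik >= f1.loglik - 1e-4

    def test_spline_fit_runs_and_curve_sums_to_one(self, univoltine_survey):
        data, _ = univoltine_survey
        fit = fit_gai(data, ModelConfig(family="spline", spline_df=8))
        assert fit.converged
        np.testing.assert_allclose(fit.a_matrix.sum(axis=1), 1.0, atol=1e-10)
        assert fit.n_params == 7

    def test_nb_outer_iterations_never_decrease_loglik(self):
        truth = TruthConfig(S=15, T=20, family="mixture", B=1, mu=(10.0,),
                            sigma=(2.0,), w=(1.0,), distribution="nb", r=1.5,
                            site_total=SiteTotalSpec("constant", 100.0), seed=9)
        data, _ = simulate_survey(truth)
        cfg = truth.model_config()
        mapper = ParameterMapper(cfg, None)
        fit = fit_gai(data, cfg)
        assert fit.converged
        # ascend check: loglik at the fit beats the Poisson-initialised state
        start = transform_starting_values(
            {"mu": [10.0], "sigma": 2.0, "w": [1.0], "r": 1.5}, cfg).theta
        ll_start = nb_loglik(start, fit.site_totals, data, cfg, mapper)
        assert fit.loglik >= ll_start - 1e-6

    @pytest.mark.parametrize("config,expected_n", [
        (ModelConfig(family="mixture", B=1), 2),
        (ModelConfig(family="mixture", B=2), 4),
        (ModelConfig(family="mixture", B=3), 6),
        (ModelConfig(family="mixture", B=3, distribution="zip"), 7),
        (ModelConfig(family="mixture", B=3, distribution="nb"), 7),
        (ModelConfig(family="mixture", B=3, distribution="nb",
                     sigma_mode="per_brood"), 9),
    ])
    def test_parameter_counts_by_model_shape(self, config, expected_n):
        mapper = ParameterMapper(config, None)
        assert mapper.n_params == expected_n

    def test_aic_arithmetic(self, univoltine_fit):
        assert aic(univoltine_fit) == pytest.approx(
            2 * univoltine_fit.n_params - 2 * univoltine_fit.loglik)

    def test_summary_reports_se_from_vcov(self, univoltine_fit):
        tab = summary(univoltine_fit)
        assert list(tab["parameter"]) == univoltine_fit.param_names
        np.testing.assert_allclose(
            tab["se"], np.sqrt(np.diag(univoltine_fit.vcov)), atol=1e-12)

    def test_bad_start_length_rejected(self, univoltine_survey):
        data, _ = univoltine_survey
        with pytest.raises(ConfigurationError, match="starting vector"):
            fit_gai(data, ModelConfig(family="mixture", B=1), start=np.zeros(5))

    def test_json_round_trip(self, tmp_path, univoltine_survey, univoltine_fit):
        data, _ = univoltine_survey
        path = tmp_path / "fit.json"
        univoltine_fit.to_json(path)
        back = FittedModel.from_json(path, data)
        np.testing.assert_allclose(back.theta_hat, univoltine_fit.theta_hat)
        assert back.aic == pytest.approx(univoltine_fit.aic)
        np.testing.assert_allclose(back.a_matrix, univoltine_fit.a_matrix)


class TestModelConfigValidation:
    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(family="fourier")

    def test_spline_forbids_formulas(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(family="spline", formulas=FormulaSpec(mu="northing"))

    def test_b_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(B=0)
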