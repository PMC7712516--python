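import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats
from scipy.special import expit

from sf6dbeta.models import (
    BETA,
    LINEAR,
    ModelData,
    ModelSpec,
    ParameterState,
    beta_log_density,
    beta_moments,
    initial_state,
    linear_predictor,
    log_posterior,
    mean_response,
)


class TestModelSpec:
    def test_six_canonical_names(self):
        spec = ModelSpec.from_name("BR+RE")
        assert spec.family == BETA and spec.random_effects and not spec.covariates
        assert spec.name == "BR+RE"
        assert ModelSpec.from_name("LR+RE+COV").design_columns()[-1] == "MS2"
        assert len(ModelSpec.from_name("LR").design_columns()) == 26

    def test_unknown_name_lists_valid_ones(self):
        with pytest.raises(ValueError, match="LR\\+RE\\+COV"):
            ModelSpec.from_name("BR+COV")

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(family="beta", prior_ig_shape=0.0)
        with pytest.raises(ValueError):
            ModelSpec(family="poisson")


class TestBetaLogDensity:
    def test_uniform_case(self):
        # Beta(1,1): mu=0.5, phi=2
        assert beta_log_density(0.3, 0.5, 2.0) == pytest.approx(0.0)

    def test_beta22_mode(self):
        # Beta(2,2) density at 0.5 is Gamma(4)/Gamma(2)^2 * 0.25 = 1.5
        assert beta_log_density(0.5, 0.5, 4.0) == pytest.approx(np.log(1.5))

    @pytest.mark.parametrize("y, mu, phi", [(0.0, 0.5, 2), (1.0, 0.5, 2), (0.5, 0.0, 2), (0.5, 0.5, 0.0)])
    def test_boundaries_rejected(self, y, mu, phi):
        with pytest.raises(ValueError):
            beta_log_density(y, mu, phi)

    @pytest.mark.parametrize("mu, phi", [(0.2, 0.8), (0.5, 4.0), (0.9, 25.0)])
    def test_normalization(self, mu, phi):
        total, _ = integrate.quad(lambda y: np.exp(beta_log_density(y, mu, phi)), 0, 1)
        assert total == pytest.approx(1.0, abs=1e-6)


class TestBetaMoments:
    def test_formula(self):
        assert beta_moments(0.5, 9.0) == pytest.approx((0.5, 0.025))

    def test_variance_monotone_in_phi(self):
        variances = [beta_moments(0.5, phi)[1] for phi in (1, 5, 50, 5000)]
        assert variances == sorted(variances, reverse=True)
        assert variances[-1] < 1e-4

    def test_monte_carlo_oracle(self):
        rng = np.random.default_rng(0)
        mu, phi = 0.7, 10.0
        draws = rng.beta(mu * phi, (1 - mu) * phi, size=100_000)
        assert draws.var() == pytest.approx(0.21 / 11, rel=0.05)

    def test_range_violations(self):
        with pytest.raises(ValueError):
            beta_moments(1.0, 5.0)
        with pytest.raises(ValueError):
            beta_moments(0.5, -1.0)


class TestLinearPredictor:
    def test_reference_intercept_maps_through_logit(self):
        # a BR+RE intercept of 2.175 puts full health at expit(2.175) ~ 0.898
        eta = linear_predictor(np.zeros(25), np.array([2.175] + [0.0] * 25))
        assert mean_response(eta, BETA) == pytest.approx(0.898, abs=5e-4)
        assert mean_response(eta, LINEAR) == pytest.approx(2.175)

    def test_zero_coefficients(self):
        eta = linear_predictor(np.zeros(25), np.zeros(26))
        assert mean_response(eta, BETA) == pytest.approx(0.5)
        assert mean_response(eta, LINEAR) == 0.0

    def test_negative_dummy_decreases_mu(self):
        beta = np.array([2.175] + [0.0] * 25)
        worse = beta.copy()
        worse[1] = -0.5
        x = np.zeros(25)
        x[0] = 1.0
        assert mean_response(linear_predictor(x, worse), BETA) < mean_response(
            linear_predictor(x, beta), BETA
        )

    def test_random_intercept_added(self):
        assert linear_predictor(np.zeros(25), np.ones(26), b_i=0.5) == 1.5

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            linear_predictor(np.zeros(10), np.zeros(26))


def _toy_frame():
    rng = np.random.default_rng(4)
    codes = ["111111", "211111", "645655", "321122", "121212"]
    rows = []
    for rid in (1, 2, 3):
        for code in codes[: 3 + rid % 2]:
            rows.append(
                {
                    "respondent_id": rid,
                    "state_code": code,
                    "y": float(rng.uniform(0.1, 0.9)),
                    "AGE": 30.0 + rid,
                    "GENDER": float(rid % 2),
                    "DEGREE": 0.0,
                    "HOUSING1": 1.0,
                    "HOUSING2": 0.0,
                    "INCOME1": 0.0,
                    "INCOME2": 1.0,
                    "MS1": 0.0,
                    "MS2": 0.0,
                }
            )
    return pd.DataFrame(rows)


def _oracle_log_posterior(spec, params, data):
    """Direct-summation oracle built on scipy.stats, independent of the package's math."""
    lp = 0.0
    eta = data.X @ params.beta
    if spec.random_effects:
        eta = eta + params.b[data.resp_codes]
    if spec.family == BETA:
        mu = expit(eta)
        for yi, mi in zip(data.y, mu):
            lp += stats.beta.logpdf(yi, mi * params.phi, (1 - mi) * params.phi)
    else:
        for yi, ei in zip(data.y, eta):
            lp += stats.norm.logpdf(yi, ei, np.sqrt(params.sigma2_eps))
    for bj in params.beta:
        lp += stats.norm.logpdf(bj, 0, np.sqrt(spec.prior_beta_variance))
    if spec.family == BETA:
        lp += stats.invgamma.logpdf(params.phi, spec.prior_ig_shape, scale=spec.prior_ig_rate)
    else:
        lp += stats.invgamma.logpdf(params.sigma2_eps, spec.prior_ig_shape, scale=spec.prior_ig_rate)
    if spec.random_effects:
        for bi in params.b:
            lp += stats.norm.logpdf(bi, 0, np.sqrt(params.sigma2_b))
        lp += stats.invgamma.logpdf(params.sigma2_b, spec.prior_ig_shape, scale=spec.prior_ig_rate)
    return lp


class TestLogPosterior:
    @pytest.mark.parametrize("name", ["BR", "BR+RE", "LR+RE", "LR+RE+COV", "BR+RE+COV"])
    def test_matches_direct_summation_oracle(self, name):
        spec = ModelSpec.from_name(name)
        data = ModelData.from_dataframe(_toy_frame(), spec)
        rng = np.random.default_rng(9)
        p = len(spec.design_columns())
        params = ParameterState(
            beta=rng.normal(0, 0.3, p),
            phi=8.0 if spec.family == BETA else None,
            sigma2_eps=0.05 if spec.family == LINEAR else None,
            sigma2_b=0.2 if spec.random_effects else None,
            b=rng.normal(0, 0.3, data.n_respondents) if spec.random_effects else None,
        )
        got = log_posterior(spec, params, data)
        assert got == pytest.approx(_oracle_log_posterior(spec, params, data), abs=1e-8)

    def test_single_beta_record_reduces_to_density_plus_priors(self):
        spec = ModelSpec.from_name("BR")
        df = _toy_frame().iloc[:1]
        data = ModelData.from_dataframe(df, spec)
        params = ParameterState(beta=np.zeros(26), phi=5.0)
        got = log_posterior(spec, params, data)
        assert got == pytest.approx(_oracle_log_posterior(spec, params, data), abs=1e-10)

    def test_variance_in_prior_tail_lowers_posterior(self):
        spec = ModelSpec.from_name("BR+RE")
        data = ModelData.from_dataframe(_toy_frame(), spec)
        base = ParameterState(beta=np.zeros(26), phi=5.0, sigma2_b=1.0, b=np.zeros(data.n_respondents))
        lps = []
        for s2 in (1.0, 1e4, 1e8):
            lps.append(log_posterior(spec, ParameterState(base.beta, 5.0, None, s2, base.b), data))
        assert lps[0] > lps[1] > lps[2]

    def test_invalid_support_rejected(self):
        spec = ModelSpec.from_name("BR")
        data = ModelData.from_dataframe(_toy_frame(), spec)
        with pytest.raises(ValueError):
            log_posterior(spec, ParameterState(beta=np.zeros(26), phi=-1.0), data)


class TestAlternativePriors:
    def test_flat_sigma_prior_density(self):
        from sf6dbeta.models import log_prior_variance

        spec = ModelSpec(family=LINEAR, sigma_prior="flat_sigma")
        # p(sigma^2) proportional to 1/sigma
        assert log_prior_variance(4.0, spec) - log_prior_variance(1.0, spec) == pytest.approx(
            -0.5 * np.log(4.0)
        )

    def test_phi_uniform_squared_support_and_shape(self):
        from sf6dbeta.models import log_prior_phi

        spec = ModelSpec(family=BETA, phi_prior="uniform_squared", phi_prior_bound=50.0)
        assert np.isneginf(log_prior_phi(2501.0, spec))  # beyond a^2
        # density proportional to phi^(-1/2) inside the support
        assert log_prior_phi(4.0, spec) - log_prior_phi(1.0, spec) == pytest.approx(
            -0.5 * np.log(4.0)
        )
        # matches the exact U(0, a) push-forward density at phi = u^2
        assert log_prior_phi(9.0, spec) == pytest.approx(np.log(1.0 / (2.0 * 50.0 * 3.0)))

    def test_invalid_prior_names_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(family=BETA, phi_prior="jeffreys")
        with pytest.raises(ValueError):
            ModelSpec(family=LINEAR, sigma_prior="half_cauchy")


class TestModelData:
    def test_boundary_values_rejected_for_beta_family(self):
        df = _toy_frame()
        df.loc[0, "y"] = 1.0
        with pytest.raises(ValueError, match="0 < y < 1"):
            ModelData.from_dataframe(df, ModelSpec.from_name("BR"))

    def test_boundary_compression_switch(self):
        df = _toy_frame()
        df.loc[0, "y"] = 1.0
        data = ModelData.from_dataframe(df, ModelSpec.from_name("BR"), boundary_policy="compress")
        assert np.all((data.y > 0) & (data.y < 1))

    def test_linear_family_accepts_boundary_values(self):
        df = _toy_frame()
        df.loc[0, "y"] = 1.0
        data = ModelData.from_dataframe(df, ModelSpec.from_name("LR"))
        assert data.y.max() == 1.0

    def test_respondents_contiguous_and_sorted(self):
        spec = ModelSpec.from_name("BR+RE")
        data = ModelData.from_dataframe(_toy_frame().sample(frac=1, random_state=0), spec)
        assert np.all(np.diff(data.resp_codes) >= 0)
        assert data.n_respondents == 3

    def test_covariates_required_for_cov_models(self):
        df = _toy_frame().drop(columns=["AGE"])
        with pytest.raises(ValueError, match="profiles"):
            ModelData.from_dataframe(df, ModelSpec.from_name("BR+RE+COV"))


class TestInitialization:
    def test_first_chain_deterministic_anchor(self):
        spec = ModelSpec.from_name("BR+RE")
        data = ModelData.from_dataframe(_toy_frame(), spec)
        state = initial_state(spec, data, np.random.default_rng(0), chain_index=0)
        assert state.beta[0] == pytest.approx(np.log(data.y.mean() / (1 - data.y.mean())))
        assert np.all(state.beta[1:] == 0)
        assert state.phi == 10.0 and state.sigma2_b == 0.1

    def test_later_chains_overdispersed_but_finite(self):
        spec = ModelSpec.from_name("BR+RE")
        data = ModelData.from_dataframe(_toy_frame(), spec)
        s0 = initial_state(spec, data, np.random.default_rng(1), chain_index=0)
        s1 = initial_state(spec, data, np.random.default_rng(1), chain_index=1)
        assert not np.allclose(s0.beta, s1.beta)
        assert np.isfinite(log_posterior(spec, s1, data))
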