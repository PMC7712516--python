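"""Model specifications, likelihoods and log-posteriors.

Six model variants are fitted to adjusted SG utilities y:

* linear regression (LR):      y_i = x_i'β + ε_i,  ε_i ~ N(0, σ₂²)
* beta regression (BR):        y_i ~ Beta(μ_i φ, (1−μ_i) φ),
                               logit(μ_i) = x_i'β,  Var(y_i) = μ(1−μ)/(1+φ)

each optionally with a per-respondent random intercept b_i ~ N(0, σ₁²) added
to the linear predictor (before the logit in the beta family), and optionally
with respondent covariates appended to x.

Default priors are vague: β ~ N(0, 10⁶) componentwise, and inverse-gamma
IG(0.001, 0.001) on σ₁², σ₂² and φ.  Two alternative weakly-informative
choices are available: a flat prior on σ (p(σ²) ∝ σ⁻¹) for the variance
components, and φ = U² with U ~ Uniform(0, a) for the precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from .states import DESIGN_COLUMNS, design_vector, parse_state_code
from .preprocessing import COVARIATE_COLUMNS

LINEAR = "linear"
BETA = "beta"

IG_PRIOR = "inverse_gamma"
FLAT_SIGMA = "flat_sigma"
PHI_UNIFORM_SQUARED = "uniform_squared"

#: The six model labels used throughout (CLI, reports).
MODEL_NAMES: tuple[str, ...] = ("LR", "BR", "LR+RE", "BR+RE", "LR+RE+COV", "BR+RE+COV")


@dataclass(frozen=True)
class ModelSpec:
    """Family, effect structure and prior hyperparameters of one model."""

    family: str
    random_effects: bool = False
    covariates: bool = False
    prior_beta_variance: float = 1e6
    prior_ig_shape: float = 0.001
    prior_ig_rate: float = 0.001
    sigma_prior: str = IG_PRIOR  # or FLAT_SIGMA, for sigma2_b and sigma2_eps
    phi_prior: str = IG_PRIOR  # or PHI_UNIFORM_SQUARED
    phi_prior_bound: float = 50.0  # the "a" of phi = U^2, U ~ U(0, a)

    def __post_init__(self) -> None:
        if self.family not in (LINEAR, BETA):
            raise ValueError(f"family must be '{LINEAR}' or '{BETA}'")
        if min(self.prior_beta_variance, self.prior_ig_shape, self.prior_ig_rate) <= 0:
            raise ValueError("prior hyperparameters must be strictly positive")
        if self.sigma_prior not in (IG_PRIOR, FLAT_SIGMA):
            raise ValueError("sigma_prior must be 'inverse_gamma' or 'flat_sigma'")
        if self.phi_prior not in (IG_PRIOR, PHI_UNIFORM_SQUARED):
            raise ValueError("phi_prior must be 'inverse_gamma' or 'uniform_squared'")

    @classmethod
    def from_name(cls, name: str, **kwargs) -> "ModelSpec":
        """Build a spec from one of the six canonical labels (e.g. 'BR+RE')."""
        table = {
            "LR": dict(family=LINEAR),
            "BR": dict(family=BETA),
            "LR+RE": dict(family=LINEAR, random_effects=True),
            "BR+RE": dict(family=BETA, random_effects=True),
            "LR+RE+COV": dict(family=LINEAR, random_effects=True, covariates=True),
            "BR+RE+COV": dict(family=BETA, random_effects=True, covariates=True),
        }
        if name not in table:
            raise ValueError(f"unknown model {name!r}; valid names: {', '.join(MODEL_NAMES)}")
        return cls(**{**table[name], **kwargs})

    @property
    def name(self) -> str:
        label = "LR" if self.family == LINEAR else "BR"
        if self.random_effects:
            label += "+RE"
        if self.covariates:
            label += "+COV"
        return label

    def design_columns(self) -> list[str]:
        cols = ["intercept", *DESIGN_COLUMNS]
        if self.covariates:
            cols += list(COVARIATE_COLUMNS)
        return cols


@dataclass
class ParameterState:
    """One point in parameter space: (β, φ or σ₂², σ₁², b)."""

    beta: np.ndarray
    phi: float | None = None  # beta family precision
    sigma2_eps: float | None = None  # linear family residual variance
    sigma2_b: float | None = None  # random-effect variance
    b: np.ndarray | None = None  # per-respondent random intercepts

    def copy(self) -> "ParameterState":
        return ParameterState(
            beta=self.beta.copy(),
            phi=self.phi,
            sigma2_eps=self.sigma2_eps,
            sigma2_b=self.sigma2_b,
            b=None if self.b is None else self.b.copy(),
        )


@dataclass
class ModelData:
    """Model-ready arrays: response, design matrix, respondent index.

    Rows are sorted by respondent so each respondent's records are contiguous
    (``resp_starts`` gives the slice starts, for fast per-respondent sums).
    """

    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    resp_codes: np.ndarray
    resp_ids: np.ndarray
    resp_starts: np.ndarray

    @property
    def n_records(self) -> int:
        return self.y.size

    @property
    def n_respondents(self) -> int:
        return self.resp_ids.size

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        spec: ModelSpec,
        boundary_policy: str = "error",
    ) -> "ModelData":
        """Assemble arrays from an adjusted-valuation table.

        For the beta family, responses must lie strictly in (0, 1);
        ``boundary_policy='compress'`` applies y' = (y(n−1)+0.5)/n first,
        ``'error'`` (default) rejects boundary values.
        """
        from .preprocessing import compress_to_open_interval

        df = data.sort_values("respondent_id", kind="stable").reset_index(drop=True)
        y = df["y"].to_numpy(dtype=float)
        if spec.family == BETA:
            if boundary_policy == "compress" and (np.any(y <= 0) or np.any(y >= 1)):
                y = compress_to_open_interval(y)
            if np.any(y <= 0) or np.any(y >= 1):
                raise ValueError(
                    "beta-family models require 0 < y < 1; preprocess boundary values "
                    "(boundary_policy='compress') or use the linear family"
                )
        n = len(df)
        X = np.empty((n, 1 + len(DESIGN_COLUMNS)), dtype=float)
        X[:, 0] = 1.0
        codes = df["state_code"].astype(str).to_numpy()
        cache: dict[str, np.ndarray] = {}
        for i, code in enumerate(codes):
            if code not in cache:
                cache[code] = design_vector(parse_state_code(code)).astype(float)
            X[i, 1:] = cache[code]
        columns = ["intercept", *DESIGN_COLUMNS]
        if spec.covariates:
            missing = set(COVARIATE_COLUMNS) - set(df.columns)
            if missing:
                raise ValueError(
                    f"covariate model requires respondent profiles; missing {sorted(missing)}"
                )
            X = np.hstack([X, df[list(COVARIATE_COLUMNS)].to_numpy(dtype=float)])
            columns += list(COVARIATE_COLUMNS)
        resp_codes, resp_ids = pd.factorize(df["respondent_id"], sort=True)
        resp_codes = np.asarray(resp_codes)
        resp_starts = np.searchsorted(resp_codes, np.arange(resp_ids.size))
        return cls(
            y=y,
            X=X,
            columns=columns,
            resp_codes=resp_codes,
            resp_ids=np.asarray(resp_ids),
            resp_starts=resp_starts,
        )


# ---------------------------------------------------------------------------
# densities


def beta_log_density(y, mu, phi):
    """Log density of Beta(μφ, (1−μ)φ) at y, the mean/precision form.

    All of y, μ must lie strictly in (0, 1) and φ > 0.  Vectorized with
    broadcasting.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(y <= 0) or np.any(y >= 1):
        raise ValueError("y must lie strictly in (0, 1)")
    if np.any(mu <= 0) or np.any(mu >= 1):
        raise ValueError("mu must lie strictly in (0, 1)")
    if np.any(phi <= 0):
        raise ValueError("phi must be > 0")
    a = mu * phi
    b = (1.0 - mu) * phi
    out = (
        gammaln(phi)
        - gammaln(a)
        - gammaln(b)
        + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-y)
    )
    return out if out.ndim else float(out)


def beta_moments(mu: float, phi: float) -> tuple[float, float]:
    """Mean and variance of the mean/precision beta: (μ, μ(1−μ)/(1+φ))."""
    if not 0 < mu < 1:
        raise ValueError("mu must lie strictly in (0, 1)")
    if phi <= 0:
        raise ValueError("phi must be > 0")
    return mu, mu * (1.0 - mu) / (1.0 + phi)


def linear_predictor(x, beta, b_i=0.0):
    """η = x'β (+ b_i).  ``x`` excludes the intercept column iff it has
    ``len(beta) - 1`` entries; otherwise dimensions must match exactly."""
    x = np.asarray(x, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if x.shape[-1] == beta.size - 1:
        x = np.concatenate([np.ones(x.shape[:-1] + (1,)), x], axis=-1)
    elif x.shape[-1] != beta.size:
        raise ValueError(f"dimension mismatch: x has {x.shape[-1]} entries, beta {beta.size}")
    return x @ beta + b_i


def mean_response(eta, family: str):
    """Map the linear predictor to the mean: inverse logit (beta) or identity."""
    return expit(eta) if family == BETA else np.asarray(eta, dtype=float)


# ---------------------------------------------------------------------------
# priors


def _log_ig(x: float, shape: float, rate: float) -> float:
    """Log density of InverseGamma(shape, rate) at x > 0 (normalized)."""
    return shape * np.log(rate) - gammaln(shape) - (shape + 1.0) * np.log(x) - rate / x


def log_prior_variance(x: float, spec: ModelSpec) -> float:
    """Log prior for a variance component (σ₁² or σ₂²)."""
    if x <= 0:
        raise ValueError("variance must be > 0")
    if spec.sigma_prior == FLAT_SIGMA:
        return -0.5 * np.log(x)  # p(sigma^2) ∝ 1/sigma, improper
    return _log_ig(x, spec.prior_ig_shape, spec.prior_ig_rate)


def log_prior_phi(phi: float, spec: ModelSpec) -> float:
    """Log prior for the beta-family precision φ."""
    if phi <= 0:
        raise ValueError("phi must be > 0")
    if spec.phi_prior == PHI_UNIFORM_SQUARED:
        a = spec.phi_prior_bound
        if phi >= a * a:
            return -np.inf
        return -np.log(2.0 * a) - 0.5 * np.log(phi)
    return _log_ig(phi, spec.prior_ig_shape, spec.prior_ig_rate)


def log_likelihood(spec: ModelSpec, params: ParameterState, data: ModelData) -> float:
    """Total log likelihood, conditional on random effects when present."""
    eta = data.X @ params.beta
    if spec.random_effects:
        if params.b is None:
            raise ValueError("random-effects model needs b")
        eta = eta + params.b[data.resp_codes]
    if spec.family == BETA:
        if params.phi is None:
            raise ValueError("beta family needs phi")
        return float(np.sum(beta_log_density(data.y, expit(eta), params.phi)))
    if params.sigma2_eps is None:
        raise ValueError("linear family needs sigma2_eps")
    resid = data.y - eta
    n = data.n_records
    return float(
        -0.5 * n * np.log(2.0 * np.pi * params.sigma2_eps)
        - 0.5 * np.sum(resid**2) / params.sigma2_eps
    )


def log_posterior(spec: ModelSpec, params: ParameterState, data: ModelData) -> float:
    """Unnormalized log posterior: likelihood + random-effect density + priors."""
    lp = log_likelihood(spec, params, data)
    tau2 = spec.prior_beta_variance
    lp += float(-0.5 * np.sum(params.beta**2) / tau2 - 0.5 * params.beta.size * np.log(2.0 * np.pi * tau2))
    if spec.family == BETA:
        lp += log_prior_phi(params.phi, spec)
    else:
        lp += log_prior_variance(params.sigma2_eps, spec)
    if spec.random_effects:
        if params.sigma2_b is None or params.b is None:
            raise ValueError("random-effects model needs sigma2_b and b")
        s2 = params.sigma2_b
        lp += float(
            -0.5 * params.b.size * np.log(2.0 * np.pi * s2) - 0.5 * np.sum(params.b**2) / s2
        )
        lp += log_prior_variance(s2, spec)
    return lp


def deviance(spec: ModelSpec, params: ParameterState, data: ModelData) -> float:
    """−2 × log likelihood (conditional on random effects)."""
    return -2.0 * log_likelihood(spec, params, data)


def initial_state(
    spec: ModelSpec,
    data: ModelData,
    rng: np.random.Generator,
    chain_index: int = 0,
) -> ParameterState:
    """Starting point: intercept at the (logit of the) grand mean, rest at 0.

    Chains beyond the first are overdispersed: N(0, 0.5²)·chain_index jitter
    on each coefficient and log-normal jitter on φ / variance components —
    broadly spread but finite starting values.
    """
    p = len(spec.design_columns())
    beta = np.zeros(p)
    grand = float(np.mean(data.y))
    if spec.family == BETA:
        grand = min(max(grand, 1e-6), 1 - 1e-6)
        beta[0] = float(logit(grand))
    else:
        beta[0] = grand
    phi = 10.0 if spec.family == BETA else None
    sigma2_eps = 0.1 if spec.family == LINEAR else None
    sigma2_b = 0.1 if spec.random_effects else None
    b = np.zeros(data.n_respondents) if spec.random_effects else None
    if chain_index > 0:
        scale = 0.5 * chain_index
        beta = beta + rng.normal(0.0, scale, size=p)
        if phi is not None:
            phi = float(phi * np.exp(rng.normal(0.0, scale)))
        if sigma2_eps is not None:
            sigma2_eps = float(sigma2_eps * np.exp(rng.normal(0.0, scale)))
        if sigma2_b is not None:
            sigma2_b = float(sigma2_b * np.exp(rng.normal(0.0, scale)))
    return ParameterState(beta=beta, phi=phi, sigma2_eps=sigma2_eps, sigma2_b=sigma2_b, b=b)
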