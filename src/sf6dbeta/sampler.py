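"""Metropolis-within-Gibbs sampler, convergence diagnostics and summaries.

The linear family is fully conjugate and is sampled by pure Gibbs: β given
the variances is multivariate normal, σ₂² and σ₁² given everything else are
inverse gamma, and the random intercepts b_i are normal.

The beta family has no conjugate blocks except σ₁² | b.  Its β coordinates,
log φ and the b_i are updated by adaptive Gaussian random-walk Metropolis:
one proposal scale per β coordinate and per block, tuned by Robbins–Monro
toward a 0.35 acceptance rate during burn-in and frozen afterwards.  φ and
the variance components are sampled on the log scale (with the Jacobian in
the acceptance ratio) so positivity never needs rejection.

Two (or more) chains are run from overdispersed starting points; convergence
is monitored with the Gelman–Rubin potential scale reduction factor R̂.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .models import (
    BETA,
    FLAT_SIGMA,
    LINEAR,
    ModelData,
    ModelSpec,
    ParameterState,
    initial_state,
    log_posterior,
    log_prior_phi,
)

RHAT_WARN = 1.1  # "about 1" made concrete


@dataclass(frozen=True)
class ChainConfig:
    """MCMC protocol: chain count, burn-in, retained draws, seed, tuning."""

    n_chains: int = 2
    burn_in: int = 5000
    n_samples: int = 10_000
    seed: int = 0
    initial_scale: float = 0.2  # starting random-walk sd for Metropolis blocks
    adapt_target: float = 0.35  # Robbins–Monro acceptance target
    beta_sweeps: int = 2  # Metropolis sweeps over beta per iteration (beta family)

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for the Gelman-Rubin diagnostic")
        if self.burn_in < 0 or self.n_samples < 1:
            raise ValueError("burn_in must be >= 0 and n_samples >= 1")


@dataclass
class PosteriorDraws:
    """Post-burn-in draws from all chains, plus the deviance trace."""

    spec: ModelSpec
    config: ChainConfig
    parameter_names: list[str]  # fixed-effect block: design columns + scale params
    draws: np.ndarray  # (n_chains, n_samples, n_fixed)
    deviance: np.ndarray  # (n_chains, n_samples)
    b_draws: np.ndarray | None = None  # (n_chains, n_samples, n_respondents)
    resp_ids: np.ndarray | None = None
    acceptance: list[dict] = field(default_factory=list)  # per chain, per block

    @property
    def n_beta(self) -> int:
        return len(self.spec.design_columns())

    @property
    def all_names(self) -> list[str]:
        names = list(self.parameter_names)
        if self.b_draws is not None:
            names += [f"b[{rid}]" for rid in self.resp_ids]
        return names

    def stacked(self, include_b: bool = True) -> np.ndarray:
        """(n_chains, n_samples, k) array over all monitored scalars."""
        if include_b and self.b_draws is not None:
            return np.concatenate([self.draws, self.b_draws], axis=2)
        return self.draws

    def pooled(self, name: str | None = None) -> np.ndarray:
        """Chains concatenated; a (N, k) matrix, or one column by name."""
        flat = self.stacked().reshape(-1, len(self.all_names))
        if name is None:
            return flat
        return flat[:, self.all_names.index(name)]

    def pooled_beta(self) -> np.ndarray:
        """(N, p) matrix of regression-coefficient draws, intercept first."""
        return self.draws.reshape(-1, self.draws.shape[2])[:, : self.n_beta]

    def posterior_mean_state(self, data: ModelData) -> ParameterState:
        """ParameterState at pooled posterior means (incl. random effects)."""
        means = self.pooled().mean(axis=0)
        names = self.all_names
        beta = means[: self.n_beta]
        get = lambda n: float(means[names.index(n)]) if n in names else None
        b = None
        if self.b_draws is not None:
            b = self.b_draws.reshape(-1, self.b_draws.shape[2]).mean(axis=0)
        return ParameterState(
            beta=beta,
            phi=get("phi"),
            sigma2_eps=get("sigma2_eps"),
            sigma2_b=get("sigma2_b"),
            b=b,
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Long table: one row per draw, columns per parameter + deviance."""
        n_chains, n_samples, _ = self.draws.shape
        flat = self.stacked().reshape(n_chains * n_samples, -1)
        df = pd.DataFrame(flat, columns=self.all_names)
        df.insert(0, "iteration", np.tile(np.arange(n_samples), n_chains))
        df.insert(0, "chain", np.repeat(np.arange(n_chains), n_samples))
        df["deviance"] = self.deviance.reshape(-1)
        return df


@dataclass
class FitSummary:
    """Posterior means, sds, 95% credible intervals, R̂ and DIC parts."""

    params: pd.DataFrame  # index: parameter; mean, sd, q2.5, q97.5, rhat, excludes_zero
    dbar: float | None = None
    p_d: float | None = None
    dic: float | None = None

    def to_json(self, path) -> None:
        import json

        payload = {
            "parameters": self.params.reset_index().to_dict(orient="records"),
            "dbar": self.dbar,
            "p_d": self.p_d,
            "dic": self.dic,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# diagnostics


def gelman_rubin(draws) -> pd.Series:
    """Potential scale reduction factor R̂, one value per monitored scalar.

    Classic between/within form: with m chains of n draws, W the mean
    within-chain variance and B/n the variance of the chain means,
    R̂ = sqrt(((n−1)/n · W + B/n) / W).  A parameter that is constant in
    every chain reports 1 by convention.
    """
    if isinstance(draws, PosteriorDraws):
        arr = draws.stacked()
        names = draws.all_names
    else:
        arr = np.asarray(draws, dtype=float)
        names = None
    if arr.ndim == 2:
        arr = arr[:, :, None]
    m, n, k = arr.shape
    if m < 2:
        raise ValueError("Gelman-Rubin needs at least 2 chains")
    if n < 10:
        raise ValueError("Gelman-Rubin needs at least 10 draws per chain")
    chain_means = arr.mean(axis=1)  # (m, k)
    within = arr.var(axis=1, ddof=1).mean(axis=0)  # (k,)
    between_over_n = chain_means.var(axis=0, ddof=1)  # (k,)
    constant = np.ptp(arr.reshape(-1, k), axis=0) == 0.0
    rhat = np.empty(k)
    for j in range(k):
        if constant[j]:
            rhat[j] = 1.0
        elif within[j] == 0.0:
            rhat[j] = np.inf
        else:
            rhat[j] = np.sqrt((n - 1) / n + between_over_n[j] / within[j])
    if names is None and k == 1:
        return pd.Series(rhat, index=["param"])
    return pd.Series(rhat, index=names if names is not None else range(k))


def summarize_posterior(draws: PosteriorDraws) -> FitSummary:
    """Pool chains into means, sds, equal-tailed 95% intervals and R̂.

    ``excludes_zero`` flags coefficients whose 95% interval misses zero.
    Emits a (non-fatal) warning when any R̂ ≥ 1.1.
    """
    flat = draws.pooled()
    names = draws.all_names
    lo, hi = np.percentile(flat, [2.5, 97.5], axis=0)
    rhat = gelman_rubin(draws)
    table = pd.DataFrame(
        {
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1) if flat.shape[0] > 1 else np.zeros(flat.shape[1]),
            "q2.5": lo,
            "q97.5": hi,
            "rhat": rhat.to_numpy(),
            "excludes_zero": (lo > 0) | (hi < 0),
        },
        index=pd.Index(names, name="parameter"),
    )
    worst = table["rhat"].max()
    if worst >= RHAT_WARN:
        warnings.warn(
            f"possible non-convergence: max R-hat = {worst:.3f} >= {RHAT_WARN}",
            stacklevel=2,
        )
    return FitSummary(params=table)


# ---------------------------------------------------------------------------
# sampling


def _draw_inverse_gamma(rng: np.random.Generator, shape: float, rate: float) -> float:
    return float(rate / rng.gamma(shape))


def _variance_posterior_shape_rate(
    spec: ModelSpec, n_terms: int, sum_sq: float
) -> tuple[float, float]:
    """Conditional IG(shape, rate) for a variance given its n_terms residuals."""
    if spec.sigma_prior == FLAT_SIGMA:
        return 0.5 * (n_terms - 1), 0.5 * sum_sq
    return spec.prior_ig_shape + 0.5 * n_terms, spec.prior_ig_rate + 0.5 * sum_sq


def run_mcmc(spec: ModelSpec, data: ModelData, config: ChainConfig) -> PosteriorDraws:
    """Fit one model by MCMC; fully reproducible given ``config.seed``."""
    if data.n_records == 0:
        raise ValueError("empty dataset")
    if spec.family == BETA and (np.any(data.y <= 0) or np.any(data.y >= 1)):
        raise ValueError("beta family requires responses strictly in (0, 1)")
    expected = spec.design_columns()
    if list(data.columns) != expected:
        raise ValueError("data/spec mismatch: rebuild ModelData with this spec")

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains, deviances, acceptance = [], [], []
    b_chains = [] if spec.random_effects else None
    for c, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        init = initial_state(spec, data, rng, chain_index=c)
        if not np.isfinite(log_posterior(spec, init, data)):
            raise ValueError("non-finite log posterior at initialization")
        if spec.family == LINEAR:
            out = _run_linear_chain(spec, data, config, rng, init)
        else:
            out = _run_beta_chain(spec, data, config, rng, init)
        chains.append(out["draws"])
        deviances.append(out["deviance"])
        acceptance.append(out["acceptance"])
        if b_chains is not None:
            b_chains.append(out["b"])

    names = list(spec.design_columns())
    names.append("phi" if spec.family == BETA else "sigma2_eps")
    if spec.random_effects:
        names.append("sigma2_b")
    return PosteriorDraws(
        spec=spec,
        config=config,
        parameter_names=names,
        draws=np.stack(chains),
        deviance=np.stack(deviances),
        b_draws=np.stack(b_chains) if b_chains is not None else None,
        resp_ids=data.resp_ids if spec.random_effects else None,
        acceptance=acceptance,
    )


def _run_linear_chain(spec, data, config, rng, init):
    """Pure Gibbs for the (possibly mixed) normal linear model."""
    y, X = data.y, data.X
    n, p = X.shape
    m = data.n_respondents
    XtX = X.T @ X
    tau2 = spec.prior_beta_variance
    total = config.burn_in + config.n_samples

    beta = init.beta.copy()
    sigma2 = float(init.sigma2_eps)
    sigma2_b = float(init.sigma2_b) if spec.random_effects else None
    b = init.b.copy() if spec.random_effects else None

    n_fixed = p + 1 + (1 if spec.random_effects else 0)
    draws = np.empty((config.n_samples, n_fixed))
    b_draws = np.empty((config.n_samples, m)) if spec.random_effects else None
    dev = np.empty(config.n_samples)

    counts = None
    if spec.random_effects:
        counts = np.bincount(data.resp_codes, minlength=m).astype(float)

    for t in range(total):
        # beta | sigma2, b
        target = y if b is None else y - b[data.resp_codes]
        prec = XtX / sigma2 + np.eye(p) / tau2
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, X.T @ target / sigma2)
        beta = mean + np.linalg.solve(L.T, rng.standard_normal(p))
        eta = X @ beta

        if spec.random_effects:
            # b_i | rest : normal with precision n_i/sigma2 + 1/sigma2_b
            resid_sums = np.bincount(data.resp_codes, weights=y - eta, minlength=m)
            prec_b = counts / sigma2 + 1.0 / sigma2_b
            mean_b = (resid_sums / sigma2) / prec_b
            b = mean_b + rng.standard_normal(m) / np.sqrt(prec_b)
            # recenter along the likelihood-invariant direction: shifting the
            # intercept by delta and every b_i by -delta leaves the fit
            # unchanged, so delta has a Gaussian full conditional (priors
            # only); this Gibbs move breaks the intercept/mean(b) random walk
            prec_d = 1.0 / tau2 + m / sigma2_b
            mean_d = (np.sum(b) / sigma2_b - beta[0] / tau2) / prec_d
            delta = mean_d + rng.standard_normal() / np.sqrt(prec_d)
            beta[0] += delta
            eta = eta + delta
            b = b - delta
            # sigma2_b | b
            shape, rate = _variance_posterior_shape_rate(spec, m, float(np.sum(b**2)))
            sigma2_b = _draw_inverse_gamma(rng, shape, rate)

        resid = y - eta if b is None else y - eta - b[data.resp_codes]
        ssr = float(np.sum(resid**2))
        shape, rate = _variance_posterior_shape_rate(spec, n, ssr)
        sigma2 = _draw_inverse_gamma(rng, shape, rate)

        if t >= config.burn_in:
            i = t - config.burn_in
            row = [*beta, sigma2]
            if spec.random_effects:
                row.append(sigma2_b)
                b_draws[i] = b
            draws[i] = row
            dev[i] = n * np.log(2.0 * np.pi * sigma2) + ssr / sigma2

    return {
        "draws": draws,
        "b": b_draws,
        "deviance": dev,
        "acceptance": {},  # all-Gibbs chain: no Metropolis blocks
    }


def _beta_record_ll(log_y, log_1my, eta, phi):
    """Per-record beta log likelihood at linear predictor eta, precision phi."""
    mu = expit(eta)
    a = mu * phi
    bb = phi - a
    return gammaln(phi) - gammaln(a) - gammaln(bb) + (a - 1.0) * log_y + (bb - 1.0) * log_1my


def _run_beta_chain(spec, data, config, rng, init):
    """Adaptive random-walk Metropolis (β, φ, b) + Gibbs (σ₁²) for the beta family."""
    y, X = data.y, data.X
    n, p = X.shape
    m = data.n_respondents
    tau2 = spec.prior_beta_variance
    total = config.burn_in + config.n_samples
    target = config.adapt_target

    log_y = np.log(y)
    log_1my = np.log1p(-y)
    # rows each beta coordinate touches (dummy columns are sparse)
    col_rows = [np.flatnonzero(X[:, j]) for j in range(p)]
    col_vals = [X[rows, j] for j, rows in enumerate(col_rows)]

    beta = init.beta.copy()
    phi = float(init.phi)
    sigma2_b = float(init.sigma2_b) if spec.random_effects else None
    b = init.b.copy() if spec.random_effects else None

    eta = X @ beta
    if b is not None:
        eta = eta + b[data.resp_codes]
    ll = _beta_record_ll(log_y, log_1my, eta, phi)

    log_s_beta = np.full(p, np.log(config.initial_scale))
    log_s_phi = np.log(config.initial_scale)
    log_s_b = np.log(config.initial_scale)
    acc_beta = np.zeros(p)
    acc_phi = 0.0
    acc_b = 0.0

    n_fixed = p + 1 + (1 if spec.random_effects else 0)
    draws = np.empty((config.n_samples, n_fixed))
    b_draws = np.empty((config.n_samples, m)) if spec.random_effects else None
    dev = np.empty(config.n_samples)

    if spec.random_effects:
        slices = np.append(data.resp_starts, n)

    for t in range(total):
        adapting = t < config.burn_in
        gamma = 1.0 / (t + 1) ** 0.6 if adapting else 0.0

        # --- beta coordinates, one at a time, incremental eta/ll updates
        for _sweep in range(config.beta_sweeps):
            for j in range(p):
                rows, vals = col_rows[j], col_vals[j]
                step = np.exp(log_s_beta[j]) * rng.standard_normal()
                prop = beta[j] + step
                eta_new = eta[rows] + vals * step
                ll_new = _beta_record_ll(log_y[rows], log_1my[rows], eta_new, phi)
                dlp = (ll_new.sum() - ll[rows].sum()) + 0.5 * (beta[j] ** 2 - prop**2) / tau2
                a_prob = min(1.0, np.exp(min(dlp, 0.0)))
                if rng.random() < a_prob:
                    beta[j] = prop
                    eta[rows] = eta_new
                    ll[rows] = ll_new
                    if not adapting:
                        acc_beta[j] += 1
                if adapting:
                    log_s_beta[j] += gamma * (a_prob - target)

        # --- phi on the log scale
        lphi = np.log(phi)
        lphi_new = lphi + np.exp(log_s_phi) * rng.standard_normal()
        phi_new = np.exp(lphi_new)
        prior_new = log_prior_phi(phi_new, spec)
        if np.isfinite(prior_new):
            ll_new = _beta_record_ll(log_y, log_1my, eta, phi_new)
            dlp = (
                ll_new.sum()
                - ll.sum()
                + prior_new
                - log_prior_phi(phi, spec)
                + (lphi_new - lphi)  # Jacobian of the log transform
            )
            a_prob = min(1.0, np.exp(min(dlp, 0.0)))
        else:
            a_prob = 0.0
        if rng.random() < a_prob:
            phi = float(phi_new)
            ll = ll_new
            if not adapting:
                acc_phi += 1
        if adapting:
            log_s_phi += gamma * (a_prob - target)

        # --- random effects: joint proposal, per-respondent accept
        if spec.random_effects:
            step_b = np.exp(log_s_b) * rng.standard_normal(m)
            b_new = b + step_b
            eta_new = eta + step_b[data.resp_codes]
            ll_new = _beta_record_ll(log_y, log_1my, eta_new, phi)
            dll = np.add.reduceat(ll_new - ll, slices[:-1])
            dlp_i = dll + 0.5 * (b**2 - b_new**2) / sigma2_b
            a_prob_i = np.minimum(1.0, np.exp(np.minimum(dlp_i, 0.0)))
            accept = rng.random(m) < a_prob_i
            if np.any(accept):
                rec_accept = accept[data.resp_codes]
                b = np.where(accept, b_new, b)
                eta = np.where(rec_accept, eta_new, eta)
                ll = np.where(rec_accept, ll_new, ll)
            if not adapting:
                acc_b += float(accept.mean())
            if adapting:
                log_s_b += gamma * (float(a_prob_i.mean()) - target)

            # recenter intercept vs mean(b): eta (hence the likelihood) is
            # unchanged, and delta's full conditional is Gaussian in the priors
            prec_d = 1.0 / tau2 + m / sigma2_b
            mean_d = (np.sum(b) / sigma2_b - beta[0] / tau2) / prec_d
            delta = mean_d + rng.standard_normal() / np.sqrt(prec_d)
            beta[0] += delta
            b = b - delta

            # sigma2_b | b : conjugate
            shape, rate = _variance_posterior_shape_rate(spec, m, float(np.sum(b**2)))
            sigma2_b = _draw_inverse_gamma(rng, shape, rate)

        if t >= config.burn_in:
            i = t - config.burn_in
            row = [*beta, phi]
            if spec.random_effects:
                row.append(sigma2_b)
                b_draws[i] = b
            draws[i] = row
            dev[i] = -2.0 * ll.sum()

    denom = float(config.n_samples)
    acceptance = {
        "beta": float(acc_beta.mean() / (denom * config.beta_sweeps)),
        "phi": acc_phi / denom,
    }
    if spec.random_effects:
        acceptance["b"] = acc_b / denom
    return {"draws": draws, "b": b_draws, "deviance": dev, "acceptance": acceptance}
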