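"""Model comparison and validation: MPE, RMSE, DIC, monotonicity, LOO.

MPE is implemented as mean absolute prediction error.  Because the same
acronym is used at two aggregation levels in practice — individual records
versus per-state mean utilities — the aggregation level is always an explicit
choice of the caller; both are reported by the CLI.

DIC uses the conditional (random-effects-focused) deviance:
D̄ = posterior mean of −2 log L, p_D = D̄ − D(θ̂) with θ̂ the posterior mean
of all sampled quantities including the random intercepts, DIC = D̄ + p_D.

The monotonicity audit checks the logical requirement that predicted utility
not increase when any single dimension worsens by one level, over a random
sample of adjacent state pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .models import BETA, LINEAR, ModelData, ModelSpec, deviance as _deviance
from .sampler import ChainConfig, PosteriorDraws, run_mcmc
from .states import AdjacentPair, HealthState, design_vector, parse_state_code


@dataclass(frozen=True)
class MonotonicityReport:
    n_pairs: int
    n_violations: int
    strictness: str  # "strict" (ties count) or "non_strict"

    @property
    def fraction_violating(self) -> float:
        return self.n_violations / self.n_pairs if self.n_pairs else 0.0


# ---------------------------------------------------------------------------
# prediction


def _state_design(states: Sequence[HealthState], n_beta: int) -> np.ndarray:
    """Design rows (intercept + 25 dummies, covariates at reference/zero)."""
    X = np.zeros((len(states), n_beta))
    X[:, 0] = 1.0
    for i, s in enumerate(states):
        X[i, 1:26] = design_vector(s)
    return X


def predict_states(
    draws: PosteriorDraws, states: Sequence[HealthState]
) -> pd.DataFrame:
    """Population-level predicted utility per state: mean and sd over draws.

    The random effect is set to 0 (the median respondent) and covariates, if
    any, to their reference values; each posterior draw of β yields one
    utility per state (inverse logit of x'β for the beta family, x'β for the
    linear family), summarized by its mean and sd.
    """
    B = draws.pooled_beta()  # (N, p)
    X = _state_design(states, B.shape[1])
    eta = X @ B.T  # (n_states, N)
    util = expit(eta) if draws.spec.family == BETA else eta
    return pd.DataFrame(
        {
            "state_code": [s.code for s in states],
            "predicted_mean": util.mean(axis=1),
            "predicted_sd": util.std(axis=1, ddof=1),
        }
    )


def predict_state_utility(
    draws: PosteriorDraws, state: HealthState
) -> tuple[float, float]:
    """(posterior mean, posterior sd) of one state's population utility."""
    out = predict_states(draws, [state])
    return float(out["predicted_mean"].iloc[0]), float(out["predicted_sd"].iloc[0])


# ---------------------------------------------------------------------------
# scalar metrics


def _paired(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValueError("observed and predicted must be equal-length and nonempty")
    return obs, pred


def mpe(observed, predicted) -> float:
    """Mean absolute prediction error."""
    obs, pred = _paired(observed, predicted)
    return float(np.mean(np.abs(obs - pred)))


def rmse(observed, predicted) -> float:
    """Root mean squared prediction error."""
    obs, pred = _paired(observed, predicted)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def dic(
    draws: PosteriorDraws, data: ModelData, spec: ModelSpec | None = None
) -> tuple[float, float, float]:
    """(D̄, p_D, DIC): posterior mean deviance, effective parameters, total."""
    spec = spec or draws.spec
    dbar = float(draws.deviance.mean())
    d_hat = _deviance(spec, draws.posterior_mean_state(data), data)
    if not np.isfinite(d_hat):
        raise ValueError("non-finite deviance at the posterior mean")
    p_d = dbar - d_hat
    return dbar, p_d, dbar + p_d


# ---------------------------------------------------------------------------
# monotonicity


def monotonicity_audit(
    fit,
    pairs: Iterable[AdjacentPair],
    strictness: str = "non_strict",
    family: str | None = None,
) -> MonotonicityReport:
    """Count adjacent pairs where the worse state gets the higher utility.

    ``fit`` is either a :class:`PosteriorDraws` (predictions averaged over
    posterior draws) or a plain coefficient vector (intercept + 25 dummies,
    plug-in prediction; ``family`` must then be given).  ``non_strict``
    (default) does not count exact ties as violations; ``strict`` does.
    """
    if strictness not in ("strict", "non_strict"):
        raise ValueError("strictness must be 'strict' or 'non_strict'")
    pairs = list(pairs)
    unique: dict[str, HealthState] = {}
    for pr in pairs:
        unique.setdefault(pr.state_a.code, pr.state_a)
        unique.setdefault(pr.state_b.code, pr.state_b)
    states = list(unique.values())

    if isinstance(fit, PosteriorDraws):
        pred = predict_states(fit, states)
        util = dict(zip(pred["state_code"], pred["predicted_mean"]))
    else:
        beta = np.asarray(fit, dtype=float)
        if family not in (BETA, LINEAR):
            raise ValueError("plug-in audit needs family='beta' or 'linear'")
        X = _state_design(states, beta.size)
        eta = X @ beta
        vals = expit(eta) if family == BETA else eta
        util = {s.code: float(v) for s, v in zip(states, vals)}

    n_viol = 0
    for pr in pairs:
        worse, better = util[pr.worse.code], util[pr.better.code]
        if worse > better or (strictness == "strict" and worse == better):
            n_viol += 1
    return MonotonicityReport(n_pairs=len(pairs), n_violations=n_viol, strictness=strictness)


# ---------------------------------------------------------------------------
# out-of-sample validation


def loo_validation(
    data: pd.DataFrame,
    spec: ModelSpec,
    config: ChainConfig,
    states_to_omit: Sequence[str | HealthState],
) -> pd.DataFrame:
    """Leave-one-state-out validation.

    For each state: refit on all records of the remaining states, predict the
    omitted state's population utility, and report the observed mean, the
    predicted mean and sd, and the standardized residual
    SR = (observed − predicted) / predicted sd.  Each refit gets its own seed
    derived from ``config.seed``.
    """
    codes = [
        s.code if isinstance(s, HealthState) else parse_state_code(str(s)).code
        for s in states_to_omit
    ]
    present = set(data["state_code"].astype(str))
    absent = [c for c in codes if c not in present]
    if absent:
        raise ValueError(f"states not present in the data: {absent}")

    seeds = np.random.SeedSequence(config.seed).spawn(len(codes))
    rows = []
    for code, ss in zip(codes, seeds):
        train = data[data["state_code"].astype(str) != code]
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        fit = run_mcmc(spec, ModelData.from_dataframe(train, spec), replace(config, seed=sub_seed))
        pred_mean, pred_sd = predict_state_utility(fit, parse_state_code(code))
        obs = float(data.loc[data["state_code"].astype(str) == code, "y"].mean())
        rows.append(
            {
                "state_code": code,
                "observed_mean": obs,
                "predicted_mean": pred_mean,
                "predicted_sd": pred_sd,
                "standardized_residual": (obs - pred_mean) / pred_sd,
            }
        )
    return pd.DataFrame(rows)


def qq_points(standardized_residuals) -> np.ndarray:
    """Sorted residuals vs standard-normal quantiles at (i − 0.5)/n.

    Returns an (n, 2) array of (theoretical, empirical) pairs, ready to plot.
    """
    res = np.sort(np.asarray(standardized_residuals, dtype=float))
    n = res.size
    if n < 2:
        raise ValueError("need at least 2 residuals")
    theo = norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return np.column_stack([theo, res])
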