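"""Synthetic valuation studies with the structure the models assume.

The generator emulates a standard-gamble valuation study: respondents are
assigned round-robin to 7 blocks of 7 health states drawn from a 49-state
panel; each respondent values their 7 block states plus the pits anchor task
(8 valuations each).  Utilities follow the beta random-effects model: for
respondent i valuing state s,

    eta = x_s' beta_true + b_i,   b_i ~ N(0, sigma_b^2)
    y   ~ Beta(mu * phi, (1 - mu) * phi),   mu = expit(eta)

with draws within 1e-6 of a boundary redrawn so the likelihood stays exactly
beta.  Default truth is the reference BR+RE coefficient vector with
phi = 9.943; the resulting state means span roughly 0.33-0.89.

A raw standard-gamble layer can be synthesized by algebraic inversion of the
anchoring formula (SG = (y - P)/(1 - P) with P the respondent's pits value),
so the preprocessing pipeline round-trips the generated utilities exactly.

The default panel is the 49 non-pits reference state codes; the pits is
valued by every respondent as the anchor task, so at defaults every non-pits
state is valued 18 times and the pits 126 times (1008 records in all).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import tables
from .models import BETA, ModelData, ModelSpec
from .preprocessing import build_dataset, filter_constant_respondents
from .sampler import ChainConfig, run_mcmc, summarize_posterior
from .states import PITS, design_vector, parse_state_code

_BOUNDARY_EPS = 1e-6


def default_panel() -> list[str]:
    """The 49 non-pits reference state codes (the pits anchors separately)."""
    codes = tables.load_table2()["state_code"].astype(str).tolist()
    return [c for c in codes if c != PITS.code]


def default_true_beta() -> np.ndarray:
    """Reference BR+RE posterior-mean coefficients (intercept + 25 dummies)."""
    return tables.table1_coefficients("BR+RE").to_numpy(dtype=float)


@dataclass
class GeneratorConfig:
    """Study-design and truth parameters of the generator.

    Defaults reproduce the study design the models target: 126 respondents,
    7 blocks of 7 states plus the pits anchor, beta-distributed utilities
    around the reference BR+RE coefficients with phi = 9.943, and respondent
    random effects with sd 0.3 on the logit scale.  Covariates are generated
    (age uniform over 18-65 years, the categorical variables uniform over
    their categories) but carry zero effect by default.
    """

    n_respondents: int = 126
    state_panel: list[str] = field(default_factory=default_panel)
    n_blocks: int = 7
    true_beta: np.ndarray = field(default_factory=default_true_beta)
    true_phi: float = 9.943
    true_sigma_b: float = 0.3
    n_constant_respondents: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_beta = np.asarray(self.true_beta, dtype=float)
        if self.true_phi <= 0 or self.true_sigma_b < 0:
            raise ValueError("true_phi must be > 0 and true_sigma_b >= 0")
        if len(self.state_panel) % self.n_blocks != 0:
            raise ValueError(
                f"panel of {len(self.state_panel)} states does not split into "
                f"{self.n_blocks} equal blocks"
            )
        if self.true_beta.size != 26:
            raise ValueError("true_beta must be intercept + 25 dummy coefficients")
        if PITS.code in self.state_panel:
            raise ValueError("the pits anchors every respondent; keep it out of the block panel")
        if self.n_constant_respondents > self.n_respondents:
            raise ValueError("more constant respondents than respondents")


@dataclass
class SyntheticStudy:
    """One generated study: raw layer inputs, profiles, and the truth."""

    valuations: pd.DataFrame  # respondent_id, state_code, sg, is_pits
    respondents: pd.DataFrame  # raw profile schema
    truth: dict  # true beta, phi, sigma_b, per-respondent b, per-record mu/y
    config: GeneratorConfig


def _draw_beta_open(rng: np.random.Generator, a, b) -> np.ndarray:
    """Beta draws redrawn while within 1e-6 of a boundary."""
    y = rng.beta(a, b)
    bad = (y < _BOUNDARY_EPS) | (y > 1.0 - _BOUNDARY_EPS)
    while np.any(bad):
        y = np.where(bad, rng.beta(a, b), y)
        bad = (y < _BOUNDARY_EPS) | (y > 1.0 - _BOUNDARY_EPS)
    return y


def generate_study(config: GeneratorConfig) -> SyntheticStudy:
    """Generate one study; reproducible given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    panel = [parse_state_code(c) for c in config.state_panel]
    block_size = len(panel) // config.n_blocks
    blocks = [
        panel[k * block_size : (k + 1) * block_size] for k in range(config.n_blocks)
    ]

    m = config.n_respondents
    b = rng.normal(0.0, config.true_sigma_b, size=m)

    profiles = pd.DataFrame(
        {
            "respondent_id": np.arange(1, m + 1),
            "age": rng.integers(18, 66, size=m),
            "gender": rng.integers(0, 2, size=m),
            "degree": rng.integers(0, 2, size=m),
            "housing": rng.integers(0, 3, size=m),
            "income": rng.integers(0, 3, size=m),
            "marital_status": rng.integers(0, 3, size=m),
        }
    )

    x_cache = {s.code: np.concatenate([[1.0], design_vector(s)]) for s in set(panel) | {PITS}}
    rows = []
    for i in range(m):
        rid = i + 1
        tasks = [(s, 0) for s in blocks[i % config.n_blocks]] + [(PITS, 1)]
        for state, is_pits in tasks:
            eta = float(x_cache[state.code] @ config.true_beta) + b[i]
            mu = float(expit(eta))
            y = float(_draw_beta_open(rng, mu * config.true_phi, (1.0 - mu) * config.true_phi))
            rows.append(
                {
                    "respondent_id": rid,
                    "state_code": state.code,
                    "is_pits": is_pits,
                    "mu": mu,
                    "y": y,
                }
            )
    records = pd.DataFrame(rows)

    if config.n_constant_respondents:
        constant_ids = rng.choice(
            np.arange(1, m + 1), size=config.n_constant_respondents, replace=False
        )
        for rid in constant_ids:
            records.loc[records["respondent_id"] == rid, "y"] = float(
                rng.uniform(0.35, 0.85)
            )
    else:
        constant_ids = np.array([], dtype=int)

    truth = {
        "beta": config.true_beta.copy(),
        "phi": config.true_phi,
        "sigma_b": config.true_sigma_b,
        "b": b,
        "constant_respondents": sorted(int(r) for r in constant_ids),
        "records": records.copy(),
    }
    study = SyntheticStudy(
        valuations=pd.DataFrame(),  # filled below
        respondents=profiles,
        truth=truth,
        config=config,
    )
    study.valuations = generate_raw_sg_layer(study)
    return study


def generate_raw_sg_layer(study: SyntheticStudy) -> pd.DataFrame:
    """Invert the anchoring formula into a raw SG table.

    The pits anchor task carries SG = P = y_pits; every other task carries
    SG = (y − P)/(1 − P), so that adjustment reconstructs y exactly.
    """
    records = study.truth["records"]
    pits_rows = records[records["is_pits"] == 1]
    p_by_resp = pits_rows.set_index("respondent_id")["y"]
    if np.any(p_by_resp.to_numpy() >= 1.0):
        raise ValueError("pits valuation of 1 cannot anchor the SG scale")
    p = records["respondent_id"].map(p_by_resp).to_numpy(dtype=float)
    y = records["y"].to_numpy(dtype=float)
    is_pits = records["is_pits"].to_numpy() == 1
    sg = np.where(is_pits, p, (y - p) / (1.0 - p))
    return pd.DataFrame(
        {
            "respondent_id": records["respondent_id"].to_numpy(),
            "state_code": records["state_code"].to_numpy(),
            "sg": sg,
            "is_pits": records["is_pits"].to_numpy(),
        }
    )


def write_study(study: SyntheticStudy, outdir) -> dict:
    """Write valuations.csv / respondents.csv plus a truth sidecar JSON."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "valuations": outdir / "valuations.csv",
        "respondents": outdir / "respondents.csv",
        "truth": outdir / "truth.json",
    }
    study.valuations.to_csv(paths["valuations"], index=False)
    study.respondents.to_csv(paths["respondents"], index=False)
    truth = study.truth
    payload = {
        "seed": study.config.seed,
        "beta": truth["beta"].tolist(),
        "phi": truth["phi"],
        "sigma_b": truth["sigma_b"],
        "b": truth["b"].tolist(),
        "constant_respondents": truth["constant_respondents"],
    }
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
    return paths


def parameter_recovery_experiment(
    n_replicates: int,
    config: GeneratorConfig,
    fit_config: ChainConfig,
    model: str = "BR+RE",
) -> pd.DataFrame:
    """Coverage/bias table for repeated generate → preprocess → fit runs.

    Each replicate generates a fresh study (seeds spawned from
    ``config.seed``), runs the exclusion filter, fits ``model``, and records
    per coefficient whether the truth lies inside the 95% credible interval,
    the posterior-mean error, and the worst R̂.  Failed fits are counted in
    the ``n_failures`` attribute of the result (``result.attrs``).
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    spec = ModelSpec.from_name(model)
    true_beta = config.true_beta
    names = ["intercept", *spec.design_columns()[1:26]]

    seeds = np.random.SeedSequence(config.seed).spawn(n_replicates)
    cover = np.zeros((n_replicates, 26))
    err = np.zeros((n_replicates, 26))
    rhat_max = np.zeros(n_replicates)
    phi_err = np.zeros(n_replicates)
    failures = 0
    done = 0
    for r, ss in enumerate(seeds):
        states = ss.generate_state(2)
        gen_seed = int(states[0] % (2**31))
        fit_seed = int(states[1] % (2**31))
        try:
            study = generate_study(replace(config, seed=gen_seed))
            adjusted = build_dataset(study.valuations, study.respondents)
            retained, _ = filter_constant_respondents(adjusted)
            data = ModelData.from_dataframe(retained, spec)
            draws = run_mcmc(spec, data, replace(fit_config, seed=fit_seed))
        except Exception:
            failures += 1
            continue
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            summary = summarize_posterior(draws).params
        block = summary.iloc[:26]
        cover[done] = (block["q2.5"].to_numpy() <= true_beta) & (
            true_beta <= block["q97.5"].to_numpy()
        )
        err[done] = block["mean"].to_numpy() - true_beta
        rhat_max[done] = float(summary["rhat"].max())
        if "phi" in summary.index:
            phi_err[done] = float(summary.loc["phi", "mean"]) - config.true_phi
        done += 1

    cover, err, rhat_max, phi_err = (a[:done] for a in (cover, err, rhat_max, phi_err))
    out = pd.DataFrame(
        {
            "parameter": names,
            "truth": true_beta,
            "coverage": cover.mean(axis=0) if done else np.nan,
            "mean_bias": err.mean(axis=0) if done else np.nan,
        }
    )
    out.attrs["n_replicates"] = done
    out.attrs["n_failures"] = failures
    out.attrs["rhat_max"] = rhat_max
    out.attrs["phi_bias"] = float(phi_err.mean()) if done else np.nan
    out.attrs["pooled_coverage"] = float(cover[:, 1:].mean()) if done else np.nan
    return out
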