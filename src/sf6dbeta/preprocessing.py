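"""Standard-gamble preprocessing: bounding, anchoring, exclusion, summaries.

Raw standard-gamble (SG) responses live on the full-health=1 anchor scale of
the elicitation task.  Each respondent also values the pits state directly
against full health and death; that pits valuation P (bounded below at −1 so
"worse than death" responses stay on the scale) re-anchors the seven other
valuations onto the death=0 / full-health=1 scale:

    SGADJ = SG + (1 − SG) · P

The adjusted values are the response variable of all downstream models.
Respondents whose eight valuations never change carry no preference
information and are excluded.
"""

from __future__ import annotations

import numbers
from typing import Iterable

import numpy as np
import pandas as pd

from .states import parse_state_code

#: Covariate design columns, in the order used by the regression models.
COVARIATE_COLUMNS: tuple[str, ...] = (
    "AGE",
    "GENDER",
    "DEGREE",
    "HOUSING1",
    "HOUSING2",
    "INCOME1",
    "INCOME2",
    "MS1",
    "MS2",
)

#: Raw profile columns expected in respondents.csv.
PROFILE_COLUMNS: tuple[str, ...] = (
    "respondent_id",
    "age",
    "gender",
    "degree",
    "housing",
    "income",
    "marital_status",
)

VALUATION_COLUMNS: tuple[str, ...] = ("respondent_id", "state_code", "sg", "is_pits")


def bound_negative(v):
    """Bound worse-than-death valuations below at −1.

    Accepts scalars or arrays; values above 1 are invalid SG responses.
    """
    arr = np.asarray(v, dtype=float)
    if np.any(arr > 1):
        raise ValueError("SG valuations cannot exceed 1")
    bounded = np.maximum(arr, -1.0)
    if isinstance(v, numbers.Number):
        return float(bounded)
    return bounded


def adjust_sg(sg, p):
    """Re-anchor a raw SG value onto the death=0 / full-health=1 scale.

    ``p`` is the respondent's (bounded) pits valuation.  Vectorized.
    """
    sg_arr = np.asarray(sg, dtype=float)
    p_arr = np.asarray(p, dtype=float)
    if np.any(sg_arr > 1):
        raise ValueError("raw SG values cannot exceed 1")
    if np.any(p_arr > 1) or np.any(p_arr < -1):
        raise ValueError("pits valuation must lie in [-1, 1]")
    out = sg_arr + (1.0 - sg_arr) * p_arr
    if isinstance(sg, numbers.Number) and isinstance(p, numbers.Number):
        return float(out)
    return out


def expand_covariates(profiles: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code respondent profiles into the model's covariate columns.

    Age stays continuous (years).  Gender and degree are 0/1 indicators.
    Housing, income and marital status are 3-category variables coded as two
    dummies each against reference category 0.
    """
    missing = set(PROFILE_COLUMNS) - set(profiles.columns)
    if missing:
        raise ValueError(f"profiles missing columns: {sorted(missing)}")
    for col in ("housing", "income", "marital_status"):
        if not profiles[col].isin([0, 1, 2]).all():
            raise ValueError(f"{col} must be coded 0/1/2 (0 = reference)")
    for col in ("gender", "degree"):
        if not profiles[col].isin([0, 1]).all():
            raise ValueError(f"{col} must be coded 0/1")
    out = pd.DataFrame(
        {
            "respondent_id": profiles["respondent_id"],
            "AGE": profiles["age"].astype(float),
            "GENDER": profiles["gender"].astype(float),
            "DEGREE": profiles["degree"].astype(float),
            "HOUSING1": (profiles["housing"] == 1).astype(float),
            "HOUSING2": (profiles["housing"] == 2).astype(float),
            "INCOME1": (profiles["income"] == 1).astype(float),
            "INCOME2": (profiles["income"] == 2).astype(float),
            "MS1": (profiles["marital_status"] == 1).astype(float),
            "MS2": (profiles["marital_status"] == 2).astype(float),
        }
    )
    return out


def build_dataset(
    valuations: pd.DataFrame, profiles: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Turn raw valuations into model-ready adjusted utilities.

    Each respondent must have exactly one pits task (``is_pits == 1``); its
    bounded value anchors that respondent's other tasks via :func:`adjust_sg`
    and itself enters the output as ``y``.  Record count is conserved.  When
    ``profiles`` is given, dummy-coded covariates are joined on respondent id
    and every respondent must have a profile row.
    """
    missing = set(VALUATION_COLUMNS) - set(valuations.columns)
    if missing:
        raise ValueError(f"valuations missing columns: {sorted(missing)}")
    df = valuations.copy()
    # validates every code, including comma-grouped input
    df["state_code"] = [parse_state_code(str(c)).code for c in df["state_code"]]
    if np.any(df["sg"].to_numpy(dtype=float) > 1):
        raise ValueError("raw SG values cannot exceed 1")

    pits = df[df["is_pits"] == 1]
    counts = pits.groupby("respondent_id").size()
    all_ids = df["respondent_id"].unique()
    bad = [rid for rid in all_ids if counts.get(rid, 0) != 1]
    if bad:
        raise ValueError(f"each respondent needs exactly one pits task; offenders: {bad[:5]}")

    p_by_resp = pd.Series(
        bound_negative(pits["sg"].to_numpy(dtype=float)),
        index=pits["respondent_id"].to_numpy(),
    )
    p = df["respondent_id"].map(p_by_resp).to_numpy(dtype=float)
    sg = df["sg"].to_numpy(dtype=float)
    is_pits = df["is_pits"].to_numpy() == 1
    y = np.where(is_pits, p, adjust_sg(sg, p))

    out = pd.DataFrame(
        {
            "respondent_id": df["respondent_id"].to_numpy(),
            "state_code": df["state_code"].to_numpy(),
            "is_pits": is_pits.astype(int),
            "y": y,
        }
    )
    if profiles is not None:
        cov = expand_covariates(profiles)
        orphan = set(out["respondent_id"]) - set(cov["respondent_id"])
        if orphan:
            raise ValueError(f"respondents without profiles: {sorted(orphan)[:5]}")
        out = out.merge(cov, on="respondent_id", how="left")
    return out


def filter_constant_respondents(
    data: pd.DataFrame, tol: float = 0.0
) -> tuple[pd.DataFrame, list]:
    """Drop respondents whose adjusted valuations never change.

    A respondent is constant when max(y) − min(y) ≤ ``tol`` (default exact
    equality).  Returns the retained records and the excluded respondent ids.
    Idempotent.  Requires at least two valuations per respondent, otherwise
    "constant" is vacuous.
    """
    sizes = data.groupby("respondent_id")["y"].size()
    if (sizes < 2).any():
        few = sizes[sizes < 2].index.tolist()
        raise ValueError(f"respondents with fewer than 2 valuations: {few[:5]}")
    spread = data.groupby("respondent_id")["y"].agg(lambda s: s.max() - s.min())
    excluded = spread[spread <= tol].index.tolist()
    retained = data[~data["respondent_id"].isin(excluded)].reset_index(drop=True)
    return retained, excluded


def state_summaries(data: pd.DataFrame) -> pd.DataFrame:
    """Per-state count, mean, sd (ddof=1; 0 for singletons) and median of y."""
    if len(data) == 0:
        raise ValueError("no valuations to summarize")
    g = data.groupby("state_code")["y"]
    out = pd.DataFrame(
        {
            "n": g.size(),
            "mean": g.mean(),
            "sd": g.std(ddof=1).fillna(0.0),
            "median": g.median(),
        }
    ).reset_index()
    return out


def compress_to_open_interval(y, n: int | None = None):
    """Shrink values on [0, 1] strictly inside (0, 1): y' = (y·(n−1) + 0.5)/n.

    Optional preprocessing for beta-family fits when boundary values occur;
    ``n`` defaults to the sample size.
    """
    arr = np.asarray(y, dtype=float)
    if n is None:
        n = arr.size
    if n < 2:
        raise ValueError("need n >= 2 for boundary compression")
    return (arr * (n - 1) + 0.5) / n
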