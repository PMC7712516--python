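"""Loaders for the shipped reference tables.

Three small CSV fixtures accompany the package:

* ``table1.csv`` — posterior mean and 95% credible interval of every
  regression coefficient under the six model variants, plus the precision φ
  of the beta-family fits; ``table1_metrics.csv`` carries each model's
  MPE/RMSE/DIC.
* ``table2.csv`` — per-state observed mean utility and the LR+RE / BR+RE
  posterior predicted mean and sd for the 49 in-sample states.
* ``table3.csv`` — the ten left-out states of the out-of-sample validation,
  with observed means, predictions and standardized residuals (SR).

The tables are transcribed verbatim; known internal quirks (state 523551's
observed mean differs between table 2 and table 3) are preserved as printed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: table1 column prefix for each model label.
_MODEL_PREFIX = {
    "LR": "lr",
    "BR": "br",
    "LR+RE": "lr_re",
    "BR+RE": "br_re",
    "LR+RE+COV": "lr_re_cov",
    "BR+RE+COV": "br_re_cov",
}


def _read(name: str, **kwargs) -> pd.DataFrame:
    ref = resources.files("sf6dbeta.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, dtype={"state_code": str}, **kwargs)


def load_table1() -> pd.DataFrame:
    """Coefficient table, indexed by parameter name."""
    return _read("table1.csv").set_index("parameter")


def load_table1_metrics() -> pd.DataFrame:
    """Per-model MPE, RMSE and DIC, indexed by model label."""
    return _read("table1_metrics.csv").set_index("model")


def load_table2() -> pd.DataFrame:
    """In-sample observed vs predicted state means (49 states)."""
    return _read("table2.csv")


def load_table3() -> pd.DataFrame:
    """Out-of-sample predictions for the 10 left-out states."""
    return _read("table3.csv")


def table1_coefficients(model: str = "BR+RE") -> pd.Series:
    """Posterior-mean coefficient vector for one model (NA rows dropped).

    Ordered intercept first, then the 25 state dummies (and the 9 covariate
    terms for +COV models).  φ is excluded; see :func:`table1_phi`.
    """
    if model not in _MODEL_PREFIX:
        raise ValueError(f"unknown model {model!r}")
    col = f"{_MODEL_PREFIX[model]}_mean"
    s = load_table1()[col].drop(index="phi").dropna()
    return s


def table1_phi(model: str = "BR+RE") -> float:
    """Posterior-mean precision φ of a beta-family model."""
    if model not in _MODEL_PREFIX:
        raise ValueError(f"unknown model {model!r}")
    val = load_table1().loc["phi", f"{_MODEL_PREFIX[model]}_mean"]
    if pd.isna(val):
        raise ValueError(f"{model} has no precision parameter")
    return float(val)
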