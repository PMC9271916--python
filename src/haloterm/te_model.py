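"""Linear termination-efficiency model.

TE (%) is affine in four sequence features:

    TE = 4.0458 * Uscore + 2.1789 * (-dG_H / n_H) + 2.524 * match_pattern
         + 0.2526 * dG_B + 55.5843

The energy regressor is the normalized hairpin stability -dG_H/n_H
(kcal/mol/bp, positive for stable stems), so stabler stems raise the
prediction; dG_B enters with its raw (negative) sign.  The default instance
carries the published coefficients, fitted on a 582-terminator *E. coli*
library; :func:`fit_ols` refits the same functional form on any feature-TE
table by ordinary least squares.

The model is considered reliable only for strong predictions: estimates
below 50% carry a low-confidence flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import TerminatorFeatures

REGRESSORS = ("uscore", "neg_dG_H_per_nH", "match_pattern", "dG_B")
LOW_CONFIDENCE_TE = 50.0


@dataclass(frozen=True)
class LinearTEModel:
    b_uscore: float = 4.0458
    b_energy: float = 2.1789     # applies to -dG_H / n_H
    b_match: float = 2.524
    b_stack: float = 0.2526      # applies to dG_B (raw, negative sign)
    intercept: float = 55.5843
    fitted_on: str = "published 582-terminator library coefficients"

    @property
    def coefficients(self) -> dict[str, float]:
        return {
            "uscore": self.b_uscore,
            "neg_dG_H_per_nH": self.b_energy,
            "match_pattern": self.b_match,
            "dG_B": self.b_stack,
            "intercept": self.intercept,
        }


DEFAULT_MODEL = LinearTEModel()


@dataclass(frozen=True)
class TEClass:
    label: str  # strong | moderate | weak | non-terminating


def classify_te(te: float) -> TEClass:
    """Strength class: strong (>90%), weak ([0, 50)%), non-terminating (<0)."""
    if te < 0:
        return TEClass("non-terminating")
    if te < 50:
        return TEClass("weak")
    if te > 90:
        return TEClass("strong")
    return TEClass("moderate")


def predict_te(
    f: TerminatorFeatures, m: LinearTEModel = DEFAULT_MODEL, clamp: bool = False
) -> float:
    """Predicted TE (%) for one feature row; unclamped by default."""
    if not f.folded or f.n_H == 0:
        raise ValueError(f"record {f.name!r} has no hairpin; TE undefined")
    te = (
        m.b_uscore * f.uscore
        + m.b_energy * (-f.dG_H / f.n_H)
        + m.b_match * f.match_pattern
        + m.b_stack * f.dG_B
        + m.intercept
    )
    if clamp:
        te = float(np.clip(te, -100.0, 100.0))
    return te


def predict_te_from_values(
    uscore: float,
    neg_dG_H_per_nH: float,
    match_pattern: float,
    dG_B: float,
    m: LinearTEModel = DEFAULT_MODEL,
) -> float:
    """Evaluate the model at an explicit regressor vector."""
    return (
        m.b_uscore * uscore
        + m.b_energy * neg_dG_H_per_nH
        + m.b_match * match_pattern
        + m.b_stack * dG_B
        + m.intercept
    )


def is_low_confidence(te: float) -> bool:
    """Predictions below 50% are outside the model's reliable regime."""
    return te < LOW_CONFIDENCE_TE


@dataclass
class FitDiagnostics:
    r_squared: float
    residual_sd: float
    n_obs: int
    condition_number: float


def fit_ols(table: pd.DataFrame) -> tuple[LinearTEModel, FitDiagnostics]:
    """Refit the linear TE model on a feature-TE table by OLS.

    The table must carry columns ``uscore``, ``neg_dG_H_per_nH``,
    ``match_pattern``, ``dG_B`` and ``te``.  Requires >= 10 rows and a
    well-conditioned design.
    """
    import statsmodels.api as sm

    missing = [c for c in (*REGRESSORS, "te") if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing column(s): {missing}")
    if len(table) < 10:
        raise ValueError(f"need >= 10 rows to fit, got {len(table)}")
    X = sm.add_constant(table[list(REGRESSORS)].astype(float), has_constant="add")
    cond = float(np.linalg.cond(X.to_numpy()))
    if cond > 1e8 or np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        # name the offending columns for the caller
        corr = table[list(REGRESSORS)].astype(float).corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        raise ValueError(f"rank-deficient design (collinear columns, e.g. {worst})")
    res = sm.OLS(table["te"].astype(float), X).fit()
    model = LinearTEModel(
        b_uscore=float(res.params["uscore"]),
        b_energy=float(res.params["neg_dG_H_per_nH"]),
        b_match=float(res.params["match_pattern"]),
        b_stack=float(res.params["dG_B"]),
        intercept=float(res.params["const"]),
        fitted_on=f"OLS refit on {len(table)} rows",
    )
    resid_df = max(int(res.df_resid), 1)
    diag = FitDiagnostics(
        r_squared=float(res.rsquared),
        residual_sd=float(math.sqrt(res.ssr / resid_df)),
        n_obs=int(res.nobs),
        condition_number=cond,
    )
    return model, diag
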