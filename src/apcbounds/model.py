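"""Weighted least-squares fit of the estimable reparameterized APC model.

The inestimable model with three linear trends

    y = b0 + alpha_L*A_L + pi_L*P_L + gamma_L*C_L + nonlinear + covariates + e

collapses, because P_L = A_L + C_L identically on the Lexis surface, to the
estimable form

    y = b0 + theta1*A_L + theta2*C_L + nonlinear + covariates + e

with theta1 = alpha_L + pi_L and theta2 = gamma_L + pi_L. This module fits
that model by survey-weighted least squares and exposes the descriptive
weighted means underlying the raw age/year/cohort profiles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import ContrastBasis, DesignMatrix, GroupingScheme
from .errors import RankDeficiencyError

_COND_LIMIT = 1e10


@dataclass
class ThetaEstimates:
    """Fitted coefficients of the estimable model, with their bases.

    ``theta1 = alpha_L + pi_L`` and ``theta2 = gamma_L + pi_L`` are in
    minutes per group step (per year if the bases were built on the year
    scale). Nonlinear coefficient vectors are on each basis's unit
    weighted-RMS contrast scale.
    """

    beta0: float
    theta1: float
    theta2: float
    age_nl: np.ndarray
    period_nl: np.ndarray
    cohort_nl: np.ndarray
    covariate_coefs: dict[str, float]
    bases: dict[str, ContrastBasis]
    scheme: GroupingScheme
    residual_sd: float
    n_obs: int
    condition_number: float
    params: np.ndarray
    columns: list[str]

    def nl_coefs(self, factor: str) -> np.ndarray:
        return {"age": self.age_nl, "period": self.period_nl,
                "cohort": self.cohort_nl}[factor]

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "theta1": self.theta1,
            "theta2": self.theta2,
            "age_nl": self.age_nl.tolist(),
            "period_nl": self.period_nl.tolist(),
            "cohort_nl": self.cohort_nl.tolist(),
            "covariate_coefs": self.covariate_coefs,
            "residual_sd": self.residual_sd,
            "n_obs": self.n_obs,
            "condition_number": self.condition_number,
            "columns": self.columns,
            "params": self.params.tolist(),
            "bases": {
                f: {
                    "group_weights": b.group_weights.tolist(),
                    "linear": b.linear.tolist(),
                    "nonlinear": [v.tolist() for v in b.nonlinear],
                    "labels": b.labels,
                }
                for f, b in self.bases.items()
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def fit_apc_model(design: DesignMatrix) -> ThetaEstimates:
    """Fit the estimable model by weighted least squares.

    Minimizes ``sum_i w_i (y_i - x_i' b)^2``. Raises
    :class:`RankDeficiencyError` when the design is singular (empty groups
    or a missing covariate level) or has fewer rows than columns.
    """
    X, y, w = design.X, design.y, design.w
    n, p = X.shape
    if n <= p:
        raise RankDeficiencyError(f"n_obs = {n} <= {p} columns")
    sw = np.sqrt(w)
    cond = float(np.linalg.cond(sw[:, None] * X))
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise RankDeficiencyError(
            f"design matrix is (near-)rank-deficient, condition number {cond:.3g}"
        )
    res = sm.WLS(y, X, weights=w).fit(method="qr")
    params = np.asarray(res.params, dtype=float)
    coef = dict(zip(design.columns, params))

    def vec(factor: str) -> np.ndarray:
        orders = design.bases[factor].orders
        return np.array([coef[f"{factor}_poly{k}"] for k in orders])

    resid = y - X @ params
    residual_sd = float(np.sqrt((w * resid**2).sum() / w.sum()))
    cov_names = [c for c in design.columns
                 if c.startswith("dow_") or c == "holiday"]
    return ThetaEstimates(
        beta0=float(coef["intercept"]),
        theta1=float(coef["age_linear"]),
        theta2=float(coef["cohort_linear"]),
        age_nl=vec("age"),
        period_nl=vec("period"),
        cohort_nl=vec("cohort"),
        covariate_coefs={c: float(coef[c]) for c in cov_names},
        bases=design.bases,
        scheme=design.scheme,
        residual_sd=residual_sd,
        n_obs=n,
        condition_number=cond,
        params=params,
        columns=list(design.columns),
    )


_DIMENSION_COLS = {
    "age": "age",
    "age_year": "age",
    "year": "year",
    "cohort_year": "cohort_year",
}


def weighted_group_means(table: pd.DataFrame, dimension: str) -> pd.DataFrame:
    """Survey-weighted mean outcome at each distinct value of a dimension.

    ``dimension`` is one of ``age`` (alias ``age_year``), ``year``,
    ``cohort_year``. Returns one row per distinct value with the weighted
    mean of ``minutes_alone``, the weight total, and the record count.
    """
    if len(table) == 0:
        raise ValueError("empty table")
    col = _DIMENSION_COLS.get(dimension)
    if col is None:
        raise ValueError(f"unknown dimension {dimension!r}")
    df = table[[col, "minutes_alone", "weight"]].copy()
    df["wy"] = df["minutes_alone"] * df["weight"]
    g = df.groupby(col, sort=True)
    out = pd.DataFrame(
        {
            "value": g["wy"].sum().index,
            "mean": (g["wy"].sum() / g["weight"].sum()).to_numpy(),
            "weight_sum": g["weight"].sum().to_numpy(),
            "n": g.size().to_numpy(),
        }
    ).reset_index(drop=True)
    return out
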