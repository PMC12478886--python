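"""Scikit-learn style estimators wrapping the APC analysis.

:class:`WeightedAPCRegression` fits the estimable reparameterized model by
survey-weighted least squares; :class:`BoundedAPCAnalysis` adds the
constraint-driven grid search and the net total effect curves. Both follow
the sklearn estimator contract (``get_params``/``set_params``, fitted
attributes with trailing underscores, ``fit`` returning ``self``) so they
compose with sklearn pipelines and model selection; ``X`` is the microdata
table itself (a DataFrame in the canonical column schema).
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
import pandas as pd

try:  # sklearn is optional: fall back to a minimal params mixin
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        def get_params(self, deep: bool = True) -> dict:
            import inspect

            keys = inspect.signature(self.__init__).parameters
            return {k: getattr(self, k) for k in keys}

        def set_params(self, **params):
            for k, v in params.items():
                setattr(self, k, v)
            return self

from .bounds import (
    BoundedRegion,
    ConstraintSpec,
    bounds_to_ranges,
    grid_search_age_bounds,
)
from .design import (
    GroupingScheme,
    assign_groups,
    build_bases,
    build_design_matrix,
    factor_design_values,
    fit_covariate_coding,
)
from .effects import net_effect_bands, summarize_curve
from .model import ThetaEstimates, fit_apc_model

_REQUIRED = ("age", "year", "minutes_alone", "weight", "day_of_week", "holiday")


def _check_table(X: pd.DataFrame, y=None) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a microdata DataFrame")
    X = X.copy()
    if y is not None:
        X["minutes_alone"] = np.asarray(y, dtype=float)
    missing = [c for c in _REQUIRED if c not in X.columns]
    if missing:
        raise ValueError(f"microdata table lacks column(s): {missing}")
    if len(X) == 0:
        raise ValueError("empty microdata table")
    return X


class WeightedAPCRegression(BaseEstimator):
    """Survey-weighted APC regression on orthogonal polynomial contrasts.

    Parameters
    ----------
    scheme : GroupingScheme, optional
        Age/period grouping; defaults to 13 five-year age groups from 15
        and 4 five-year periods from 2003.
    linear_scale : {"group", "year"}
        Scale of the linear contrasts: minutes per group step (default) or
        per calendar year.
    contrast_weights : {"weights", "counts"}
        Whether contrast orthogonality uses survey-weight totals (default)
        or raw case counts per group.
    max_order : int
        Highest polynomial order retained per factor (capped at G-1).

    Attributes
    ----------
    estimates_ : ThetaEstimates
        Full fitted coefficient set with bases and diagnostics.
    beta0_, theta1_, theta2_ : float
        Intercept (weighted grand mean scale) and the two identified
        linear combinations, theta1 = alpha_L + pi_L and
        theta2 = gamma_L + pi_L.
    """

    def __init__(
        self,
        scheme: Optional[GroupingScheme] = None,
        linear_scale: Literal["group", "year"] = "group",
        contrast_weights: Literal["weights", "counts"] = "weights",
        max_order: int = 5,
    ):
        self.scheme = scheme
        self.linear_scale = linear_scale
        self.contrast_weights = contrast_weights
        self.max_order = max_order

    def fit(self, X: pd.DataFrame, y=None) -> "WeightedAPCRegression":
        table = _check_table(X, y)
        scheme = self.scheme if self.scheme is not None else GroupingScheme()
        grouped = assign_groups(table, scheme)
        bases = build_bases(
            grouped,
            scheme,
            scale=self.linear_scale,
            contrast_weights=self.contrast_weights,
            max_order=self.max_order,
        )
        covariates = fit_covariate_coding(grouped)
        design = build_design_matrix(grouped, bases, covariates, scheme)
        est = fit_apc_model(design)
        self.estimates_ = est
        self.scheme_ = scheme
        self.bases_ = bases
        self.covariates_ = covariates
        self.design_columns_ = list(design.columns)
        self.beta0_ = est.beta0
        self.theta1_ = est.theta1
        self.theta2_ = est.theta2
        self.n_obs_ = est.n_obs
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Fitted mean minutes for new records (same grouping and coding)."""
        if not hasattr(self, "estimates_"):
            raise RuntimeError("estimator is not fitted")
        table = _check_table(X.assign(minutes_alone=0.0)
                             if "minutes_alone" not in X.columns else X)
        grouped = assign_groups(table, self.scheme_)
        apc, apc_names = factor_design_values(grouped, self.bases_)
        cov, cov_names = self.covariates_.encode(grouped)
        Xm = np.column_stack([np.ones(len(grouped)), apc, cov])
        return Xm @ self.estimates_.params

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Weighted R^2 of the fitted model on the given table."""
        table = _check_table(X, y)
        yv = table["minutes_alone"].to_numpy(dtype=float)
        w = table["weight"].to_numpy(dtype=float)
        resid = yv - self.predict(table)
        ybar = np.average(yv, weights=w)
        ss_res = float(np.sum(w * resid**2))
        ss_tot = float(np.sum(w * (yv - ybar) ** 2))
        return 1.0 - ss_res / ss_tot


class BoundedAPCAnalysis(BaseEstimator):
    """Full bounded-APC analysis: fit, constrain, and assemble net effects.

    Fitting runs the weighted regression, grid-searches the linear age
    effects whose net total age curve attains its minimum in the target age
    group, propagates the bounds along the canonical solution line, and
    evaluates the three net total effect curves with identification bands.

    Attributes
    ----------
    regression_ : WeightedAPCRegression
    region_ : BoundedRegion
        Constrained ranges of the linear effects plus the midpoint triple.
    net_effects_ : dict[str, NetEffectCurve]
    summaries_ : dict[str, dict]
    """

    def __init__(
        self,
        scheme: Optional[GroupingScheme] = None,
        constraint: Optional[ConstraintSpec] = None,
        linear_scale: Literal["group", "year"] = "group",
        contrast_weights: Literal["weights", "counts"] = "weights",
        max_order: int = 5,
    ):
        self.scheme = scheme
        self.constraint = constraint
        self.linear_scale = linear_scale
        self.contrast_weights = contrast_weights
        self.max_order = max_order

    def fit(self, X: pd.DataFrame, y=None) -> "BoundedAPCAnalysis":
        reg = WeightedAPCRegression(
            scheme=self.scheme,
            linear_scale=self.linear_scale,
            contrast_weights=self.contrast_weights,
            max_order=self.max_order,
        ).fit(X, y)
        constraint = (
            self.constraint if self.constraint is not None else ConstraintSpec()
        )
        theta: ThetaEstimates = reg.estimates_
        alpha_range = grid_search_age_bounds(theta, constraint)
        region: BoundedRegion = bounds_to_ranges(
            theta.theta1, theta.theta2, alpha_range
        )
        curves = net_effect_bands(theta, region)
        self.regression_ = reg
        self.estimates_ = theta
        self.theta1_ = theta.theta1
        self.theta2_ = theta.theta2
        self.alpha_range_ = alpha_range
        self.region_ = region
        self.net_effects_ = curves
        self.summaries_ = {d: summarize_curve(c) for d, c in curves.items()}
        return self
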