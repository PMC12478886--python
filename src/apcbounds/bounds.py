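"""Canonical solution line and constraint-driven bounds on linear effects.

Only theta1 = alpha_L + pi_L and theta2 = gamma_L + pi_L are identified, so
the linear (age, period, cohort) effects form a one-dimensional family — the
canonical solution line — parameterized by the linear period effect:

    alpha_L = theta1 - pi_L,   gamma_L = theta2 - pi_L.

A substantive constraint (people spend the least time alone in their
mid-30s, i.e., the net total age curve must attain its minimum at the age
group containing age 35) is imposed by a grid search over candidate linear
age effects; the accepted extremes bound the line segment, and the bounds
propagate to period and cohort with slope +/-1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

from .errors import InfeasibleConstraintError
from .model import ThetaEstimates


class LinearTriple(NamedTuple):
    """Linear age/period/cohort effects (minutes per group step)."""

    alpha_L: float
    pi_L: float
    gamma_L: float


def line_point(theta1: float, theta2: float, pi_L: float) -> LinearTriple:
    """The point on the canonical solution line with linear period effect pi_L."""
    return LinearTriple(theta1 - pi_L, pi_L, theta2 - pi_L)


def canonical_line(
    theta1: float, theta2: float, pi_values: np.ndarray | None = None
) -> pd.DataFrame:
    """Tabulate the canonical line for plotting/export (2-D APC plot data)."""
    if pi_values is None:
        pi_values = np.linspace(-10.0, 10.0, 401)
    pts = [line_point(theta1, theta2, float(p)) for p in pi_values]
    return pd.DataFrame(pts, columns=["alpha_L", "pi_L", "gamma_L"])[
        ["pi_L", "alpha_L", "gamma_L"]
    ]


class ConstraintSpec(BaseModel):
    """Grid-search specification for the net-age-minimum constraint.

    ``target_min_age`` is the single-year age whose group must attain the
    minimum of the net total age curve. ``tie_policy`` decides whether the
    target group merely has to attain the minimum (ties allowed, default) or
    must be the unique argmin.
    """

    target_min_age: int = 35
    grid_lo: float = -20.0
    grid_hi: float = 20.0
    grid_step: float = 0.01
    tie_policy: Literal["target_attains_min", "unique_argmin"] = (
        "target_attains_min"
    )

    @model_validator(mode="after")
    def _grid_ok(self):
        if not self.grid_lo < self.grid_hi:
            raise ValueError("grid_lo must be < grid_hi")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        return self


@dataclass
class BoundedRegion:
    """Constrained ranges of the three linear effects, plus the midpoint.

    The three ranges have equal width (the canonical line has slope +/-1 in
    these coordinates) and the midpoint is the line point at the center of
    the period range.
    """

    alpha_range: tuple[float, float]
    pi_range: tuple[float, float]
    gamma_range: tuple[float, float]
    midpoint: LinearTriple

    def range_for(self, dimension: str) -> tuple[float, float]:
        return {"age": self.alpha_range, "period": self.pi_range,
                "cohort": self.gamma_range}[dimension]

    def mid_for(self, dimension: str) -> float:
        return {"age": self.midpoint.alpha_L, "period": self.midpoint.pi_L,
                "cohort": self.midpoint.gamma_L}[dimension]

    def to_dict(self, ndigits: int | None = None) -> dict:
        def r(x: float) -> float:
            return round(x, ndigits) if ndigits is not None else x

        return {
            "alpha_range": [r(v) for v in self.alpha_range],
            "pi_range": [r(v) for v in self.pi_range],
            "gamma_range": [r(v) for v in self.gamma_range],
            "midpoint": {
                "alpha_L": r(self.midpoint.alpha_L),
                "pi_L": r(self.midpoint.pi_L),
                "gamma_L": r(self.midpoint.gamma_L),
            },
        }

    def to_json(self, path: str | Path, ndigits: int | None = None) -> None:
        Path(path).write_text(json.dumps(self.to_dict(ndigits), indent=2))


def _net_age_curves(
    theta: ThetaEstimates, alphas: np.ndarray
) -> np.ndarray:
    """Intercept-free net total age curves, one row per candidate alpha."""
    basis = theta.bases["age"]
    nl = np.zeros(basis.n_groups)
    for coef, vec in zip(theta.age_nl, basis.nonlinear):
        nl = nl + coef * vec
    return alphas[:, None] * basis.linear[None, :] + nl[None, :]


def grid_search_age_bounds(
    theta: ThetaEstimates, constraint: ConstraintSpec | None = None
) -> tuple[float, float]:
    """Bounds on the linear age effect from the net-age-minimum constraint.

    Scans candidate linear age effects over the grid; a candidate is
    accepted when the net total age curve (candidate linear part plus the
    fitted age nonlinearities) attains its minimum at the age group
    containing ``target_min_age``. Returns the smallest and largest accepted
    candidates; raises :class:`InfeasibleConstraintError` with diagnostics
    when none is accepted.
    """
    if constraint is None:
        constraint = ConstraintSpec()
    scheme = theta.scheme
    target = scheme.age_group_index(constraint.target_min_age)

    n_steps = int(np.floor(
        (constraint.grid_hi - constraint.grid_lo) / constraint.grid_step + 1e-9
    ))
    alphas = constraint.grid_lo + constraint.grid_step * np.arange(n_steps + 1)
    curves = _net_age_curves(theta, alphas)
    mins = curves.min(axis=1)
    tol = 1e-9 * max(1.0, float(np.abs(curves).max()))
    at_min = curves <= (mins[:, None] + tol)
    if constraint.tie_policy == "target_attains_min":
        ok = at_min[:, target]
    else:
        ok = at_min[:, target] & (at_min.sum(axis=1) == 1)
    if not ok.any():
        probes = {}
        for name, a in (("grid_lo", constraint.grid_lo), ("zero", 0.0),
                        ("grid_hi", constraint.grid_hi)):
            curve = _net_age_curves(theta, np.array([a]))[0]
            probes[name] = {
                "alpha": a,
                "argmin_group": int(np.argmin(curve)),
            }
        raise InfeasibleConstraintError(
            f"no candidate linear age effect in "
            f"[{constraint.grid_lo}, {constraint.grid_hi}] puts the net age "
            f"minimum in group {target}",
            diagnostics=probes,
        )
    accepted = alphas[ok]
    return float(accepted.min()), float(accepted.max())


def bounds_to_ranges(
    theta1: float, theta2: float, alpha_range: tuple[float, float]
) -> BoundedRegion:
    """Propagate linear-age bounds along the canonical line.

    pi_range  = [theta1 - alpha_max, theta1 - alpha_min]
    gamma_range = [theta2 - theta1 + alpha_min, theta2 - theta1 + alpha_max]
    and the midpoint is the line point at the center of pi_range.
    """
    a_lo, a_hi = alpha_range
    if not a_lo <= a_hi:
        raise ValueError("empty alpha_range")
    pi_range = (theta1 - a_hi, theta1 - a_lo)
    gamma_range = (theta2 - theta1 + a_lo, theta2 - theta1 + a_hi)
    pi_mid = 0.5 * (pi_range[0] + pi_range[1])
    return BoundedRegion(
        alpha_range=(a_lo, a_hi),
        pi_range=pi_range,
        gamma_range=gamma_range,
        midpoint=line_point(theta1, theta2, pi_mid),
    )
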