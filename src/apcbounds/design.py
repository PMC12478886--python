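"""Group assignment and weighted orthogonal polynomial contrast design.

Age, period (diary year), and cohort (birth year) are binned into
equal-width groups on the Lexis surface; with ``n_age`` age groups and
``n_period`` period groups the diagonals give ``n_age + n_period - 1``
cohort groups, and the group indices satisfy

    cohort_idx = period_idx - age_idx + (n_age - 1)

exactly. Because cell sizes (survey-weight totals) are unequal, ordinary
orthogonal polynomial contrasts would leak linear trend into the nonlinear
terms; the contrasts here are built by Gram-Schmidt under the *weighted*
inner product ``<u, v> = sum_g w_g u_g v_g`` so that the linear and
nonlinear columns of each factor are exactly orthogonal in the fitted
sample. The linear contrast is left on the group-index scale (slope one per
group step) so that regression coefficients read as minutes per group step;
nonlinear contrasts are normalized to unit weighted root-mean-square.
Nonlinear orders are truncated at five (or ``G - 1`` if smaller) to smooth
the estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

from .errors import DesignError
from .io import DAY_LEVELS

MAX_POLY_ORDER = 5

FactorName = Literal["age", "period", "cohort"]


class GroupingScheme(BaseModel):
    """Equal-width age/period grouping on the Lexis surface.

    Defaults: 13 five-year age groups starting at 15 (15-19 ... 75-79) and
    4 five-year period groups starting in 2003 (2003-2007 ... 2018-2022),
    giving 16 cohort diagonals (1924-1932 ... 1999-2007).
    """

    age_start: int = 15
    age_width: int = 5
    n_age: int = 13
    period_start: int = 2003
    period_width: int = 5
    n_period: int = 4

    @model_validator(mode="after")
    def _positive(self):
        for name in ("age_width", "n_age", "period_width", "n_period"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        return self

    @property
    def n_cohort(self) -> int:
        return self.n_age + self.n_period - 1

    @property
    def age_max(self) -> int:
        return self.age_start + self.age_width * self.n_age - 1

    @property
    def year_max(self) -> int:
        return self.period_start + self.period_width * self.n_period - 1

    def age_group_index(self, age: int) -> int:
        if not (self.age_start <= age <= self.age_max):
            raise ValueError(f"age {age} outside [{self.age_start}, {self.age_max}]")
        return (age - self.age_start) // self.age_width

    def period_group_index(self, year: int) -> int:
        if not (self.period_start <= year <= self.year_max):
            raise ValueError(
                f"year {year} outside [{self.period_start}, {self.year_max}]"
            )
        return (year - self.period_start) // self.period_width

    def age_labels(self) -> list[str]:
        return [
            f"{self.age_start + i * self.age_width}-"
            f"{self.age_start + (i + 1) * self.age_width - 1}"
            for i in range(self.n_age)
        ]

    def period_labels(self) -> list[str]:
        return [
            f"{self.period_start + i * self.period_width}-"
            f"{self.period_start + (i + 1) * self.period_width - 1}"
            for i in range(self.n_period)
        ]

    def cohort_labels(self) -> list[str]:
        """Birth-year span of each Lexis diagonal (overlapping is expected)."""
        labels = []
        for j in range(self.n_cohort):
            births = []
            for p in range(self.n_period):
                a = p - (j - (self.n_age - 1))
                if 0 <= a < self.n_age:
                    p_lo = self.period_start + p * self.period_width
                    p_hi = p_lo + self.period_width - 1
                    a_lo = self.age_start + a * self.age_width
                    a_hi = a_lo + self.age_width - 1
                    births.append(p_lo - a_hi)
                    births.append(p_hi - a_lo)
            labels.append(f"{min(births)}-{max(births)}")
        return labels

    def labels(self, factor: FactorName) -> list[str]:
        return {
            "age": self.age_labels,
            "period": self.period_labels,
            "cohort": self.cohort_labels,
        }[factor]()

    def n_groups(self, factor: FactorName) -> int:
        return {"age": self.n_age, "period": self.n_period,
                "cohort": self.n_cohort}[factor]


def assign_groups(table: pd.DataFrame, scheme: GroupingScheme) -> pd.DataFrame:
    """Attach 0-based age_idx / period_idx / cohort_idx columns.

    All ages and years must fall inside the scheme's ranges (filter first);
    an out-of-range record raises with its row index.
    """
    age = table["age"].to_numpy()
    year = table["year"].to_numpy()
    bad_age = (age < scheme.age_start) | (age > scheme.age_max)
    if bad_age.any():
        i = int(np.argmax(bad_age))
        raise DesignError(
            f"record {table.index[i]}: age {age[i]} outside scheme range "
            f"[{scheme.age_start}, {scheme.age_max}]"
        )
    bad_year = (year < scheme.period_start) | (year > scheme.year_max)
    if bad_year.any():
        i = int(np.argmax(bad_year))
        raise DesignError(
            f"record {table.index[i]}: year {year[i]} outside scheme range "
            f"[{scheme.period_start}, {scheme.year_max}]"
        )
    out = table.copy()
    out["age_idx"] = (age - scheme.age_start) // scheme.age_width
    out["period_idx"] = (year - scheme.period_start) // scheme.period_width
    out["cohort_idx"] = out["period_idx"] - out["age_idx"] + (scheme.n_age - 1)
    return out


@dataclass
class ContrastBasis:
    """Weighted orthogonal polynomial contrasts for one factor.

    ``linear`` is the weighted-centered group index (slope 1 per group step,
    or per year when built with ``scale="year"``); ``nonlinear[k]`` holds the
    order-(k+2) contrast, unit weighted-RMS normalized. All vectors have
    weighted sum zero and are pairwise orthogonal under the (normalized)
    group-weight inner product.
    """

    factor: str
    group_weights: np.ndarray
    linear: np.ndarray
    nonlinear: list[np.ndarray]
    labels: list[str] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return len(self.group_weights)

    @property
    def orders(self) -> list[int]:
        return list(range(2, 2 + len(self.nonlinear)))

    def vectors(self) -> list[np.ndarray]:
        return [self.linear, *self.nonlinear]

    def gram(self) -> np.ndarray:
        """Gram matrix of all contrast vectors under the weight inner product."""
        w = self.group_weights / self.group_weights.sum()
        v = np.column_stack(self.vectors())
        return v.T @ (w[:, None] * v)


def weighted_orthogonal_contrasts(
    group_weights: Sequence[float],
    max_order: int,
    factor: str = "",
    scale: Literal["group", "year"] = "group",
    group_width: int = 5,
    labels: Sequence[str] | None = None,
) -> ContrastBasis:
    """Build weighted orthogonal polynomial contrasts on the group index.

    Gram-Schmidt orthogonalization of the monomials ``1, g, g^2, ...`` of the
    0-based group index ``g`` under the inner product weighted by the
    (normalized) group weights. The order-1 vector is the weighted-centered
    index itself; higher orders are normalized to unit weighted RMS.
    """
    w = np.asarray(group_weights, dtype=float)
    G = len(w)
    if G < 2:
        raise DesignError("need at least 2 groups")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise DesignError("all group weights must be positive and finite")
    if max_order > G - 1:
        raise DesignError(f"max_order {max_order} exceeds G-1 = {G - 1}")
    wn = w / w.sum()
    g = np.arange(G, dtype=float)

    linear = g - float(wn @ g)
    if scale == "year":
        linear = linear / group_width
    ortho = [np.ones(G), g - float(wn @ g)]  # index-scale linear for projection
    nonlinear: list[np.ndarray] = []
    for k in range(2, max_order + 1):
        v = g**k
        for b in ortho:
            v = v - (float(wn @ (v * b)) / float(wn @ (b * b))) * b
        norm = np.sqrt(float(wn @ v**2))
        if norm < 1e-12:
            raise DesignError(f"degenerate order-{k} contrast (norm ~ 0)")
        v = v / norm
        ortho.append(v)
        nonlinear.append(v)
    return ContrastBasis(
        factor=factor,
        group_weights=w,
        linear=linear,
        nonlinear=nonlinear,
        labels=list(labels) if labels is not None else [],
    )


def group_weight_totals(
    grouped: pd.DataFrame,
    idx_col: str,
    n_groups: int,
    source: Literal["weights", "counts"] = "weights",
) -> np.ndarray:
    """Per-group totals of survey weights (default) or raw case counts."""
    idx = grouped[idx_col].to_numpy()
    if source == "weights":
        vals = grouped["weight"].to_numpy(dtype=float)
    else:
        vals = np.ones(len(grouped))
    return np.bincount(idx, weights=vals, minlength=n_groups)


def build_bases(
    grouped: pd.DataFrame,
    scheme: GroupingScheme,
    scale: Literal["group", "year"] = "group",
    contrast_weights: Literal["weights", "counts"] = "weights",
    max_order: int = MAX_POLY_ORDER,
) -> dict[str, ContrastBasis]:
    """Contrast bases for age, period, and cohort from the realized sample."""
    bases = {}
    for factor, idx_col in (
        ("age", "age_idx"),
        ("period", "period_idx"),
        ("cohort", "cohort_idx"),
    ):
        G = scheme.n_groups(factor)  # type: ignore[arg-type]
        w = group_weight_totals(grouped, idx_col, G, contrast_weights)
        if np.any(w <= 0):
            empty = np.flatnonzero(w <= 0).tolist()
            raise DesignError(f"empty {factor} group(s) at indices {empty}")
        width = scheme.age_width if factor != "period" else scheme.period_width
        bases[factor] = weighted_orthogonal_contrasts(
            w,
            min(max_order, G - 1),
            factor=factor,
            scale=scale,
            group_width=width,
            labels=scheme.labels(factor),  # type: ignore[arg-type]
        )
    return bases


@dataclass
class CovariateCoding:
    """Weighted-effect coding for day-of-week and holiday.

    The dropped levels (Sunday when present, otherwise the last observed
    day; non-holiday) get ``-s_l / s_drop`` in each level's column, where
    ``s`` are survey-weight shares, so every covariate column has weighted
    mean zero and the model intercept stays on the weighted grand-mean
    scale. Only day levels present in the fitted table get columns, which
    lets weekday/weekend-restricted sensitivity analyses run unchanged.
    """

    day_shares: dict[str, float]
    holiday_share: float
    dropped_day: str

    @property
    def day_columns(self) -> list[str]:
        return [f"dow_{d}" for d in self.day_shares if d != self.dropped_day]

    def encode(self, table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        n = len(table)
        days = table["day_of_week"].to_numpy()
        unknown = set(np.unique(days)) - set(self.day_shares)
        if unknown:
            raise DesignError(
                f"day-of-week level(s) {sorted(unknown)} absent from the "
                f"fitted coding"
            )
        cols = []
        names = []
        s_drop = self.day_shares[self.dropped_day]
        for d in self.day_shares:
            if d == self.dropped_day:
                continue
            x = np.zeros(n)
            x[days == d] = 1.0
            x[days == self.dropped_day] = -self.day_shares[d] / s_drop
            cols.append(x)
            names.append(f"dow_{d}")
        hol = table["holiday"].to_numpy(dtype=bool)
        s_h = self.holiday_share
        x = np.where(hol, 1.0, -s_h / (1.0 - s_h))
        cols.append(x)
        names.append("holiday")
        return np.column_stack(cols), names


def fit_covariate_coding(table: pd.DataFrame) -> CovariateCoding:
    w = table["weight"].to_numpy(dtype=float)
    total = w.sum()
    days = table["day_of_week"].to_numpy()
    shares = {
        d: float(w[days == d].sum() / total)
        for d in DAY_LEVELS
        if (days == d).any()
    }
    if len(shares) < 2:
        raise DesignError("need at least two day-of-week levels")
    dropped = "Sun" if "Sun" in shares else list(shares)[-1]
    hol = table["holiday"].to_numpy(dtype=bool)
    s_h = float(w[hol].sum() / total)
    if s_h <= 0 or s_h >= 1:
        raise DesignError("both holiday levels must be present")
    return CovariateCoding(
        day_shares=shares, holiday_share=s_h, dropped_day=dropped
    )


@dataclass
class DesignMatrix:
    """Per-record design for the estimable reparameterized model.

    Columns: intercept, age_linear (A_L), cohort_linear (C_L), age
    nonlinear, period nonlinear, cohort nonlinear, six day-of-week
    contrasts, holiday. The period *linear* term is deliberately absent:
    on the Lexis surface the centered period index equals A_L + C_L
    record-for-record, so only theta1 = alpha_L + pi_L (on A_L) and
    theta2 = gamma_L + pi_L (on C_L) are estimable.
    """

    X: np.ndarray
    columns: list[str]
    y: np.ndarray
    w: np.ndarray
    bases: dict[str, ContrastBasis]
    covariates: CovariateCoding
    scheme: GroupingScheme

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.columns)


def factor_design_values(
    grouped: pd.DataFrame, bases: dict[str, ContrastBasis]
) -> tuple[np.ndarray, list[str]]:
    """APC columns (linear + nonlinear) looked up by group index."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    a = grouped["age_idx"].to_numpy()
    c = grouped["cohort_idx"].to_numpy()
    cols.append(bases["age"].linear[a])
    names.append("age_linear")
    cols.append(bases["cohort"].linear[c])
    names.append("cohort_linear")
    idx = {"age": a, "period": grouped["period_idx"].to_numpy(), "cohort": c}
    for factor in ("age", "period", "cohort"):
        for order, vec in zip(bases[factor].orders, bases[factor].nonlinear):
            cols.append(vec[idx[factor]])
            names.append(f"{factor}_poly{order}")
    return np.column_stack(cols), names


def build_design_matrix(
    grouped: pd.DataFrame,
    bases: dict[str, ContrastBasis],
    covariates: CovariateCoding | None = None,
    scheme: GroupingScheme | None = None,
) -> DesignMatrix:
    """Assemble the full design (20 columns for the default scheme)."""
    if covariates is None:
        covariates = fit_covariate_coding(grouped)
    if scheme is None:
        scheme = GroupingScheme(
            n_age=bases["age"].n_groups, n_period=bases["period"].n_groups
        )
    apc, apc_names = factor_design_values(grouped, bases)
    cov, cov_names = covariates.encode(grouped)
    n = len(grouped)
    X = np.column_stack([np.ones(n), apc, cov])
    columns = ["intercept", *apc_names, *cov_names]
    return DesignMatrix(
        X=X,
        columns=columns,
        y=grouped["minutes_alone"].to_numpy(dtype=float),
        w=grouped["weight"].to_numpy(dtype=float),
        bases=bases,
        covariates=covariates,
        scheme=scheme,
    )


def export_basis(basis: ContrastBasis) -> pd.DataFrame:
    """One row per group: weights, labels, and every contrast vector."""
    data = {
        "group": np.arange(basis.n_groups),
        "label": basis.labels or [str(i) for i in range(basis.n_groups)],
        "weight": basis.group_weights,
        "linear": basis.linear,
    }
    for order, vec in zip(basis.orders, basis.nonlinear):
        data[f"poly{order}"] = vec
    return pd.DataFrame(data)
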