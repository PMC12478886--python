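"""Synthetic survey-weighted time-diary microdata with known APC effects.

The generator emulates the structure of a pooled cross-sectional diary
sample on the Lexis surface: ages 15-79, diary years 2003-2022, cohort =
year - age exactly, unequal (age, year) cell sizes, positive lognormal
survey weights, and a minutes-per-day outcome driven by additive linear and
nonlinear age/period/cohort effects plus day-of-week and holiday effects
and Gaussian noise.

Ground-truth nonlinear coefficients are defined on the weighted orthogonal
contrast bases of the *realized* sample — the same bases the design module
builds when the simulated table is fitted — so that, at zero noise, model
fitting recovers every coefficient to numerical precision rather than
approximately. The linear effects enter through the centered linear
contrasts, whose Lexis identity P_L = A_L + C_L makes the generator
invariant along the null direction (alpha+d, pi-d, gamma+d): under the same
seed, shifted configurations share every stochastic draw bit-for-bit and
differ in the outcome only by float rounding of the shifted coefficients.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

from .design import (
    GroupingScheme,
    assign_groups,
    build_bases,
)
from .effects import NetEffectCurve
from .io import DAY_LEVELS

MAX_NL = {"age": 4, "period": 2, "cohort": 4}  # orders 2..min(5, G-1)


class SimConfig(BaseModel):
    """Generator configuration; defaults are the study-like conditions.

    The default effect sizes mirror a men-like configuration: linear triple
    (2.8, 1.4, -1.0) minutes per five-year group step, a U-shaped age
    nonlinearity whose net minimum (at the default linear age effect) falls
    in the 35-39 group, a mirrored cohort nonlinearity, a mild period
    acceleration, weekend/holiday contrasts of tens of minutes, and
    residual noise of 60 minutes.
    """

    seed: int = 0
    n_records: int = 50_000
    age_range: tuple[int, int] = (15, 79)
    year_range: tuple[int, int] = (2003, 2022)
    group_width: int = 5
    gender_mix: float = 0.5
    grand_mean: float = 300.0
    linear_triple: tuple[float, float, float] = (2.8, 1.4, -1.0)
    age_nl: tuple[float, ...] = (8.7, 0.0, 0.0, 0.0)
    period_nl: tuple[float, ...] = (1.2, 0.8)
    cohort_nl: tuple[float, ...] = (6.0, 0.0, 0.0, 0.0)
    dow_effects: tuple[float, ...] = (15.0, 18.0, 18.0, 18.0, 12.0, -35.0, -46.0)
    holiday_effect: float = -40.0
    holiday_rate: float = 0.03
    noise_sd: float = 60.0
    weight_law: Literal["constant", "lognormal"] = "lognormal"
    weight_mu: float = 0.0
    weight_sigma: float = 0.5
    cell_density: Literal["uniform", "age_skewed"] = "uniform"
    clamp_outcome: bool = False

    @model_validator(mode="after")
    def _check(self):
        if self.n_records <= 0:
            raise ValueError("n_records must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.gender_mix <= 1.0:
            raise ValueError("gender_mix must be in [0, 1]")
        if not 0.0 <= self.holiday_rate < 1.0:
            raise ValueError("holiday_rate must be in [0, 1)")
        if len(self.dow_effects) != 7:
            raise ValueError("dow_effects must have 7 entries (Mon..Sun)")
        scheme = self.scheme()
        limits = {
            "age_nl": min(5, scheme.n_age - 1) - 1,
            "period_nl": min(5, scheme.n_period - 1) - 1,
            "cohort_nl": min(5, scheme.n_cohort - 1) - 1,
        }
        for name, limit in limits.items():
            if len(getattr(self, name)) > limit:
                raise ValueError(
                    f"{name} has {len(getattr(self, name))} coefficients; "
                    f"orders beyond {limit + 1} are not representable "
                    f"(truncation at order 5 / G-1)"
                )
        return self

    def scheme(self) -> GroupingScheme:
        a_lo, a_hi = self.age_range
        y_lo, y_hi = self.year_range
        for name, (lo, hi) in (("age_range", (a_lo, a_hi)),
                               ("year_range", (y_lo, y_hi))):
            span = hi - lo + 1
            if span <= 0 or span % self.group_width:
                raise ValueError(
                    f"{name} span must be a positive multiple of "
                    f"group_width={self.group_width}"
                )
        return GroupingScheme(
            age_start=a_lo,
            age_width=self.group_width,
            n_age=(a_hi - a_lo + 1) // self.group_width,
            period_start=y_lo,
            period_width=self.group_width,
            n_period=(y_hi - y_lo + 1) // self.group_width,
        )


def _draw_frame(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw everything except the outcome; order of draws is part of the API.

    All draws are independent of the effect-size parameters, so two configs
    differing only in effects share every random variate under one seed.
    """
    n = config.n_records
    a_lo, a_hi = config.age_range
    y_lo, y_hi = config.year_range
    ages = np.arange(a_lo, a_hi + 1)
    if config.cell_density == "uniform":
        p_age = np.full(ages.size, 1.0 / ages.size)
    else:  # age_skewed: linearly declining sampling mass toward old ages
        p_age = np.linspace(1.5, 0.5, ages.size)
        p_age /= p_age.sum()
    age = rng.choice(ages, size=n, p=p_age)
    year = rng.integers(y_lo, y_hi + 1, size=n)
    female = rng.random(n) < config.gender_mix
    day = rng.integers(0, 7, size=n)
    holiday = rng.random(n) < config.holiday_rate
    if config.weight_law == "constant":
        weight = np.ones(n)
    else:
        weight = rng.lognormal(config.weight_mu, config.weight_sigma, size=n)
    return pd.DataFrame(
        {
            "age": age.astype(int),
            "year": year.astype(int),
            "cohort_year": (year - age).astype(int),
            "gender": np.where(female, "female", "male"),
            "weight": weight,
            "day_of_week": np.asarray(DAY_LEVELS)[day],
            "holiday": holiday,
        }
    )


def _noise_free_outcome(config: SimConfig, frame: pd.DataFrame) -> np.ndarray:
    """Expected minutes for each record under the configured effects."""
    scheme = config.scheme()
    grouped = assign_groups(frame, scheme)
    bases = build_bases(grouped, scheme)
    a = grouped["age_idx"].to_numpy()
    p = grouped["period_idx"].to_numpy()
    c = grouped["cohort_idx"].to_numpy()
    alpha_L, pi_L, gamma_L = config.linear_triple

    mu = np.full(len(frame), config.grand_mean, dtype=float)
    mu += alpha_L * bases["age"].linear[a]
    mu += pi_L * bases["period"].linear[p]
    mu += gamma_L * bases["cohort"].linear[c]
    for coefs, factor, idx in (
        (config.age_nl, "age", a),
        (config.period_nl, "period", p),
        (config.cohort_nl, "cohort", c),
    ):
        for coef, vec in zip(coefs, bases[factor].nonlinear):
            mu += coef * vec[idx]

    w = frame["weight"].to_numpy(dtype=float)
    dow = np.asarray(config.dow_effects, dtype=float)
    day_idx = pd.Categorical(
        frame["day_of_week"], categories=DAY_LEVELS
    ).codes
    day_effect = dow[day_idx]
    mu += day_effect - float(np.average(day_effect, weights=w))

    hol = frame["holiday"].to_numpy(dtype=bool)
    hol_effect = np.where(hol, config.holiday_effect, 0.0)
    mu += hol_effect - float(np.average(hol_effect, weights=w))
    return mu


def simulate_microdata(config: SimConfig) -> pd.DataFrame:
    """Generate a microdata table; same config and seed => identical table."""
    rng = np.random.default_rng(config.seed)
    frame = _draw_frame(config, rng)
    noise = rng.standard_normal(config.n_records)
    mu = _noise_free_outcome(config, frame)
    y = mu + config.noise_sd * noise
    if config.clamp_outcome:
        y = np.clip(y, 0.0, 1440.0)
    frame.insert(4, "minutes_alone", y)
    return frame


def true_identifiable_params(config: SimConfig) -> tuple[float, float]:
    """The identified linear combinations (theta1, theta2) implied by the
    generating triple: theta1 = alpha_L + pi_L, theta2 = gamma_L + pi_L."""
    alpha_L, pi_L, gamma_L = config.linear_triple
    return alpha_L + pi_L, gamma_L + pi_L


def expected_group_means(config: SimConfig) -> dict[str, NetEffectCurve]:
    """Noise-free weighted group-mean curves of the seeded sample.

    The recovery target for fitted net effects: weighted means of the
    noise-free outcome surface by age, period, and cohort group, under the
    realized cell densities, covariate mix, and survey weights.
    """
    rng = np.random.default_rng(config.seed)
    frame = _draw_frame(config, rng)
    mu = _noise_free_outcome(config, frame)
    scheme = config.scheme()
    grouped = assign_groups(frame, scheme)
    w = frame["weight"].to_numpy(dtype=float)
    out: dict[str, NetEffectCurve] = {}
    for factor, idx_col in (
        ("age", "age_idx"),
        ("period", "period_idx"),
        ("cohort", "cohort_idx"),
    ):
        G = scheme.n_groups(factor)  # type: ignore[arg-type]
        idx = grouped[idx_col].to_numpy()
        num = np.bincount(idx, weights=w * mu, minlength=G)
        den = np.bincount(idx, weights=w, minlength=G)
        means = np.divide(num, den, out=np.full(G, np.nan), where=den > 0)
        out[factor] = NetEffectCurve(
            dimension=factor,
            group_labels=scheme.labels(factor),  # type: ignore[arg-type]
            values_mid=means,
            values_min=means.copy(),
            values_max=means.copy(),
            evaluated_at="noise-free weighted group means of the seeded sample",
        )
    return out


def write_truth(config: SimConfig, path: str | Path) -> dict:
    """Serialize the identifiable ground-truth quantities alongside a draw."""
    theta1, theta2 = true_identifiable_params(config)
    payload = {
        "theta1": theta1,
        "theta2": theta2,
        "linear_triple": list(config.linear_triple),
        "grand_mean": config.grand_mean,
        "age_nl": list(config.age_nl),
        "period_nl": list(config.period_nl),
        "cohort_nl": list(config.cohort_nl),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
    return payload
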