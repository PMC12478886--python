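import numpy as np
import pandas as pd
import pytest

from apcbounds import (
    BoundedAPCAnalysis,
    GroupingScheme,
    SimConfig,
    ThetaEstimates,
    simulate_microdata,
    weighted_orthogonal_contrasts,
)

# Replicate seeds for the recovery study: fixed a priori, never re-rolled.
RECOVERY_SEEDS = [20250930 + i for i in range(20)]
RECOVERY_CONFIG = dict(n_records=50_000, noise_sd=60.0,
                       linear_triple=(2.8, 1.4, -1.0))


@pytest.fixture(scope="session")
def men_like_table():
    """One medium simulated draw reused by fitting tests (n=20,000)."""
    return simulate_microdata(SimConfig(seed=7, n_records=20_000))


@pytest.fixture(scope="session")
def recovery_runs():
    """Twenty independent fits at the recovery-study conditions.

    Returns (theta1_hats, theta2_hats, alpha_ranges) as arrays/list.
    """
    t1, t2, ranges = [], [], []
    for seed in RECOVERY_SEEDS:
        cfg = SimConfig(seed=seed, **RECOVERY_CONFIG)
        analysis = BoundedAPCAnalysis().fit(simulate_microdata(cfg))
        t1.append(analysis.theta1_)
        t2.append(analysis.theta2_)
        ranges.append(analysis.alpha_range_)
    return np.array(t1), np.array(t2), ranges


@pytest.fixture
def tiny_table():
    """Hand-built valid microdata covering both genders, all day levels."""
    days = ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"]
    rows = []
    for i in range(21):
        age = 15 + (i * 3) % 65
        year = 2003 + (i * 7) % 20
        rows.append(
            dict(
                age=age,
                year=year,
                cohort_year=year - age,
                gender="female" if i % 2 else "male",
                minutes_alone=100.0 + 10 * i,
                weight=0.5 + 0.1 * i,
                day_of_week=days[i % 7],
                holiday=(i % 10 == 0),
            )
        )
    return pd.DataFrame(rows)


@pytest.fixture
def make_theta():
    """Factory for synthetic ThetaEstimates with equal-weight bases."""

    def _make(
        theta1=4.2,
        theta2=0.4,
        beta0=300.0,
        age_nl=(0.0, 0.0, 0.0, 0.0),
        period_nl=(0.0, 0.0),
        cohort_nl=(0.0, 0.0, 0.0, 0.0),
        scheme=None,
    ):
        scheme = scheme or GroupingScheme()
        bases = {}
        for factor in ("age", "period", "cohort"):
            G = scheme.n_groups(factor)
            bases[factor] = weighted_orthogonal_contrasts(
                np.ones(G), min(5, G - 1), factor=factor,
                labels=scheme.labels(factor),
            )
        return ThetaEstimates(
            beta0=beta0,
            theta1=theta1,
            theta2=theta2,
            age_nl=np.asarray(age_nl, float),
            period_nl=np.asarray(period_nl, float),
            cohort_nl=np.asarray(cohort_nl, float),
            covariate_coefs={},
            bases=bases,
            scheme=scheme,
            residual_sd=0.0,
            n_obs=0,
            condition_number=1.0,
            params=np.array([]),
            columns=[],
        )

    return _make
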