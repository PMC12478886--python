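"""Synthetic-data generator: determinism, ground truth, recovery."""

import numpy as np
import pandas as pd
import pytest

from apcbounds import (
    SimConfig,
    WeightedAPCRegression,
    expected_group_means,
    simulate_microdata,
    true_identifiable_params,
    validate_microdata,
    weighted_group_means,
)


class TestConfig:
    def test_nonlinear_order_limits_enforced(self):
        with pytest.raises(ValueError, match="period_nl"):
            SimConfig(period_nl=(1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="age_nl"):
            SimConfig(age_nl=(1.0,) * 5)

    def test_basic_validation(self):
        with pytest.raises(ValueError):
            SimConfig(n_records=0)
        with pytest.raises(ValueError):
            SimConfig(noise_sd=-1.0)
        with pytest.raises(ValueError):
            SimConfig(year_range=(2003, 2021))  # span not a multiple of 5

    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((2.8, 1.4, -1.0), (4.2, 0.4)),
            ((0.0, 0.0, 0.0), (0.0, 0.0)),
            ((5.15, 0.0, -0.03), (5.15, -0.03)),
        ],
    )
    def test_true_identifiable_params(self, triple, expected):
        cfg = SimConfig(linear_triple=triple)
        t1, t2 = true_identifiable_params(cfg)
        assert t1 == pytest.approx(expected[0], abs=1e-12)
        assert t2 == pytest.approx(expected[1], abs=1e-12)


class TestGeneration:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(seed=9, n_records=5_000)
        pd.testing.assert_frame_equal(
            simulate_microdata(cfg), simulate_microdata(cfg)
        )

    def test_different_seed_differs(self):
        a = simulate_microdata(SimConfig(seed=1, n_records=2_000))
        b = simulate_microdata(SimConfig(seed=2, n_records=2_000))
        assert not a["minutes_alone"].equals(b["minutes_alone"])

    def test_degenerate_constant_outcome(self):
        cfg = SimConfig(
            seed=3, n_records=2_000, noise_sd=0.0, grand_mean=300.0,
            linear_triple=(0.0, 0.0, 0.0), age_nl=(), period_nl=(),
            cohort_nl=(), dow_effects=(0.0,) * 7, holiday_effect=0.0,
        )
        table = simulate_microdata(cfg)
        np.testing.assert_allclose(table["minutes_alone"], 300.0, atol=1e-10)

    def test_output_passes_microdata_validation(self):
        table = simulate_microdata(SimConfig(seed=5, n_records=3_000,
                                             clamp_outcome=True))
        clean, report = validate_microdata(table)
        assert report.n_rejected == 0
        assert len(clean) == 3_000
        assert (table["cohort_year"] == table["year"] - table["age"]).all()
        assert (table["weight"] > 0).all()

    def test_clamping_restricts_range(self):
        cfg = SimConfig(seed=5, n_records=3_000, noise_sd=400.0,
                        clamp_outcome=True)
        y = simulate_microdata(cfg)["minutes_alone"]
        assert y.min() >= 0.0 and y.max() <= 1440.0

    def test_age_skewed_density_shifts_cell_sizes(self):
        u = simulate_microdata(SimConfig(seed=6, n_records=20_000))
        s = simulate_microdata(SimConfig(seed=6, n_records=20_000,
                                         cell_density="age_skewed"))
        assert (s["age"] < 45).mean() > (u["age"] < 45).mean() + 0.02

    @pytest.mark.parametrize("delta", [1.0, 5.0, 17.0])
    def test_null_direction_leaves_data_invariant(self, delta):
        # shifting along (+d, -d, +d) changes nothing: every random draw
        # is identical and the outcome agrees to float rounding (the
        # shifted coefficients are themselves rounded, so equality beyond
        # a few ULPs of ~300 minutes is not representable)
        base = SimConfig(seed=8, n_records=5_000)
        a, p, g = base.linear_triple
        shifted = base.model_copy(
            update={"linear_triple": (a + delta, p - delta, g + delta)}
        )
        t0, t1 = simulate_microdata(base), simulate_microdata(shifted)
        pd.testing.assert_frame_equal(
            t0.drop(columns="minutes_alone"),
            t1.drop(columns="minutes_alone"),
            check_exact=True,
        )
        np.testing.assert_allclose(
            t0["minutes_alone"], t1["minutes_alone"], rtol=0, atol=1e-9
        )


class TestExpectedMeans:
    def test_all_effects_zero_gives_flat_curves(self):
        cfg = SimConfig(
            seed=2, n_records=4_000, linear_triple=(0.0, 0.0, 0.0),
            age_nl=(), period_nl=(), cohort_nl=(),
            dow_effects=(0.0,) * 7, holiday_effect=0.0,
        )
        for curve in expected_group_means(cfg).values():
            np.testing.assert_allclose(curve.values_mid, 300.0, atol=1e-9)

    def test_equals_group_means_of_noise_free_draw(self):
        # independent accumulation oracle via the descriptive-means path
        cfg = SimConfig(seed=13, n_records=8_000, noise_sd=0.0)
        expected = expected_group_means(cfg)
        table = simulate_microdata(cfg)
        grouped = table.assign(
            age_idx=(table["age"] - 15) // 5,
            period_idx=(table["year"] - 2003) // 5,
        )
        for dim, idx in (("age", "age_idx"), ("period", "period_idx")):
            brute = (
                grouped.assign(wy=grouped.minutes_alone * grouped.weight)
                .groupby(idx)
                .apply(lambda d: d["wy"].sum() / d["weight"].sum(),
                       include_groups=False)
            )
            np.testing.assert_allclose(
                expected[dim].values_mid, brute.to_numpy(), atol=1e-9
            )

    def test_noisy_group_means_match_expectation_within_three_ses(self):
        # quadratic-age-only configuration, n = 50,000
        cfg = SimConfig(
            seed=21, n_records=50_000, noise_sd=60.0,
            linear_triple=(0.0, 0.0, 0.0), age_nl=(8.7, 0, 0, 0),
            period_nl=(0.0, 0.0), cohort_nl=(),
            dow_effects=(0.0,) * 7, holiday_effect=0.0,
        )
        table = simulate_microdata(cfg)
        truth = expected_group_means(cfg)["age"].values_mid
        g = table.assign(idx=(table["age"] - 15) // 5).groupby("idx")
        means = g.apply(
            lambda d: np.average(d["minutes_alone"], weights=d["weight"]),
            include_groups=False,
        ).to_numpy()
        se = g["weight"].apply(
            lambda w: 60.0 * np.sqrt((w**2).sum()) / w.sum()
        ).to_numpy()
        assert np.all(np.abs(means - truth) < 3 * se)


class TestRecovery:
    def test_zero_noise_recovers_all_coefficients_exactly(self):
        cfg = SimConfig(seed=17, n_records=20_000, noise_sd=0.0)
        est = WeightedAPCRegression().fit(simulate_microdata(cfg)).estimates_
        t1, t2 = true_identifiable_params(cfg)
        assert est.theta1 == pytest.approx(t1, abs=1e-8)
        assert est.theta2 == pytest.approx(t2, abs=1e-8)
        assert est.beta0 == pytest.approx(cfg.grand_mean, abs=1e-8)
        np.testing.assert_allclose(est.age_nl, cfg.age_nl, atol=1e-8)
        np.testing.assert_allclose(est.period_nl, cfg.period_nl, atol=1e-8)
        np.testing.assert_allclose(est.cohort_nl, cfg.cohort_nl, atol=1e-8)
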