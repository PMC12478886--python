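"""Group assignment, weighted orthogonal contrasts, design matrix."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from apcbounds import (
    DesignError,
    GroupingScheme,
    SimConfig,
    assign_groups,
    build_bases,
    build_design_matrix,
    simulate_microdata,
    weighted_orthogonal_contrasts,
)
from apcbounds.design import fit_covariate_coding

SCHEME = GroupingScheme()


def _one_record(age, year):
    return pd.DataFrame(
        {
            "age": [age],
            "year": [year],
            "gender": ["female"],
            "minutes_alone": [100.0],
            "weight": [1.0],
            "day_of_week": ["Mon"],
            "holiday": [False],
        }
    )


class TestGroupAssignment:
    @pytest.mark.parametrize(
        "age,year,expected",
        [
            (79, 2003, (12, 0, 0)),   # oldest cohort diagonal
            (15, 2022, (0, 3, 15)),   # youngest cohort diagonal
            (33, 2013, (3, 2, 11)),
        ],
    )
    def test_examples(self, age, year, expected):
        g = assign_groups(_one_record(age, year), SCHEME)
        assert (
            int(g["age_idx"][0]),
            int(g["period_idx"][0]),
            int(g["cohort_idx"][0]),
        ) == expected

    def test_scheme_defaults(self):
        assert SCHEME.n_cohort == 16
        assert SCHEME.age_max == 79
        assert SCHEME.year_max == 2022
        assert SCHEME.age_labels()[0] == "15-19"
        assert SCHEME.period_labels()[-1] == "2018-2022"
        assert SCHEME.cohort_labels()[0] == "1924-1932"
        assert SCHEME.cohort_labels()[-1] == "1999-2007"

    def test_out_of_range_raises_naming_record(self):
        with pytest.raises(DesignError, match="age 80"):
            assign_groups(_one_record(80, 2010), SCHEME)
        with pytest.raises(DesignError, match="year 2023"):
            assign_groups(_one_record(40, 2023), SCHEME)

    def test_cohort_index_is_lexis_bijection(self):
        # every (age_idx, period_idx) cell maps onto a valid diagonal
        ages, periods = np.meshgrid(np.arange(13), np.arange(4))
        cohorts = periods - ages + 12
        assert cohorts.min() == 0 and cohorts.max() == 15
        for j in range(16):
            cells = np.argwhere(cohorts == j)
            # all cells of one cohort lie on one diagonal
            assert len({p - a for p, a in cells}) == 1


class TestContrasts:
    def test_equal_weights_three_groups(self):
        basis = weighted_orthogonal_contrasts(np.ones(3), 2)
        np.testing.assert_allclose(basis.linear, [-1.0, 0.0, 1.0], atol=1e-12)
        quad = np.array([1.0, -2.0, 1.0]) / np.sqrt(2.0)  # unit weighted RMS
        np.testing.assert_allclose(basis.nonlinear[0], quad, atol=1e-12)

    def test_unequal_weights_hand_computed(self):
        # weighted mean index of weights (1,1,2) is 1.25
        basis = weighted_orthogonal_contrasts(np.array([1.0, 1.0, 2.0]), 2)
        np.testing.assert_allclose(basis.linear, [-1.25, -0.25, 0.75], atol=1e-12)
        assert abs(np.dot(basis.group_weights, basis.linear)) < 1e-10

    def test_invalid_inputs(self):
        with pytest.raises(DesignError):
            weighted_orthogonal_contrasts(np.array([1.0, 0.0, 2.0]), 2)
        with pytest.raises(DesignError):
            weighted_orthogonal_contrasts(np.ones(3), 3)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_gram_matrix_diagonal_under_weight_inner_product(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.1, 10.0, size=13)
        basis = weighted_orthogonal_contrasts(w, 5)
        gram = basis.gram()
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-10
        wn = w / w.sum()
        for vec in basis.vectors():
            assert abs(wn @ vec) < 1e-10
        for vec in basis.nonlinear:  # unit weighted RMS normalization
            assert abs(wn @ vec**2 - 1.0) < 1e-10

    @given(st.integers(0, 2**31 - 1), st.floats(0.01, 1e4))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_rescaling_weights_leaves_basis_unchanged(self, seed, scale):
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.1, 10.0, size=8)
        b1 = weighted_orthogonal_contrasts(w, 5)
        b2 = weighted_orthogonal_contrasts(w * scale, 5)
        np.testing.assert_allclose(b1.linear, b2.linear, atol=1e-9)
        for v1, v2 in zip(b1.nonlinear, b2.nonlinear):
            np.testing.assert_allclose(v1, v2, atol=1e-9)

    def test_year_scale_divides_by_group_width(self):
        b_group = weighted_orthogonal_contrasts(np.ones(4), 2, scale="group")
        b_year = weighted_orthogonal_contrasts(
            np.ones(4), 2, scale="year", group_width=5
        )
        np.testing.assert_allclose(b_year.linear, b_group.linear / 5.0)


@pytest.fixture(scope="module")
def design(men_like_table_module):
    grouped = assign_groups(men_like_table_module, SCHEME)
    bases = build_bases(grouped, SCHEME)
    return build_design_matrix(grouped, bases, scheme=SCHEME), grouped, bases


@pytest.fixture(scope="module")
def men_like_table_module():
    return simulate_microdata(SimConfig(seed=7, n_records=20_000))


class TestDesignMatrix:
    def test_twenty_labeled_columns_without_period_linear(self, design):
        dm, _, _ = design
        assert len(dm.columns) == 20
        assert dm.columns[:3] == ["intercept", "age_linear", "cohort_linear"]
        assert "period_linear" not in dm.columns
        assert [c for c in dm.columns if c.startswith("period_")] == [
            "period_poly2", "period_poly3",
        ]
        assert sum(c.startswith("dow_") for c in dm.columns) == 6
        assert "holiday" in dm.columns

    def test_centered_period_index_equals_age_plus_cohort_contrast(self, design):
        # P_L = A_L + C_L record-for-record on the Lexis surface
        dm, grouped, bases = design
        p_lin = bases["period"].linear[grouped["period_idx"].to_numpy()]
        a_lin = dm.X[:, dm.columns.index("age_linear")]
        c_lin = dm.X[:, dm.columns.index("cohort_linear")]
        np.testing.assert_allclose(p_lin, a_lin + c_lin, atol=1e-9)

    def test_excluded_period_linear_has_zero_residual_on_span(self, design):
        # why the reparameterized model is estimable
        dm, grouped, bases = design
        p_lin = bases["period"].linear[grouped["period_idx"].to_numpy()]
        Z = np.column_stack(
            [np.ones(dm.n_obs),
             dm.X[:, dm.columns.index("age_linear")],
             dm.X[:, dm.columns.index("cohort_linear")]]
        )
        coef, *_ = np.linalg.lstsq(Z, p_lin, rcond=None)
        assert np.abs(p_lin - Z @ coef).max() < 1e-8

    def test_covariate_columns_have_weighted_mean_zero(self, design):
        dm, _, _ = design
        for name in [c for c in dm.columns if c.startswith("dow_")] + ["holiday"]:
            col = dm.X[:, dm.columns.index(name)]
            assert abs(np.average(col, weights=dm.w)) < 1e-10

    def test_group_weights_match_brute_force_sums(self, design):
        dm, grouped, bases = design
        for factor, idx_col in (("age", "age_idx"), ("period", "period_idx"),
                                ("cohort", "cohort_idx")):
            brute = grouped.groupby(idx_col)["weight"].sum()
            np.testing.assert_allclose(
                bases[factor].group_weights, brute.to_numpy(), rtol=1e-12
            )

    def test_empty_group_raises_listing_it(self, men_like_table_module):
        sub = men_like_table_module[men_like_table_module["age"] > 24]
        grouped = assign_groups(sub, SCHEME)
        with pytest.raises(DesignError, match="empty age group"):
            build_bases(grouped, SCHEME)

    def test_missing_covariate_level_raises(self, men_like_table_module):
        sub = men_like_table_module[~men_like_table_module["holiday"]]
        grouped = assign_groups(sub, SCHEME)
        with pytest.raises(DesignError, match="holiday"):
            fit_covariate_coding(grouped)
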