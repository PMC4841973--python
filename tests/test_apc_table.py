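"""Lexis-table algebra, descriptive rates and tidy-file I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apcie import (
    APCTable,
    TableValidationError,
    cell_rates,
    cohort_index,
    cohort_label,
    marginal_rates,
    read_table,
    standardize_rates,
    write_table,
)

STUDY_AGES = 10 + 5 * np.arange(14)      # 10-14 ... 75-79
STUDY_PERIODS = 1985 + 5 * np.arange(6)  # 1985 ... 2010


class TestCohortIndex:
    @pytest.mark.parametrize(
        "i,j,a,expected",
        [
            (14, 1, 14, 1),   # eldest age group, first period: oldest cohort
            (1, 6, 14, 19),   # youngest age group, last period: youngest cohort
            (1, 1, 14, 14),
            (1, 1, 2, 2),
            (2, 1, 2, 1),
        ],
    )
    def test_formula(self, i, j, a, expected):
        assert cohort_index(i, j, a) == expected

    @pytest.mark.parametrize("i,j", [(0, 1), (15, 1), (1, 0)])
    def test_out_of_bounds_names_axis(self, i, j):
        with pytest.raises(IndexError, match="age|period"):
            cohort_index(i, j, a=14)

    @given(a=st.integers(2, 10), p=st.integers(2, 10))
    @settings(max_examples=30, deadline=None)
    def test_bijection_between_diagonals_and_cohorts(self, a, p):
        """Each cell maps to one diagonal; together they cover 1..a+p-1."""
        ks = {(i, j): cohort_index(i, j, a)
              for i in range(1, a + 1) for j in range(1, p + 1)}
        assert set(ks.values()) == set(range(1, a + p))
        for (i, j), k in ks.items():
            assert (j - i) == (k - a)  # constant along each anti-diagonal


class TestCohortLabels:
    @pytest.mark.parametrize(
        "k,label", [(1, "1905-09"), (2, "1910-14"), (19, "1995-99")]
    )
    def test_study_grid_labels(self, k, label):
        assert cohort_label(k, STUDY_AGES, STUDY_PERIODS) == label

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            cohort_label(20, STUDY_AGES, STUDY_PERIODS)


class TestRates:
    def test_cell_rates_definition(self, constant_table):
        rates = cell_rates(constant_table)
        assert np.allclose(rates, 20.0)
        assert np.allclose(cell_rates(constant_table, scale=1.0), 2e-4)

    def test_zero_deaths_zero_rate(self):
        t = APCTable(np.array([[0.0, 26.0]]), np.full((1, 2), 1e5),
                     np.array([40]), np.array([1985, 1990]))
        assert cell_rates(t)[0, 0] == 0.0
        assert cell_rates(t)[0, 1] == 26.0

    def test_marginal_is_pooled_ratio_not_mean_of_rates(self):
        # one age row, deaths (10, 30) over equal exposures: pooled 20
        t = APCTable(np.array([[10.0, 30.0], [10.0, 30.0]]),
                     np.full((2, 2), 1e5),
                     np.array([40, 45]), np.array([1985, 1990]))
        assert marginal_rates(t, "age").rates == pytest.approx([20.0, 20.0])

    def test_constant_surface_all_marginals_equal(self, constant_table):
        for axis in ("age", "period", "cohort"):
            assert marginal_rates(constant_table, axis).rates == pytest.approx(20.0)

    def test_cohort_marginal_matches_brute_force_diagonals(self):
        rng = np.random.default_rng(5)
        a, p = 4, 3
        t = APCTable(rng.poisson(50, (a, p)).astype(float),
                     rng.uniform(5e4, 2e5, (a, p)),
                     10 + 5 * np.arange(a), 1985 + 5 * np.arange(p))
        rt = marginal_rates(t, "cohort")
        assert len(rt.rates) == a + p - 1
        for k in range(1, a + p):
            cells = [(i, j) for i in range(1, a + 1) for j in range(1, p + 1)
                     if a - i + j == k]
            d = sum(t.deaths[i - 1, j - 1] for i, j in cells)
            e = sum(t.exposures[i - 1, j - 1] for i, j in cells)
            assert rt.rates[k - 1] == pytest.approx(1e5 * d / e)
        # corner cohorts are single cells
        assert rt.rates[0] == pytest.approx(1e5 * t.deaths[-1, 0] / t.exposures[-1, 0])
        assert rt.rates[-1] == pytest.approx(1e5 * t.deaths[0, -1] / t.exposures[0, -1])

    def test_every_axis_conserves_total_deaths(self, study_grid_table):
        t = study_grid_table
        for axis in ("age", "period", "cohort"):
            rt = marginal_rates(t, axis)
            # recover numerators from pooled rates and pooled exposures
            if axis == "cohort":
                k = t.cohort_of_cell()
                e = np.array([t.exposures[k == c].sum()
                              for c in range(1, t.n_cohorts + 1)])
            elif axis == "age":
                e = t.exposures.sum(axis=1)
            else:
                e = t.exposures.sum(axis=0)
            assert (rt.rates * e / 1e5).sum() == pytest.approx(t.deaths.sum())

    def test_rates_invariant_under_joint_scaling(self, study_grid_table):
        t = study_grid_table
        scaled = APCTable(t.deaths * 3, t.exposures * 3,
                          t.age_starts, t.period_starts)
        for axis in ("age", "period", "cohort"):
            assert marginal_rates(scaled, axis).rates == pytest.approx(
                marginal_rates(t, axis).rates
            )

    def test_unknown_axis(self, constant_table):
        with pytest.raises(ValueError, match="axis"):
            marginal_rates(constant_table, "decade")


class TestStandardization:
    @pytest.mark.parametrize(
        "rates,weights,expected",
        [
            ([10.0, 30.0], [0.5, 0.5], 20.0),
            ([10.0, 30.0], [1.0, 0.0], 10.0),
            ([7.5, 7.5, 7.5], [0.2, 0.5, 0.3], 7.5),  # constant surface
            ([10.0, 30.0], [2.0, 2.0], 20.0),          # normalized internally
        ],
    )
    def test_direct_standardization(self, rates, weights, expected):
        assert standardize_rates(rates, weights) == pytest.approx(expected)

    def test_errors(self):
        with pytest.raises(ValueError, match="weights"):
            standardize_rates([1.0, 2.0], [1.0])
        with pytest.raises(ValueError, match="zero"):
            standardize_rates([1.0, 2.0], [0.0, 0.0])


class TestIO:
    def test_round_trip_lossless(self, tmp_path, study_grid_table):
        path = tmp_path / "t.csv"
        write_table(study_grid_table, path)
        back = read_table(path)
        assert np.array_equal(back.deaths, study_grid_table.deaths)
        assert np.allclose(back.exposures, study_grid_table.exposures)
        assert np.array_equal(back.age_starts, study_grid_table.age_starts)
        assert np.array_equal(back.period_starts, study_grid_table.period_starts)

    def test_missing_cell_named(self, tmp_path, constant_table):
        path = tmp_path / "t.csv"
        write_table(constant_table, path)
        df = pd.read_csv(path)
        df = df[~((df.age_start == 20) & (df.period_start == 1990))]
        df.to_csv(path, index=False)
        with pytest.raises(TableValidationError, match="age_start=20.*period_start=1990"):
            read_table(path)

    def test_nonpositive_exposure_rejected(self, tmp_path, constant_table):
        path = tmp_path / "t.csv"
        write_table(constant_table, path)
        df = pd.read_csv(path)
        df.loc[0, "exposure"] = 0.0
        df.to_csv(path, index=False)
        with pytest.raises(TableValidationError, match="exposure"):
            read_table(path)

    def test_malformed_numeric_rejected(self, tmp_path, constant_table):
        path = tmp_path / "t.csv"
        write_table(constant_table, path)
        df = pd.read_csv(path).astype({"deaths": object})
        df.loc[3, "deaths"] = "twenty"
        df.to_csv(path, index=False)
        with pytest.raises(TableValidationError, match="deaths"):
            read_table(path)

    def test_stratum_filter(self, tmp_path, constant_table):
        path = tmp_path / "t.csv"
        rows = []
        for country, bump in (("Japan", 0.0), ("Korea", 5.0)):
            for i, age in enumerate(constant_table.age_starts):
                for j, per in enumerate(constant_table.period_starts):
                    rows.append({"age_start": age, "period_start": per,
                                 "deaths": 20 + bump, "exposure": 1e5,
                                 "country": country})
        pd.DataFrame(rows).to_csv(path, index=False)
        t = read_table(path, stratum={"country": "Korea"})
        assert np.allclose(t.deaths, 25.0)
        assert t.stratum["country"] == "Korea"
        with pytest.raises(TableValidationError, match="stratum"):
            read_table(path, stratum={"country": "France"})


class TestInvariants:
    def test_shape_mismatch(self):
        with pytest.raises(TableValidationError):
            APCTable(np.zeros((2, 3)), np.ones((2, 2)),
                     np.array([10, 15]), np.array([1985, 1990, 1995]))

    def test_negative_deaths(self):
        with pytest.raises(TableValidationError):
            APCTable(np.array([[-1.0, 0.0]]), np.ones((1, 2)),
                     np.array([10]), np.array([1985, 1990]))

    def test_zero_exposure(self):
        with pytest.raises(TableValidationError):
            APCTable(np.zeros((1, 2)), np.array([[1.0, 0.0]]),
                     np.array([10]), np.array([1985, 1990]))

    def test_irregular_age_step(self):
        with pytest.raises(TableValidationError, match="steps"):
            APCTable(np.zeros((2, 2)), np.ones((2, 2)),
                     np.array([10, 20]), np.array([1985, 1990]))

    def test_cohort_count(self, study_grid_table):
        assert study_grid_table.n_cohorts == 19
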