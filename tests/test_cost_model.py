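import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chronicost.cost_model import (
    aggregate_pac,
    baseline_per_capita,
    compute_pac,
    cost_ratio,
    extrapolate_national,
    per_capita_surfaces,
    project_per_capita,
    total_costs,
    total_excess_costs,
)
from chronicost.grids import (
    AGE_GROUPS,
    DIAGNOSES,
    EXPENDITURE_FIELDS,
    SEXES,
)
from chronicost.prevalence_projection import PrevalenceSurface
from chronicost.synthetic_data.costs import COLUMNS, AggregatedCostTable


def make_table(per_capita=60.0, members=10, cost_per_field=None):
    """Uniform synthetic table: same members and per-field cost everywhere."""
    if cost_per_field is None:
        cost_per_field = per_capita * members / len(EXPENDITURE_FIELDS)
    rows = []
    for d in DIAGNOSES:
        for s in SEXES:
            for lo, hi in AGE_GROUPS:
                for f in EXPENDITURE_FIELDS:
                    rows.append((f, d, s, lo, hi, float(cost_per_field), int(members)))
    return AggregatedCostTable(pd.DataFrame(rows, columns=list(COLUMNS)))


class TestBaselinePerCapita:
    def test_six_fields_hand_sum(self):
        # one stratum worth: 6 fields x 100 EUR over 10 members -> 60 per head
        table = make_table(cost_per_field=100.0, members=10)
        prof = baseline_per_capita(table)
        for d in DIAGNOSES:
            np.testing.assert_allclose(prof.curves[d], 60.0)
            for s in SEXES:
                assert prof.aggregate[(d, s)] == pytest.approx(60.0)

    def test_all_zero_costs(self):
        table = make_table(cost_per_field=0.0, members=10)
        prof = baseline_per_capita(table)
        for d in DIAGNOSES:
            assert (prof.curves[d] == 0).all()

    def test_zero_member_stratum_warns_and_zeroes(self):
        df = make_table(cost_per_field=100.0, members=10).frame.copy()
        mask = (df["diagnosis"] == "T1") & (df["sex"] == "male") & (df["age_group_lo"] == 0)
        df.loc[mask, ["total_cost_eur", "member_count"]] = 0
        with pytest.warns(UserWarning, match="zero members"):
            prof = baseline_per_capita(AggregatedCostTable(df))
        assert prof.curves["T1"][0, 0] == 0.0

    def test_negative_entries_rejected(self):
        df = make_table().frame.copy()
        df.loc[0, "total_cost_eur"] = -1.0
        with pytest.raises(ValueError):
            AggregatedCostTable(df)

    def test_default_calibration_near_published_values(self, profile):
        expected = {
            ("T1", "male"): 4285.0,
            ("T1", "female"): 4889.0,
            ("T2", "male"): 3868.0,
            ("T2", "female"): 3889.0,
            ("none", "male"): 2360.0,
            ("none", "female"): 2316.0,
        }
        for key, val in expected.items():
            assert profile.aggregate[key] == pytest.approx(val, rel=0.01)


class TestProjectPerCapita:
    def test_zero_growth_constant(self, profile):
        out = project_per_capita(profile, 0.0, 2040)
        for d in ("T1", "T2", "none"):
            np.testing.assert_allclose(out[d], profile.curves[d])

    def test_growth_compounding(self):
        prof_curves = {
            "none": np.full((2, 101), 2000.0),
            "T1": np.full((2, 101), 4000.0),
            "T2": np.full((2, 101), 4000.0),
        }
        from chronicost.cost_model import PerCapitaCostProfile

        prof = PerCapitaCostProfile(prof_curves)
        out = project_per_capita(prof, 0.05, 2040)
        expected = 2000.0 + 2000.0 * 1.05**30
        np.testing.assert_allclose(out["T1"], expected)
        assert expected == pytest.approx(10643.9, abs=0.05)

    def test_zero_excess_stays_at_none(self):
        from chronicost.cost_model import PerCapitaCostProfile

        curves = {d: np.full((2, 101), 1500.0) for d in DIAGNOSES}
        prof = PerCapitaCostProfile(curves)
        for r in (0.0, 0.01, 0.05):
            out = project_per_capita(prof, r, 2035)
            np.testing.assert_allclose(out["T2"], curves["none"])

    def test_invalid_growth_rejected(self, profile):
        with pytest.raises(ValueError):
            project_per_capita(profile, -1.0, 2030)
        with pytest.raises(ValueError):
            project_per_capita(profile, 0.01, 2005)


def _prev_pop_percap(p1=0.0, p2=0.0, n=1000.0, c=None):
    prev = PrevalenceSurface(
        {"T1": np.full((2, 101, 31), p1), "T2": np.full((2, 101, 31), p2)}
    )
    pop = np.full((2, 101, 31), n)
    if c is None:
        c = {d: np.full((2, 101, 31), 1000.0) for d in ("T1", "T2", "none")}
    return prev, pop, c


class TestTotals:
    def test_zero_prevalence_zero_diabetes_totals(self):
        prev, pop, c = _prev_pop_percap()
        out = total_costs(prev, pop, c)
        assert (out["T1"] == 0).all() and (out["T2"] == 0).all()
        assert (out["none"] > 0).all()

    def test_two_strata_hand_sum(self):
        prev = PrevalenceSurface(
            {"T1": np.zeros((2, 101, 31)), "T2": np.zeros((2, 101, 31))}
        )
        prev.values["T2"][0, 10, 0] = 0.1
        prev.values["T2"][0, 20, 0] = 0.2
        pop = np.zeros((2, 101, 31))
        pop[0, 10, 0] = 100.0
        pop[0, 20, 0] = 200.0
        c = {d: np.zeros((2, 101, 31)) for d in ("T1", "T2", "none")}
        c["T2"][0, 10, 0] = 1000.0
        c["T2"][0, 20, 0] = 2000.0
        out = total_costs(prev, pop, c)
        assert out["T2"][0, 0] == pytest.approx(90_000.0)

    def test_linearity_in_population(self):
        prev, pop, c = _prev_pop_percap(p1=0.01, p2=0.05)
        out1 = total_costs(prev, pop, c)
        out2 = total_costs(prev, 2.0 * pop, c)
        for d in out1:
            np.testing.assert_allclose(out2[d], 2.0 * out1[d])

    def test_excess_identity_with_totals(self, profile, pop, epi):
        # total costs minus cases priced at c_none equals total excess
        prev = PrevalenceSurface(
            {
                "T1": np.repeat(epi.prevalence0["T1"][:, :, None], 31, axis=2),
                "T2": np.repeat(epi.prevalence0["T2"][:, :, None], 31, axis=2),
            }
        )
        percap = per_capita_surfaces(profile, 0.03)
        totals = total_costs(prev, pop.counts, percap)
        excess_surf = {d: percap[d] - percap["none"] for d in ("T1", "T2")}
        excess = total_excess_costs(prev, pop.counts, excess_surf)
        for d in ("T1", "T2"):
            priced_at_none = (pop.counts * prev.values[d] * percap["none"]).sum(axis=1)
            np.testing.assert_allclose(totals[d] - priced_at_none, excess[d], rtol=1e-9)

    def test_single_stratum_excess(self):
        prev, pop, _ = _prev_pop_percap(p2=0.05, n=1000.0)
        excess = {
            "T1": np.zeros((2, 101, 31)),
            "T2": np.full((2, 101, 31), 3000.0),
        }
        out = total_excess_costs(prev, pop, excess)
        assert out["T2"][0, 0] == pytest.approx(0.05 * 1000.0 * 3000.0 * 101)

    def test_grid_mismatch_rejected(self):
        prev, pop, c = _prev_pop_percap()
        with pytest.raises(ValueError, match="mismatch"):
            total_costs(prev, pop[:, :50, :], c)

    def test_growth_monotonicity(self, profile, pop, epi):
        prev = PrevalenceSurface(
            {
                "T1": np.repeat(epi.prevalence0["T1"][:, :, None], 31, axis=2),
                "T2": np.repeat(epi.prevalence0["T2"][:, :, None], 31, axis=2),
            }
        )
        results = {}
        for r in (0.0, 0.01, 0.05):
            results[r] = total_costs(prev, pop.counts, per_capita_surfaces(profile, r))
        for d in ("T1", "T2"):
            t0, t1, t5 = (results[r][d].sum(axis=0) for r in (0.0, 0.01, 0.05))
            assert (t5[1:] > t1[1:]).all()
            assert (t1[1:] > t0[1:]).all()

    def test_scale_equivariance(self, noiseless_cost_table, pop, epi):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            prof = baseline_per_capita(noiseless_cost_table)
            scaled_df = noiseless_cost_table.frame.copy()
            scaled_df["total_cost_eur"] *= 3.0
            prof3 = baseline_per_capita(AggregatedCostTable(scaled_df))
        prev = PrevalenceSurface(
            {
                "T1": np.repeat(epi.prevalence0["T1"][:, :, None], 31, axis=2),
                "T2": np.repeat(epi.prevalence0["T2"][:, :, None], 31, axis=2),
            }
        )
        c1 = per_capita_surfaces(prof, 0.01)
        c3 = per_capita_surfaces(prof3, 0.01)
        tot1 = total_costs(prev, pop.counts, c1)
        tot3 = total_costs(prev, pop.counts, c3)
        for d in ("T1", "T2", "none"):
            np.testing.assert_allclose(tot3[d], 3.0 * tot1[d], rtol=1e-12)
        # ratios and PAC are scale-free (where above the euro floor)
        r1 = cost_ratio(c1["T2"], prof.curves["none"])
        r3 = cost_ratio(c3["T2"], prof3.curves["none"])
        mask = np.repeat((prof.curves["none"] > 1.0)[:, :, None], 31, axis=2)
        np.testing.assert_allclose(r3[mask], r1[mask], rtol=1e-12)


class TestCostRatio:
    def test_equal_costs_unit_ratio(self):
        c = np.full((2, 101, 31), 2360.0)
        np.testing.assert_allclose(cost_ratio(c, np.full((2, 101), 2360.0)), 1.0)

    def test_simple_division(self):
        r = cost_ratio(np.full((2, 101, 31), 4720.0), np.full((2, 101), 2360.0))
        np.testing.assert_allclose(r, 2.0)

    def test_strictly_increasing_under_growth(self, profile):
        c = per_capita_surfaces(profile, 0.05)
        r = cost_ratio(c["T2"], profile.curves["none"])
        e = profile.excess("T2")
        mask = (e > 0) & (profile.curves["none"] > 1.0)
        diffs = np.diff(r, axis=2)[mask]
        assert (diffs > 0).all()

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            cost_ratio(np.full((2, 101), np.inf), np.full((2, 101), 1.0))


class TestPac:
    def test_zero_prevalence(self):
        pac = compute_pac(np.zeros((2, 101, 31)), np.full((2, 101, 31), 3.0))
        assert (pac == 0).all()

    def test_unit_ratio(self):
        pac = compute_pac(np.full((2, 101, 31), 0.3), np.ones((2, 101, 31)))
        assert (pac == 0).all()

    def test_direct_evaluation(self):
        pac = compute_pac(np.array([[0.5]]), np.array([[3.0]]))
        assert pac[0, 0] == pytest.approx(0.5)

    def test_protective_ratio_clipped_to_zero(self):
        pac = compute_pac(np.array([[0.5]]), np.array([[0.5]]))
        assert pac[0, 0] == 0.0

    def test_always_below_one(self):
        pac = compute_pac(np.array([[0.999]]), np.array([[1000.0]]))
        assert pac[0, 0] < 1.0

    @given(
        p=st.floats(min_value=0.0, max_value=1.0),
        cd=st.floats(min_value=0.01, max_value=1e5),
        cn=st.floats(min_value=0.01, max_value=1e5),
    )
    @settings(max_examples=200, deadline=None)
    def test_algebraic_identity(self, p, cd, cn):
        # p(R-1)/(1+p(R-1)) == p(cd-cn) / (p*cd + (1-p)*cn) for R = cd/cn
        r = cd / cn
        x = p * (r - 1.0)
        lhs = x / (1.0 + x)
        rhs = p * (cd - cn) / (p * cd + (1.0 - p) * cn)
        assert lhs == pytest.approx(rhs, abs=1e-12, rel=1e-9)


class TestAggregatePac:
    def test_zero_pac(self):
        prev, pop, c = _prev_pop_percap(p2=0.0)
        out = aggregate_pac(prev, pop, c, "T2")
        np.testing.assert_allclose(out, 0.0, atol=1e-15)

    def test_single_stratum_equals_pointwise_pac(self):
        p, cd, cn = 0.2, 3000.0, 1000.0
        prev = PrevalenceSurface(
            {"T1": np.zeros((2, 101, 31)), "T2": np.full((2, 101, 31), p)}
        )
        pop = np.full((2, 101, 31), 500.0)
        c = {
            "T1": np.full((2, 101, 31), cn),
            "T2": np.full((2, 101, 31), cd),
            "none": np.full((2, 101, 31), cn),
        }
        out = aggregate_pac(prev, pop, c, "T2")
        x = p * (cd / cn - 1.0)
        np.testing.assert_allclose(out, x / (1.0 + x), rtol=1e-12)

    def test_equals_excess_over_total_on_random_tables(self):
        rng = np.random.default_rng(5)
        prev = PrevalenceSurface(
            {
                "T1": rng.uniform(0, 0.05, (2, 101, 31)),
                "T2": rng.uniform(0, 0.3, (2, 101, 31)),
            }
        )
        pop = rng.uniform(100, 1e5, (2, 101, 31))
        c = {
            "T1": rng.uniform(2000, 8000, (2, 101, 31)),
            "T2": rng.uniform(2000, 8000, (2, 101, 31)),
            "none": rng.uniform(1000, 4000, (2, 101, 31)),
        }
        out = aggregate_pac(prev, pop, c, "T2")
        excess = (pop * prev.values["T2"] * (c["T2"] - c["none"])).sum(axis=(0, 1))
        total = (
            pop * (prev.values["T2"] * c["T2"] + (1 - prev.values["T2"]) * c["none"])
        ).sum(axis=(0, 1))
        np.testing.assert_allclose(out, excess / total, rtol=1e-12)

    def test_zero_total_cost_rejected(self):
        prev, pop, _ = _prev_pop_percap(p2=0.1)
        c = {d: np.zeros((2, 101, 31)) for d in ("T1", "T2", "none")}
        with pytest.raises(ValueError, match="zero total"):
            aggregate_pac(prev, pop, c, "T2")


class TestExtrapolateNational:
    def test_type2_sixteen_billion(self):
        out = extrapolate_national(0.102, 160e9 * 0.068, 0.068)
        assert out["national_total"] == pytest.approx(160e9)
        assert out["attributable"] == pytest.approx(16.32e9)

    def test_type1_six_billion(self):
        out = extrapolate_national(0.038, 160e9 * 0.068, 0.068)
        assert out["attributable"] == pytest.approx(6.08e9)

    def test_zero_pac(self):
        out = extrapolate_national(0.0, 1e9, 0.068)
        assert out["attributable"] == 0.0

    def test_zero_sample_fraction_rejected(self):
        with pytest.raises(ValueError, match="sample_fraction"):
            extrapolate_national(0.1, 1e9, 0.0)
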