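"""ISO weeks, activity-based FTE, group assignment, pathologist-years."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import labequity as le
from labequity.scoring import UNITS_PREFIX, score_table
from labequity.staffing import (
    GroupingConfig,
    PRO_RATA_PREFIX,
    assign_group,
    build_pathologist_years,
    compute_fte,
    group_summary,
    iso_week_key,
    weeks_signed,
)
from labequity.synthetic import synthetic_tariff

GROUPING = GroupingConfig(
    org_of_site={"AH": "alpha_org", "B1H": "beta_org", "B2H": "beta_org"},
    alpha_org="alpha_org",
    subgroup_of_site={"B1H": "beta1", "B2H": "beta2"},
)


class TestIsoWeekKey:
    @pytest.mark.parametrize(
        "date, key",
        [
            (dt.date(2019, 12, 30), (2020, 1)),  # Monday belonging to next ISO year
            (dt.date(2016, 1, 1), (2015, 53)),   # Friday still in prior ISO year
            (dt.date(2018, 7, 4), (2018, 27)),
        ],
    )
    def test_boundaries(self, date, key):
        assert iso_week_key(date) == key

    @given(st.dates(min_value=dt.date(2000, 1, 4), max_value=dt.date(2030, 12, 20)))
    def test_whole_week_shares_one_key(self, d):
        monday = d - dt.timedelta(days=d.weekday())
        keys = {iso_week_key(monday + dt.timedelta(days=i)) for i in range(7)}
        assert len(keys) == 1


class TestWeeksSigned:
    def test_many_cases_one_day(self):
        assert weeks_signed([dt.date(2018, 3, 7)] * 10) == 1

    def test_24_mondays(self):
        mondays = [dt.date(2018, 1, 1) + dt.timedelta(weeks=k) for k in range(24)]
        assert weeks_signed(mondays) == 24

    def test_matches_distinct_monday_oracle(self):
        rng = np.random.default_rng(11)
        dates = [
            dt.date(2017, 1, 1) + dt.timedelta(days=int(x))
            for x in rng.integers(0, 364, size=200)
        ]
        mondays = {d - dt.timedelta(days=d.weekday()) for d in dates}
        assert weeks_signed(dates) == len(mondays)


class TestComputeFte:
    @pytest.mark.parametrize(
        "weeks, fte",
        [(24, 0.5), (42, 1.0), (41, 41 / 48), (0, 0.0), (48, 1.0), (1, 1 / 48)],
    )
    def test_rule(self, weeks, fte):
        assert compute_fte(weeks) == pytest.approx(fte)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            compute_fte(-1)

    def test_monotone_with_fixed_point_above_41(self):
        vals = [compute_fte(w) for w in range(0, 55)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert all(v == 1.0 for v in vals[42:])


class TestAssignGroup:
    def test_alpha_majority_surgical(self):
        label, num, fb = assign_group(
            {"alpha_org": 0.7, "beta_org": 0.3}, {"AH": 0.7, "B1H": 0.3}, GROUPING
        )
        assert (label, num, fb) == ("alpha", 1, False)

    def test_tie_goes_to_beta(self):
        label, _, _ = assign_group(
            {"alpha_org": 0.5, "beta_org": 0.5}, {"B1H": 0.6, "B2H": 0.4}, GROUPING
        )
        assert label == "beta1"

    def test_beta_subclassified_by_all_case_fractions(self):
        label, num, _ = assign_group(
            {"beta_org": 1.0}, {"B1H": 0.2, "B2H": 0.8}, GROUPING
        )
        assert (label, num) == ("beta2", 3)

    def test_beta_inner_tie_goes_to_beta2(self):
        label, _, _ = assign_group({"beta_org": 1.0}, {"B1H": 0.5, "B2H": 0.5}, GROUPING)
        assert label == "beta2"

    def test_cytology_only_uses_all_case_fallback(self):
        label, _, fb = assign_group({}, {"AH": 0.9, "B1H": 0.1}, GROUPING)
        assert label == "alpha" and fb is True

    def test_label_permutation(self):
        cfg = GroupingConfig(
            org_of_site=GROUPING.org_of_site,
            alpha_org="alpha_org",
            subgroup_of_site=GROUPING.subgroup_of_site,
            label_map={"alpha": 3, "beta1": 1, "beta2": 2},
        )
        _, num, _ = assign_group({"alpha_org": 1.0}, {"AH": 1.0}, cfg)
        assert num == 3


def _cases_for_weeks(n_weeks, total_units, year=2018):
    """One case per Monday; block counts back-solved so the 1 + 0.5/block
    tariff yields exactly total_units."""
    n_blocks = int((total_units - n_weeks) / 0.5)
    q, r = divmod(n_blocks, n_weeks)
    cases = []
    for k in range(n_weeks):
        cases.append(
            le.CaseRecord(
                case_id=f"W{k}",
                pathologist_id="P1",
                signout_date=dt.date(year, 1, 1) + dt.timedelta(weeks=k),
                site="AH",
                organization="alpha_org",
                case_class="surgical",
                specimen_count=1,
                block_count=q + (1 if k < r else 0),
            )
        )
    return cases


class TestBuildPathologistYears:
    def test_half_year_pro_rata_doubles(self):
        # 24 signing weeks, 3000 raw units -> FTE 0.5, pro-rata 6000
        scored, _ = score_table(_cases_for_weeks(24, 3000.0), synthetic_tariff())
        py = build_pathologist_years(scored, GROUPING)
        row = py.iloc[0]
        assert row["weeks_signed"] == 24
        assert row["fte"] == 0.5
        assert row[UNITS_PREFIX + "L4E"] == pytest.approx(3000.0)
        assert row[PRO_RATA_PREFIX + "L4E"] == pytest.approx(6000.0)

    def test_full_time_pro_rata_equals_raw(self):
        scored, _ = score_table(_cases_for_weeks(45, 7000.0), synthetic_tariff())
        py = build_pathologist_years(scored, GROUPING)
        row = py.iloc[0]
        assert row["fte"] == 1.0
        assert row[PRO_RATA_PREFIX + "L4E"] == row[UNITS_PREFIX + "L4E"]

    def test_recovers_generator_ledger_exactly(self, small_lab, small_scenario):
        from labequity.ingest import ExclusionConfig, apply_exclusions
        from labequity.synthetic import grouping_config

        cases, ledger = small_lab
        kept, _ = apply_exclusions(cases, ExclusionConfig(study_years=small_scenario.years))
        scored, _ = score_table(kept, synthetic_tariff())
        py = build_pathologist_years(scored, grouping_config(small_scenario))
        merged = py.merge(
            ledger.pathologist_years, on=["pathologist_id", "year"],
            suffixes=("", "_truth"), validate="1:1",
        )
        assert len(merged) == len(ledger.pathologist_years)
        assert (merged["weeks_signed"] == merged["weeks_signed_truth"]).all()
        assert (merged["fte"] == merged["fte_truth"]).all()
        assert (merged["group"] == merged["group_truth"]).all()
        assert merged[UNITS_PREFIX + "L4E"].to_numpy() == pytest.approx(
            merged["units_L4E"].to_numpy(), abs=1e-9
        )

    def test_case_order_invariance(self, small_lab):
        cases, _ = small_lab
        subset = cases[:2000]
        scored_a, _ = score_table(subset, synthetic_tariff())
        scored_b, _ = score_table(list(reversed(subset)), synthetic_tariff())
        py_a = build_pathologist_years(scored_a, GROUPING)
        py_b = build_pathologist_years(scored_b, GROUPING)
        pd.testing.assert_frame_equal(
            py_a.sort_values(["pathologist_id", "year"]).reset_index(drop=True),
            py_b.sort_values(["pathologist_id", "year"]).reset_index(drop=True),
        )


def _pyears(rows):
    base = {"pathologist_id": "P", "weeks_signed": 46, "group_label": "alpha",
            "group_fallback": False, "n_cases": 100}
    out = []
    for i, r in enumerate(rows):
        d = dict(base)
        d["pathologist_id"] = f"P{i}"
        d.update(r)
        d[UNITS_PREFIX + "L4E"] = d[PRO_RATA_PREFIX + "L4E"] * d["fte"]
        out.append(d)
    return pd.DataFrame(out)


class TestGroupSummary:
    def test_single_member_sd_missing(self):
        py = _pyears([{"year": 2018, "fte": 1.0, "group": 1, PRO_RATA_PREFIX + "L4E": 5000.0}])
        yearly, _ = group_summary(py, "L4E")
        row = yearly.iloc[0]
        assert row["member_mean"] == row["member_median"] == 5000.0
        assert row["member_min"] == row["member_max"] == 5000.0
        assert pd.isna(row["member_sd"])

    def test_two_member_sample_sd(self):
        py = _pyears([
            {"year": 2018, "fte": 1.0, "group": 1, PRO_RATA_PREFIX + "L4E": 4000.0},
            {"year": 2018, "fte": 1.0, "group": 1, PRO_RATA_PREFIX + "L4E": 6000.0},
        ])
        yearly, _ = group_summary(py, "L4E")
        assert yearly.iloc[0]["member_mean"] == 5000.0
        assert yearly.iloc[0]["member_sd"] == pytest.approx(np.sqrt(2e6))

    def test_period_average_n_can_be_fractional(self):
        rows = [{"year": 2018, "fte": 1.0, "group": 1, PRO_RATA_PREFIX + "L4E": 5000.0}
                for _ in range(10)]
        rows += [{"year": 2019, "fte": 1.0, "group": 1, PRO_RATA_PREFIX + "L4E": 5000.0}
                 for _ in range(11)]
        _, period = group_summary(_pyears(rows), "L4E")
        assert period.iloc[0]["n_signers"] == pytest.approx(10.5)

    def test_member_mean_differs_from_units_per_fte(self):
        # one full-timer at 8000, one half-timer pro-rata 4000:
        # member mean = 6000, but group total/FTE = (8000+2000)/1.5
        py = _pyears([
            {"year": 2018, "fte": 1.0, "group": 1, PRO_RATA_PREFIX + "L4E": 8000.0},
            {"year": 2018, "fte": 0.5, "group": 1, PRO_RATA_PREFIX + "L4E": 4000.0},
        ])
        yearly, _ = group_summary(py, "L4E")
        assert yearly.iloc[0]["member_mean"] == pytest.approx(6000.0)
        assert yearly.iloc[0]["units_per_fte"] == pytest.approx(10000.0 / 1.5)
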