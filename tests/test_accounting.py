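import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import events_frame, make_event
from copdcost import accounting
from copdcost.accounting import (
    PriceIndexError,
    PriceIndexSeries,
    UnitCostTable,
    adjust_unit_cost,
    assemble_breakdown,
    compute_direct_costs,
    compute_indirect_costs,
    compute_stratum_costs,
    filter_copd_events,
    filter_copd_medication,
    per_capita,
    percent_change,
    round_half_up,
    summarise_utilisation,
    validate_breakdown,
)


class TestRoundHalfUp:
    @pytest.mark.parametrize(
        "x,expected",
        [(0.5, 1), (1.5, 2), (2.4, 2), (2.5, 3), (-0.5, -1), (-2.5, -3), (0.0, 0), (17.0125, 17)],
    )
    def test_values(self, x, expected):
        assert round_half_up(x) == expected


class TestUnitCostTable:
    def test_non_positive_cost_rejected(self):
        with pytest.raises(ValueError, match="shc_hospital_day"):
            UnitCostTable(142, 0, 200, 24600, 2006)


class TestPriceIndex:
    def test_reference_year_required(self):
        with pytest.raises(ValueError, match="reference year"):
            PriceIndexSeries({2005: 100.0}, reference_year=2006)

    def test_non_positive_index_rejected(self):
        with pytest.raises(ValueError, match="must be > 0"):
            PriceIndexSeries({2006: 0.0}, reference_year=2006)

    def test_missing_year_is_explicit_error(self, flat_index):
        with pytest.raises(PriceIndexError, match="1980"):
            flat_index.at(1980)


class TestAdjustUnitCost:
    def test_identity_at_reference_year(self, flat_index):
        assert adjust_unit_cost(590, 2006, flat_index) == 590

    def test_ratio_arithmetic(self):
        index = PriceIndexSeries({2000: 95.0, 2006: 100.0}, reference_year=2006)
        assert adjust_unit_cost(590, 2000, index) == pytest.approx(560.50)

    def test_reference_year_costs_unchanged(self, unit_costs, flat_index):
        for cost in (142, 590, 200, 24600):
            assert adjust_unit_cost(cost, 2006, flat_index) == cost


class TestDiagnosisFilter:
    def test_empty_input(self):
        assert filter_copd_events(events_frame([])).empty

    def test_enumerated_codes(self):
        events = events_frame([make_event(primary_icd10=c) for c in ["J44", "J43.1", "J45", "J18", "I50"]])
        kept = filter_copd_events(events)
        assert len(kept) == 2
        assert set(kept["primary_icd10"]) == {"J44", "J43.1"}

    def test_subcodes_match_by_prefix(self):
        events = events_frame([make_event(primary_icd10=c) for c in ["J44.0", "J44.8", "J43.9"]])
        assert len(filter_copd_events(events)) == 3

    def test_reads_only_primary_code(self):
        # a lone primary J44 event is retained; there is no secondary-code field to consult
        events = events_frame([make_event(primary_icd10="J44")])
        assert len(filter_copd_events(events)) == 1

    def test_drug_purchases_never_selected(self):
        events = events_frame([make_event(category="drug_purchase", primary_icd10="J44")])
        assert filter_copd_events(events).empty

    def test_benefit_events_filtered_by_cause_code(self):
        events = events_frame(
            [
                make_event(category="sickness_allowance_day", primary_icd10="J44"),
                make_event(category="sickness_allowance_day", primary_icd10="J45"),
                make_event(category="disability_pension", primary_icd10="J43"),
            ]
        )
        assert len(filter_copd_events(events)) == 2

    def test_j33_logged_but_not_retained(self, caplog):
        events = events_frame([make_event(category="disability_pension", primary_icd10="J33")])
        with caplog.at_level("WARNING"):
            kept = filter_copd_events(events)
        assert kept.empty
        assert "J33" in caplog.text

    def test_idempotent(self):
        events = events_frame(
            [make_event(primary_icd10=c) for c in ["J44", "J43", "J45", "I50", "J18", "J44.0"]]
        )
        once = filter_copd_events(events)
        twice = filter_copd_events(once)
        pd.testing.assert_frame_equal(once, twice)


class TestMedicationFilter:
    def test_no_entitled_persons(self):
        events = events_frame([make_event(category="drug_purchase", quantity=10.0)])
        assert filter_copd_medication(events).empty

    def test_truth_table(self):
        events = events_frame(
            [
                make_event(category="drug_purchase", reimbursement_entitled=e, uses_anticholinergic=a)
                for e, a in [(True, True), (True, False), (False, True), (False, False)]
            ]
        )
        kept = filter_copd_medication(events)
        assert len(kept) == 1
        assert kept["reimbursement_entitled"].all() and kept["uses_anticholinergic"].all()

    def test_person_level_rule(self):
        # entitled anticholinergic user buying any respiratory drug: flags ride on the person
        events = events_frame(
            [make_event(category="drug_purchase", reimbursement_entitled=True, uses_anticholinergic=True)]
        )
        assert len(filter_copd_medication(events)) == 1

    def test_non_drug_events_never_selected(self):
        events = events_frame(
            [make_event(category="shc_hospital_day", reimbursement_entitled=True, uses_anticholinergic=True)]
        )
        assert filter_copd_medication(events).empty

    def test_idempotent(self):
        events = events_frame(
            [
                make_event(category="drug_purchase", reimbursement_entitled=e, uses_anticholinergic=a)
                for e, a in [(True, True), (True, False), (False, True)]
            ]
        )
        once = filter_copd_medication(events)
        twice = filter_copd_medication(once)
        pd.testing.assert_frame_equal(once, twice)


class TestSummariseUtilisation:
    def test_empty(self):
        util = summarise_utilisation(events_frame([]))
        assert util.empty

    def test_quantity_sum(self):
        events = events_frame([make_event(quantity=q) for q in (2, 3, 5)])
        util = summarise_utilisation(events)
        assert util.loc[2006, "shc_hospital_days"] == 10

    def test_years_do_not_leak(self):
        events = events_frame(
            [
                make_event(year=1996, quantity=7),
                make_event(year=2006, quantity=11),
                make_event(year=1996, category="shc_outpatient_visit", quantity=1),
            ]
        )
        util = summarise_utilisation(events)
        assert util.loc[1996, "shc_hospital_days"] == 7
        assert util.loc[2006, "shc_hospital_days"] == 11
        assert util.loc[1996, "shc_outpatient_visits"] == 1
        assert util.loc[2006, "shc_outpatient_visits"] == 0

    def test_medication_cost_is_euro_sum(self):
        events = events_frame(
            [
                make_event(category="drug_purchase", quantity=12.5),
                make_event(category="drug_purchase", quantity=7.5),
            ]
        )
        util = summarise_utilisation(events)
        assert util.loc[2006, "medication_cost"] == 20.0


def utilisation_row(year=2006, **kw) -> pd.DataFrame:
    row = {c: 0.0 for c in accounting.UTILISATION_COLUMNS}
    row.update(kw)
    df = pd.DataFrame([row], index=pd.Index([year], name="year"))
    return df


class TestDirectCosts:
    def test_outpatient_worked_example(self, unit_costs, flat_index):
        util = utilisation_row(shc_outpatient_visits=20_115)
        direct = compute_direct_costs(util, unit_costs, flat_index)
        assert direct.loc[2006, "outpatient_shc"] == pytest.approx(4_023_000)

    def test_zero_utilisation(self, unit_costs, flat_index):
        direct = compute_direct_costs(utilisation_row(), unit_costs, flat_index)
        assert direct.loc[2006, "total_direct"] == 0.0

    def test_total_is_component_sum(self, unit_costs, flat_index):
        util = utilisation_row(
            phc_hospital_days=10, shc_hospital_days=20, shc_outpatient_visits=30, medication_cost=999.5
        )
        direct = compute_direct_costs(util, unit_costs, flat_index)
        row = direct.loc[2006]
        assert row["total_direct"] == pytest.approx(
            row["outpatient_shc"] + row["hospital_shc"] + row["hospital_phc"] + row["medication"]
        )

    def test_missing_index_year_raises(self, unit_costs, flat_index):
        util = utilisation_row(year=1980, shc_outpatient_visits=1)
        with pytest.raises(PriceIndexError):
            compute_direct_costs(util, unit_costs, flat_index)

    def test_brute_force_oracle(self, unit_costs, flat_index):
        # per-event loop pricing must equal the vectorised computation exactly
        rng = np.random.default_rng(11)
        categories = ["phc_hospital_day", "shc_hospital_day", "shc_outpatient_visit", "drug_purchase"]
        rows = []
        for i in range(50):
            cat = categories[rng.integers(4)]
            q = float(rng.integers(1, 6)) if cat != "drug_purchase" else float(rng.uniform(5, 80))
            rows.append(make_event(person_id=f"P{i}", category=cat, quantity=q, year=2000 + int(rng.integers(3))))
        events = events_frame(rows)
        index = PriceIndexSeries({2000: 90.0, 2001: 95.0, 2002: 98.0, 2006: 100.0}, 2006)
        unit_by_cat = {
            "phc_hospital_day": unit_costs.phc_hospital_day,
            "shc_hospital_day": unit_costs.shc_hospital_day,
            "shc_outpatient_visit": unit_costs.shc_outpatient_visit,
        }
        expected: dict[int, float] = {}
        for row in rows:
            if row["category"] == "drug_purchase":
                cost = row["quantity"]
            else:
                cost = row["quantity"] * unit_by_cat[row["category"]] * index.values[row["year"]] / 100.0
            expected[row["year"]] = expected.get(row["year"], 0.0) + cost
        direct = compute_direct_costs(summarise_utilisation(events), unit_costs, index)
        for year, total in expected.items():
            assert direct.loc[year, "total_direct"] == pytest.approx(total, rel=1e-12)

    def test_scale_equivariance(self, unit_costs, flat_index):
        util = utilisation_row(
            phc_hospital_days=10, shc_hospital_days=20, shc_outpatient_visits=30, medication_cost=500.0
        )
        doubled = util * 2.0
        d1 = compute_direct_costs(util, unit_costs, flat_index)
        d2 = compute_direct_costs(doubled, unit_costs, flat_index)
        pd.testing.assert_frame_equal(d2, d1 * 2.0)


class TestIndirectCosts:
    def test_zero_inputs(self, unit_costs):
        indirect = compute_indirect_costs(utilisation_row(), unit_costs)
        assert indirect.loc[2006, "total_indirect"] == 0.0

    def test_one_man_year(self, unit_costs):
        util = utilisation_row(sickness_allowance_days=260)
        indirect = compute_indirect_costs(util, unit_costs, days_per_man_year=260)
        assert indirect.loc[2006, "sickness_allowance"] == pytest.approx(24_600)

    def test_pension_person_years(self, unit_costs):
        util = utilisation_row(disability_pension_subjects=1_844)
        indirect = compute_indirect_costs(util, unit_costs)
        assert indirect.loc[2006, "disability_pension"] == pytest.approx(45_362_400)

    def test_fractional_person_years_supported(self, unit_costs):
        util = utilisation_row(disability_pension_subjects=1_843.4539)
        indirect = compute_indirect_costs(util, unit_costs)
        assert indirect.loc[2006, "disability_pension"] == pytest.approx(1_843.4539 * 24_600)

    def test_non_positive_divisor_rejected(self, unit_costs):
        with pytest.raises(ValueError, match="days_per_man_year"):
            compute_indirect_costs(utilisation_row(), unit_costs, days_per_man_year=0)

    def test_index_adjusts_man_year_cost(self, unit_costs):
        util = utilisation_row(year=2000, disability_pension_subjects=10)
        index = PriceIndexSeries({2000: 80.0, 2006: 100.0}, 2006)
        indirect = compute_indirect_costs(util, unit_costs, index=index)
        assert indirect.loc[2000, "disability_pension"] == pytest.approx(10 * 24_600 * 0.8)


class TestAssembleBreakdown:
    def test_component_sums_from_reference_rows(self, unit_costs, flat_index):
        direct = pd.DataFrame(
            {
                "outpatient_shc": [4_023_000.0],
                "hospital_shc": [19_154_939.0],
                "hospital_phc": [9_835_330.0],
                "medication": [23_268_935.0],
                "total_direct": [56_282_204.0],
            },
            index=pd.Index([2006], name="year"),
        )
        indirect = pd.DataFrame(
            {
                "sickness_allowance": [6_074_400.0],
                "disability_pension": [45_348_966.0],
                "total_indirect": [51_423_366.0],
            },
            index=pd.Index([2006], name="year"),
        )
        breakdown = assemble_breakdown(direct, indirect)
        assert breakdown.loc[2006, "total_direct"] == 56_282_204
        assert breakdown.loc[2006, "total_indirect"] == 51_423_366
        assert breakdown.loc[2006, "total"] == 107_705_570
        validate_breakdown(breakdown)

    def test_all_zero(self, unit_costs, flat_index):
        direct = compute_direct_costs(utilisation_row(), unit_costs, flat_index)
        indirect = compute_indirect_costs(utilisation_row(), unit_costs)
        breakdown = assemble_breakdown(direct, indirect)
        assert (breakdown.loc[2006] == 0).all()

    def test_year_mismatch_rejected(self, unit_costs, flat_index):
        direct = compute_direct_costs(utilisation_row(year=1996), unit_costs, flat_index)
        indirect = compute_indirect_costs(utilisation_row(year=2006), unit_costs)
        with pytest.raises(ValueError, match="year mismatch"):
            assemble_breakdown(direct, indirect)

    def test_rounding_happens_once_at_assembly(self, unit_costs, flat_index):
        direct = compute_direct_costs(utilisation_row(medication_cost=10.4), unit_costs, flat_index)
        indirect = compute_indirect_costs(utilisation_row(sickness_allowance_days=1), unit_costs)
        breakdown = assemble_breakdown(direct, indirect)
        assert breakdown.loc[2006, "medication"] == 10
        assert breakdown.loc[2006, "sickness_allowance"] == round_half_up(24_600 / 260)
        assert breakdown.dtypes.unique().tolist() == [np.dtype("int64")]


class TestPerCapita:
    def test_reference_values(self):
        assert per_capita(110_119_638, 5_132_320) == 2_145_611
        assert per_capita(32_446, 5_276_955) == 615

    def test_zero_value(self):
        assert per_capita(0, 123_456) == 0

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError, match="population"):
            per_capita(1, 0)

    @given(
        st.floats(min_value=0, max_value=1e12, allow_nan=False),
        st.floats(min_value=1, max_value=1e8, allow_nan=False),
    )
    def test_scale_invariance(self, value, population):
        # equal up to float rounding: one integer step or a relative ulp at huge magnitudes
        a, b = per_capita(value * 10, population * 10), per_capita(value, population)
        assert abs(a - b) <= max(1, 1e-12 * max(abs(a), abs(b)))


class TestPercentChange:
    def test_reported_changes(self):
        assert percent_change(58_986, 69_021, rounded=True) == 17
        assert percent_change(68_231, 32_446, rounded=True) == -52

    def test_no_change(self):
        assert percent_change(123, 123) == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            percent_change(0, 10)

    @given(st.floats(min_value=1e-3, max_value=1e9), st.floats(min_value=0, max_value=1e9))
    def test_sign_matches_direction(self, before, after):
        change = percent_change(before, after)
        assert (change > 0) == (after > before) or change == 0


class TestStratumCosts:
    def test_two_strata_split(self, unit_costs, flat_index):
        care = events_frame(
            [
                make_event(age_group="60-64", sex="male", category="shc_hospital_day", quantity=2),
                make_event(age_group="70-74", sex="female", category="shc_outpatient_visit", quantity=1),
                make_event(age_group="60-64", sex="male", category="sickness_allowance_day", quantity=26),
            ]
        )
        meds = events_frame(
            [
                make_event(
                    age_group="70-74",
                    sex="female",
                    category="drug_purchase",
                    quantity=100.0,
                    reimbursement_entitled=True,
                    uses_anticholinergic=True,
                )
            ]
        )
        table = compute_stratum_costs(care, meds, unit_costs, flat_index, 2006, days_per_man_year=260)
        get = lambda ag, sx, ch: float(
            table[(table.age_group == ag) & (table.sex == sx) & (table.channel == ch)]["eur"].iloc[0]
        )
        assert get("60-64", "male", "direct") == pytest.approx(2 * 590)
        assert get("60-64", "male", "indirect") == pytest.approx(26 / 260 * 24_600)
        assert get("70-74", "female", "direct") == pytest.approx(200 + 100)
        assert get("70-74", "female", "indirect") == 0.0
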