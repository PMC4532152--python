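import pandas as pd
import pytest

from copdcost.accounting import PriceIndexSeries, UnitCostTable
from copdcost.synth import EVENT_COLUMNS, SimulationConfig


def make_event(**overrides) -> dict:
    """One register-event row with sensible defaults, overridable per test."""
    row = {
        "person_id": "P1",
        "year": 2006,
        "category": "shc_hospital_day",
        "primary_icd10": "J44",
        "quantity": 1.0,
        "reimbursement_entitled": False,
        "uses_anticholinergic": False,
        "age_group": "60-64",
        "sex": "male",
    }
    row.update(overrides)
    return row


def events_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=list(EVENT_COLUMNS))


@pytest.fixture
def unit_costs() -> UnitCostTable:
    return UnitCostTable(
        phc_hospital_day=142,
        shc_hospital_day=590,
        shc_outpatient_visit=200,
        lost_man_year=24_600,
        reference_year=2006,
    )


@pytest.fixture
def flat_index() -> PriceIndexSeries:
    """Index pinned at 100 for 1996-2006: unit costs apply unadjusted everywhere."""
    return PriceIndexSeries({y: 100.0 for y in range(1996, 2007)}, reference_year=2006)


@pytest.fixture
def tiny_config() -> SimulationConfig:
    return SimulationConfig(
        years=(2005, 2006),
        strata=[
            {
                "age_group": "60-64",
                "sex": "male",
                "population": 2000,
                "fractions": {"active": 0.2, "quit_1_3": 0.05, "quit_3_5": 0.04, "quit_5_10": 0.06},
            },
            {
                "age_group": "70-74",
                "sex": "female",
                "population": 1500,
                "fractions": {"active": 0.1, "quit_1_3": 0.02, "quit_3_5": 0.02, "quit_5_10": 0.03},
            },
        ],
        event_rates={
            "phc_hospital_day": 0.3,
            "shc_hospital_day": 0.2,
            "shc_outpatient_visit": 0.15,
            "drug_purchase": 0.8,
            "sickness_allowance_day": 0.4,
            "disability_pension": 0.02,
        },
        seed=42,
    )
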