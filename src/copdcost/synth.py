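"""Seeded synthetic register extracts and aggregate series.

Generates person-level register events (hospital days, outpatient visits,
drug purchases, sickness-allowance days, disability pensions) with smoking-
and age-dependent event rates, plus the aggregate inputs the accounting and
projection stages consume: a price-index series, a smoking-prevalence series
and population counts. Everything is driven by a single validated config and
a seed; identical config implies byte-identical output tables.

Event counts per stratum-year are Poisson with mean
``rate * weighted smoker equivalents`` — an explicit modelling choice that
gives replication-based tests known error bars.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .smoking import DEFAULT_WEIGHTS, SMOKING_CATEGORIES, SmokingWeights, cap_fractions, weighted_prevalence
from .strata import SEXES, parse_age_lower

EVENT_CATEGORIES: tuple[str, ...] = (
    "phc_hospital_day",
    "shc_hospital_day",
    "shc_outpatient_visit",
    "drug_purchase",
    "sickness_allowance_day",
    "disability_pension",
)

#: columns of a register-event table, in file order
EVENT_COLUMNS: tuple[str, ...] = (
    "person_id",
    "year",
    "category",
    "primary_icd10",
    "quantity",
    "reimbursement_entitled",
    "uses_anticholinergic",
    "age_group",
    "sex",
)

DEFAULT_DISTRACTOR_CODES: tuple[str, ...] = ("J18", "J45", "I50")
_COPD_CODES: tuple[str, ...] = ("J44", "J43", "J44.0", "J44.8", "J43.9")


class StratumConfig(BaseModel):
    """Per-stratum inputs; scalars apply to every simulated year, dicts are per-year."""

    age_group: str
    sex: str
    population: float | dict[int, float]
    fractions: dict[str, float | dict[int, float]]

    @field_validator("age_group")
    @classmethod
    def _check_band(cls, v: str) -> str:
        parse_age_lower(v)
        return v

    @field_validator("sex")
    @classmethod
    def _check_sex(cls, v: str) -> str:
        if v not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        return v

    @field_validator("population")
    @classmethod
    def _check_pop(cls, v):
        vals = v.values() if isinstance(v, dict) else [v]
        if any(x < 0 for x in vals):
            raise ValueError("population must be >= 0")
        return v

    @field_validator("fractions")
    @classmethod
    def _check_fractions(cls, v):
        for cat in v:
            if cat not in SMOKING_CATEGORIES:
                raise ValueError(f"unknown smoking category {cat!r}; expected {SMOKING_CATEGORIES}")
        for cat, val in v.items():
            vals = val.values() if isinstance(val, dict) else [val]
            for x in vals:
                if not 0.0 <= x <= 1.0:
                    raise ValueError(f"fractions[{cat}] must be in [0, 1]")
        return v

    def population_in(self, year: int) -> float:
        if isinstance(self.population, dict):
            return float(self.population[year])
        return float(self.population)

    def fractions_in(self, year: int) -> dict[str, float]:
        out: dict[str, float] = {}
        for cat in SMOKING_CATEGORIES:
            val = self.fractions.get(cat, 0.0)
            out[cat] = float(val[year]) if isinstance(val, dict) else float(val)
        if sum(out.values()) > 1.0 + 1e-12:
            raise ValueError(f"smoking fractions sum to more than 1 in year {year} for {self.age_group}/{self.sex}")
        return out


class SimulationConfig(BaseModel):
    """Full description of a synthetic register run (validated, YAML/JSON-loadable)."""

    years: tuple[int, int]
    strata: list[StratumConfig] = Field(min_length=1)
    event_rates: dict[str, float]
    copd_diagnosis_share: float = 0.85
    distractor_codes: Sequence[str] = DEFAULT_DISTRACTOR_CODES
    entitlement_prob: float = 0.8
    anticholinergic_prob: float = 0.85
    drug_cost_mean: float = 60.0
    seed: int = 0

    @field_validator("years")
    @classmethod
    def _check_years(cls, v: tuple[int, int]) -> tuple[int, int]:
        if v[1] < v[0]:
            raise ValueError("years must be an ordered (start, end) pair")
        return v

    @field_validator("event_rates")
    @classmethod
    def _check_rates(cls, v: dict[str, float]) -> dict[str, float]:
        for cat, rate in v.items():
            if cat not in EVENT_CATEGORIES:
                raise ValueError(f"unknown event category {cat!r}; expected one of {EVENT_CATEGORIES}")
            if rate < 0:
                raise ValueError(f"event_rates[{cat}] must be >= 0, got {rate}")
        return v

    @field_validator("copd_diagnosis_share", "entitlement_prob", "anticholinergic_prob")
    @classmethod
    def _check_prob(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("probability must be in [0, 1]")
        return v

    @field_validator("drug_cost_mean")
    @classmethod
    def _check_cost(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("drug_cost_mean must be > 0")
        return v

    @model_validator(mode="after")
    def _check_fraction_sums(self) -> "SimulationConfig":
        for s in self.strata:
            for year in range(self.years[0], self.years[1] + 1):
                s.fractions_in(year)  # raises if the four-category sum exceeds 1
        return self

    def year_range(self) -> range:
        return range(self.years[0], self.years[1] + 1)


def weighted_equivalents_of(stratum: StratumConfig, year: int, weights: SmokingWeights = DEFAULT_WEIGHTS) -> float:
    """Population times weighted smoking prevalence for one stratum-year."""
    return stratum.population_in(year) * weighted_prevalence(stratum.fractions_in(year), weights)


def _draw_code(rng: np.random.Generator, share: float, distractors: Sequence[str]) -> str:
    if rng.random() < share:
        return _COPD_CODES[rng.integers(len(_COPD_CODES))]
    if not distractors:
        return "R69"
    return distractors[rng.integers(len(distractors))]


def generate_registers(config: SimulationConfig, weights: SmokingWeights = DEFAULT_WEIGHTS) -> pd.DataFrame:
    """Generate the person-level event table for every stratum-year of ``config``.

    Counts per (stratum, year, category) are Poisson(rate x equivalents);
    diagnosis codes carry a COPD rubric (J43/J44 family) with probability
    ``copd_diagnosis_share`` and a distractor code otherwise. Disability
    pensions are unique per person-year by construction.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[tuple] = []
    person_seq = 0
    distractors = tuple(config.distractor_codes)
    for year in config.year_range():
        for stratum in config.strata:
            equivalents = weighted_equivalents_of(stratum, year, weights)
            for category in EVENT_CATEGORIES:
                rate = config.event_rates.get(category, 0.0)
                mean = rate * equivalents
                n = int(rng.poisson(mean)) if mean > 0 else 0
                for _ in range(n):
                    person_seq += 1
                    person_id = f"P{person_seq:08d}"
                    if category == "drug_purchase":
                        code = ""
                        quantity = float(np.round(rng.gamma(2.0, config.drug_cost_mean / 2.0), 2))
                        entitled = bool(rng.random() < config.entitlement_prob)
                        anticho = bool(rng.random() < config.anticholinergic_prob)
                    else:
                        code = _draw_code(rng, config.copd_diagnosis_share, distractors)
                        quantity = 1.0
                        entitled = False
                        anticho = False
                    rows.append(
                        (person_id, year, category, code, quantity, entitled, anticho, stratum.age_group, stratum.sex)
                    )
    df = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    if df.empty:
        df = df.astype(
            {
                "year": "int64",
                "quantity": "float64",
                "reimbursement_entitled": "bool",
                "uses_anticholinergic": "bool",
            },
            errors="ignore",
        )
    return df


def generate_price_index(years: range | Sequence[int], annual_rate: float, base_year: int | None = None) -> pd.Series:
    """Geometric price-index series with the base year at 100."""
    years = list(years)
    if not years:
        raise ValueError("empty year range")
    if annual_rate <= -1:
        raise ValueError("annual_rate must be > -1")
    if base_year is None:
        base_year = min(years)
    values = [100.0 * (1.0 + annual_rate) ** (y - base_year) for y in years]
    return pd.Series(values, index=pd.Index(years, name="year"), name="index")


def generate_smoking_series(
    config: SimulationConfig,
    slope_pp_per_year: Mapping[str, float] | Mapping[tuple[str, str], Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Smoking-prevalence series with linear drift in percentage points per year.

    ``slope_pp_per_year`` is either one slope per category (applied to every
    stratum) or a nested mapping ``(age_group, sex) -> category -> slope``.
    Fractions are anchored at each stratum's first-year values, drift
    linearly, and are clamped/capped so the four-category sum stays in [0, 1].
    """
    start = config.years[0]
    records: list[dict] = []
    for stratum in config.strata:
        base = stratum.fractions_in(start)
        if slope_pp_per_year is None:
            slopes = {cat: 0.0 for cat in SMOKING_CATEGORIES}
        elif all(isinstance(k, str) for k in slope_pp_per_year):
            slopes = {cat: float(slope_pp_per_year.get(cat, 0.0)) for cat in SMOKING_CATEGORIES}  # type: ignore[union-attr]
        else:
            per = slope_pp_per_year.get((stratum.age_group, stratum.sex), {})  # type: ignore[call-overload]
            slopes = {cat: float(per.get(cat, 0.0)) for cat in SMOKING_CATEGORIES}
        for year in config.year_range():
            raw = {cat: base[cat] + slopes[cat] / 100.0 * (year - start) for cat in SMOKING_CATEGORIES}
            capped = cap_fractions(raw)
            for cat in SMOKING_CATEGORIES:
                records.append(
                    {
                        "year": year,
                        "age_group": stratum.age_group,
                        "sex": stratum.sex,
                        "category": cat,
                        "fraction": capped[cat],
                    }
                )
    return pd.DataFrame.from_records(records, columns=["year", "age_group", "sex", "category", "fraction"])


def generate_population_table(config: SimulationConfig) -> pd.DataFrame:
    """Long-format population counts (year, age_group, sex, count) for the run."""
    records = [
        {"year": year, "age_group": s.age_group, "sex": s.sex, "count": s.population_in(year)}
        for year in config.year_range()
        for s in config.strata
    ]
    return pd.DataFrame.from_records(records, columns=["year", "age_group", "sex", "count"])
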