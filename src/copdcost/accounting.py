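"""Top-down cost accounting over filtered register events.

Care events are attributed to COPD by primary ICD-10 rubric (prefix J43 or
J44); drug purchases by the special-reimbursement entitlement combined with
inhaled-anticholinergic use. Filtered utilisation is priced with
reference-year unit costs restated through a public-expenditure price index,
and allowance days / pension person-years are valued per lost man-year.

All intermediate arithmetic is exact floating point; Euro amounts are
rounded half-up to integers only when a breakdown is assembled or a
per-100,000 figure is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

logger = logging.getLogger(__name__)

COPD_PREFIXES: tuple[str, ...] = ("J43", "J44")
#: rubric accepted in allowance/pension cause fields only under protest (logged)
SUSPECT_PREFIX = "J33"

CARE_CATEGORIES: tuple[str, ...] = ("phc_hospital_day", "shc_hospital_day", "shc_outpatient_visit")
BENEFIT_CATEGORIES: tuple[str, ...] = ("sickness_allowance_day", "disability_pension")

DIRECT_COMPONENTS: tuple[str, ...] = ("outpatient_shc", "hospital_shc", "hospital_phc", "medication")
INDIRECT_COMPONENTS: tuple[str, ...] = ("sickness_allowance", "disability_pension")
BREAKDOWN_COLUMNS: tuple[str, ...] = (
    *DIRECT_COMPONENTS,
    "total_direct",
    *INDIRECT_COMPONENTS,
    "total_indirect",
    "total",
)

UTILISATION_COLUMNS: tuple[str, ...] = (
    "phc_hospital_days",
    "shc_hospital_days",
    "shc_outpatient_visits",
    "sickness_allowance_days",
    "disability_pension_subjects",
    "medication_cost",
)

_CATEGORY_TO_UTIL = {
    "phc_hospital_day": "phc_hospital_days",
    "shc_hospital_day": "shc_hospital_days",
    "shc_outpatient_visit": "shc_outpatient_visits",
    "sickness_allowance_day": "sickness_allowance_days",
    "disability_pension": "disability_pension_subjects",
}


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero (accounting rule)."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True, slots=True)
class UnitCostTable:
    """Reference-year unit costs in Euros."""

    phc_hospital_day: float
    shc_hospital_day: float
    shc_outpatient_visit: float
    lost_man_year: float
    reference_year: int

    def __post_init__(self) -> None:
        for field in ("phc_hospital_day", "shc_hospital_day", "shc_outpatient_visit", "lost_man_year"):
            if getattr(self, field) <= 0:
                raise ValueError(f"unit cost {field} must be > 0")


class PriceIndexError(LookupError):
    """A year is missing from the price-index series (no silent extrapolation)."""


@dataclass(frozen=True)
class PriceIndexSeries:
    """Deflator series; the reference year indexes at its stated value (typically 100)."""

    values: dict[int, float]
    reference_year: int

    def __post_init__(self) -> None:
        if self.reference_year not in self.values:
            raise ValueError(f"reference year {self.reference_year} missing from index series")
        for year, v in self.values.items():
            if v <= 0:
                raise ValueError(f"price index for {year} must be > 0, got {v}")

    @classmethod
    def from_series(cls, s: pd.Series, reference_year: int) -> "PriceIndexSeries":
        return cls({int(y): float(v) for y, v in s.items()}, reference_year)

    def at(self, year: int) -> float:
        try:
            return self.values[int(year)]
        except KeyError:
            raise PriceIndexError(f"price index has no value for year {year}") from None

    def ratio(self, target_year: int) -> float:
        return self.at(target_year) / self.at(self.reference_year)


def adjust_unit_cost(cost: float, target_year: int, index: PriceIndexSeries) -> float:
    """Restate a reference-year unit cost in the target year's nominal Euros."""
    return cost * index.ratio(target_year)


def _starts_with_copd(codes: pd.Series) -> pd.Series:
    return codes.fillna("").astype(str).str.startswith(COPD_PREFIXES)


def filter_copd_events(events: pd.DataFrame) -> pd.DataFrame:
    """Retain care/benefit events whose primary ICD-10 code starts with J43 or J44.

    Drug purchases are never selected here (they have no diagnosis code in
    the source register); use :func:`filter_copd_medication` for those.
    Occurrences of the J33 rubric in benefit cause fields are logged, as they
    almost certainly denote miscoded COPD, but they are not retained.
    """
    if events.empty:
        return events.iloc[0:0].copy()
    eligible = events["category"].isin(CARE_CATEGORIES + BENEFIT_CATEGORIES)
    n_suspect = int(
        (
            eligible
            & events["category"].isin(BENEFIT_CATEGORIES)
            & events["primary_icd10"].fillna("").astype(str).str.startswith(SUSPECT_PREFIX)
        ).sum()
    )
    if n_suspect:
        logger.warning(
            "%d benefit events carry rubric %s (likely miscoded emphysema); not retained", n_suspect, SUSPECT_PREFIX
        )
    kept = events[eligible & _starts_with_copd(events["primary_icd10"])].copy()
    logger.info("diagnosis filter: %d of %d events retained", len(kept), len(events))
    return kept


def filter_copd_medication(events: pd.DataFrame) -> pd.DataFrame:
    """Retain drug purchases by persons both reimbursement-entitled and using anticholinergics.

    Both flags are person-level attributes carried on every purchase row, so
    a qualifying person's non-anticholinergic respiratory drugs qualify too.
    """
    if events.empty:
        return events.iloc[0:0].copy()
    mask = (
        (events["category"] == "drug_purchase")
        & events["reimbursement_entitled"].astype(bool)
        & events["uses_anticholinergic"].astype(bool)
    )
    kept = events[mask].copy()
    logger.info("medication filter: %d of %d events retained", len(kept), len(events))
    return kept


def summarise_utilisation(filtered: pd.DataFrame) -> pd.DataFrame:
    """Per-year utilisation sums from already-filtered events.

    Returns a frame indexed by year with count columns per care/benefit
    channel and the Euro sum of retained drug purchases.
    """
    if filtered.empty:
        return pd.DataFrame(columns=list(UTILISATION_COLUMNS), index=pd.Index([], name="year", dtype=int))
    out = pd.DataFrame(
        0.0,
        index=pd.Index(sorted(filtered["year"].unique()), name="year"),
        columns=list(UTILISATION_COLUMNS),
    )
    for category, column in _CATEGORY_TO_UTIL.items():
        sums = filtered.loc[filtered["category"] == category].groupby("year")["quantity"].sum()
        out.loc[sums.index, column] = sums
    med = filtered.loc[filtered["category"] == "drug_purchase"].groupby("year")["quantity"].sum()
    out.loc[med.index, "medication_cost"] = med
    return out


def compute_direct_costs(utilisation: pd.DataFrame, costs: UnitCostTable, index: PriceIndexSeries) -> pd.DataFrame:
    """Price utilisation into the four direct components plus their total (exact €, unrounded).

    Medication costs pass through as register Euro totals; they are already
    nominal for their year and get no separate inflation adjustment.
    """
    rows = {}
    for year in utilisation.index:
        u = utilisation.loc[year]
        outpatient = u["shc_outpatient_visits"] * adjust_unit_cost(costs.shc_outpatient_visit, year, index)
        hosp_shc = u["shc_hospital_days"] * adjust_unit_cost(costs.shc_hospital_day, year, index)
        hosp_phc = u["phc_hospital_days"] * adjust_unit_cost(costs.phc_hospital_day, year, index)
        medication = float(u["medication_cost"])
        rows[year] = {
            "outpatient_shc": outpatient,
            "hospital_shc": hosp_shc,
            "hospital_phc": hosp_phc,
            "medication": medication,
            "total_direct": outpatient + hosp_shc + hosp_phc + medication,
        }
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["outpatient_shc", "hospital_shc", "hospital_phc", "medication", "total_direct"])
    out.index.name = "year"
    return out


def compute_indirect_costs(
    utilisation: pd.DataFrame,
    costs: UnitCostTable,
    days_per_man_year: float = 260.0,
    index: PriceIndexSeries | None = None,
) -> pd.DataFrame:
    """Value productivity losses: allowance days as fractional man-years, pensions as person-years.

    When a price index is supplied, the man-year cost is restated per year;
    otherwise the reference-year cost applies throughout.
    """
    if days_per_man_year <= 0:
        raise ValueError(f"days_per_man_year must be > 0, got {days_per_man_year}")
    rows = {}
    for year in utilisation.index:
        u = utilisation.loc[year]
        man_year_cost = costs.lost_man_year if index is None else adjust_unit_cost(costs.lost_man_year, year, index)
        sickness = (u["sickness_allowance_days"] / days_per_man_year) * man_year_cost
        pension = u["disability_pension_subjects"] * man_year_cost
        rows[year] = {
            "sickness_allowance": sickness,
            "disability_pension": pension,
            "total_indirect": sickness + pension,
        }
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["sickness_allowance", "disability_pension", "total_indirect"])
    out.index.name = "year"
    return out


def assemble_breakdown(direct: pd.DataFrame, indirect: pd.DataFrame) -> pd.DataFrame:
    """Combine direct and indirect components into an integer-Euro breakdown.

    Components are rounded half-up here, once; totals are sums of the rounded
    components so the additivity invariants hold exactly by construction.
    """
    if list(direct.index) != list(indirect.index):
        raise ValueError(f"year mismatch: direct covers {list(direct.index)}, indirect covers {list(indirect.index)}")
    rows = {}
    for year in direct.index:
        d = {c: round_half_up(direct.loc[year, c]) for c in DIRECT_COMPONENTS}
        i = {c: round_half_up(indirect.loc[year, c]) for c in INDIRECT_COMPONENTS}
        total_direct = sum(d.values())
        total_indirect = sum(i.values())
        rows[year] = {
            **d,
            "total_direct": total_direct,
            **i,
            "total_indirect": total_indirect,
            "total": total_direct + total_indirect,
        }
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(BREAKDOWN_COLUMNS)).astype("int64")
    out.index.name = "year"
    return out


def validate_breakdown(breakdown: pd.DataFrame) -> None:
    """Assert the additivity invariants of an integer-Euro breakdown table."""
    td = breakdown[list(DIRECT_COMPONENTS)].sum(axis=1)
    ti = breakdown[list(INDIRECT_COMPONENTS)].sum(axis=1)
    if not (td == breakdown["total_direct"]).all():
        raise ValueError("total_direct does not equal the sum of its components")
    if not (ti == breakdown["total_indirect"]).all():
        raise ValueError("total_indirect does not equal the sum of its components")
    if not ((breakdown["total_direct"] + breakdown["total_indirect"]) == breakdown["total"]).all():
        raise ValueError("total does not equal total_direct + total_indirect")


def per_capita(value: float, population: float, per: float = 100_000.0) -> int:
    """Value per 100,000 inhabitants, rounded half-up to an integer."""
    if population <= 0:
        raise ValueError(f"population must be > 0, got {population}")
    return round_half_up(value * per / population)


def percent_change(before: float, after: float, rounded: bool = False) -> float | int:
    """Signed percentage change from ``before`` to ``after``."""
    if before <= 0:
        raise ValueError(f"baseline must be > 0, got {before}")
    change = 100.0 * (after - before) / before
    return round_half_up(change) if rounded else change


def compute_stratum_costs(
    care_events: pd.DataFrame,
    med_events: pd.DataFrame,
    costs: UnitCostTable,
    index: PriceIndexSeries,
    year: int,
    days_per_man_year: float = 260.0,
) -> pd.DataFrame:
    """Per-stratum direct/indirect Euro totals for one year (long format).

    Feeds the projection stage, which standardises base-year costs per
    stratum. Returns columns (age_group, sex, channel, eur).
    """
    records: list[dict] = []
    care = care_events[care_events["year"] == year]
    med = med_events[med_events["year"] == year]
    strata = sorted(
        set(map(tuple, care[["age_group", "sex"]].itertuples(index=False, name=None)))
        | set(map(tuple, med[["age_group", "sex"]].itertuples(index=False, name=None)))
    )
    for age_group, sex in strata:
        c = care[(care["age_group"] == age_group) & (care["sex"] == sex)]
        m = med[(med["age_group"] == age_group) & (med["sex"] == sex)]
        util = summarise_utilisation(pd.concat([c, m], ignore_index=True))
        if util.empty:
            direct_total = indirect_total = 0.0
        else:
            direct_total = float(compute_direct_costs(util, costs, index)["total_direct"].sum())
            indirect_total = float(
                compute_indirect_costs(util, costs, days_per_man_year, index)["total_indirect"].sum()
            )
        records.append({"age_group": age_group, "sex": sex, "channel": "direct", "eur": direct_total})
        records.append({"age_group": age_group, "sex": sex, "channel": "indirect", "eur": indirect_total})
    return pd.DataFrame.from_records(records, columns=["age_group", "sex", "channel", "eur"])
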