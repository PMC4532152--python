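"""Smoking-standardised projection of future annual costs.

Base-year stratum costs are divided by weighted smoker-equivalent counts to
give a cost per equivalent; smoking-category fractions are extrapolated
linearly from their historical trend; projected equivalents (extrapolated
fractions x projected population) times the standardised costs give real
future costs, to which a flat annual inflation factor is applied.

Indirect (productivity-loss) costs are only accrued by strata below the
retirement age: higher morbidity among the already-retired does not remove
anyone from the workforce.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .accounting import percent_change
from .smoking import DEFAULT_WEIGHTS, SMOKING_CATEGORIES, SmokingWeights, cap_fractions, weighted_prevalence
from .strata import parse_age_lower

__all__ = [
    "SmokingWeights",
    "DEFAULT_WEIGHTS",
    "StandardisedCost",
    "ProjectionResult",
    "weighted_equivalents",
    "standardise_costs",
    "smoking_trend_slopes",
    "extrapolate_fractions",
    "project_costs",
    "summarise_projection",
]

CHANNELS: tuple[str, str] = ("direct", "indirect")


def weighted_equivalents(
    fractions: Mapping[str, float], population: float, weights: SmokingWeights = DEFAULT_WEIGHTS
) -> float:
    """Weighted smoker-equivalent count for one stratum-year."""
    if population < 0:
        raise ValueError("population must be >= 0")
    return population * weighted_prevalence(fractions, weights)


@dataclass(frozen=True)
class StandardisedCost:
    """Base-year Euros per weighted smoker-equivalent, per stratum and channel.

    ``table`` has columns (age_group, sex, channel, eur_per_equivalent).
    """

    table: pd.DataFrame
    base_year: int

    def lookup(self, age_group: str, sex: str, channel: str) -> float:
        t = self.table
        rows = t[(t["age_group"] == age_group) & (t["sex"] == sex) & (t["channel"] == channel)]
        if rows.empty:
            return 0.0
        return float(rows["eur_per_equivalent"].iloc[0])

    def strata(self) -> list[tuple[str, str]]:
        return sorted(set(map(tuple, self.table[["age_group", "sex"]].itertuples(index=False, name=None))))


def standardise_costs(base_costs: pd.DataFrame, equivalents: pd.DataFrame, base_year: int) -> StandardisedCost:
    """Divide base-year stratum costs by weighted equivalents.

    ``base_costs``: columns (age_group, sex, channel, eur);
    ``equivalents``: columns (age_group, sex, equivalents).
    A positive cost in a stratum with zero equivalents is an error naming the
    stratum; a zero cost standardises to zero regardless of equivalents.
    """
    eq = {(r.age_group, r.sex): float(r.equivalents) for r in equivalents.itertuples(index=False)}
    records: list[dict] = []
    for row in base_costs.itertuples(index=False):
        cost = float(row.eur)
        if cost < 0:
            raise ValueError(f"negative cost for stratum {row.age_group}/{row.sex}")
        n = eq.get((row.age_group, row.sex), 0.0)
        if cost == 0.0:
            per = 0.0
        elif n <= 0:
            raise ValueError(
                f"stratum {row.age_group}/{row.sex} has positive {row.channel} cost but zero smoker equivalents"
            )
        else:
            per = cost / n
        records.append(
            {"age_group": row.age_group, "sex": row.sex, "channel": row.channel, "eur_per_equivalent": per}
        )
    return StandardisedCost(
        pd.DataFrame.from_records(records, columns=["age_group", "sex", "channel", "eur_per_equivalent"]),
        base_year,
    )


def smoking_trend_slopes(history: pd.DataFrame) -> pd.DataFrame:
    """OLS slope (fraction per year) of each stratum-category prevalence series.

    ``history`` columns: (year, age_group, sex, category, fraction). Each
    group needs at least two distinct years.
    """
    records: list[dict] = []
    for (age_group, sex, category), grp in history.groupby(["age_group", "sex", "category"], sort=True):
        years = grp["year"].to_numpy(dtype=float)
        fracs = grp["fraction"].to_numpy(dtype=float)
        if len(np.unique(years)) < 2:
            raise ValueError(f"need >= 2 history years for {age_group}/{sex}/{category}, got {len(years)}")
        slope, intercept = np.polyfit(years, fracs, 1)
        records.append(
            {
                "age_group": age_group,
                "sex": sex,
                "category": category,
                "slope_per_year": float(slope),
                "intercept": float(intercept),
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["age_group", "sex", "category", "slope_per_year", "intercept"]
    )


def extrapolate_fractions(
    history: pd.DataFrame, target_years: Sequence[int] | range, mode: str = "linear"
) -> pd.DataFrame:
    """Continue each prevalence series into ``target_years`` at its historical rate.

    ``mode='linear'`` fits an OLS line per stratum-category and evaluates it
    at the target years; ``mode='proportional'`` fits the line on log
    fractions instead (geometric decay; requires strictly positive history).
    Results are clamped to [0, 1] and the per-stratum-year category sum is
    capped at 1 by truncating the largest category.
    """
    if mode not in ("linear", "proportional"):
        raise ValueError(f"mode must be 'linear' or 'proportional', got {mode!r}")
    target_years = list(target_years)
    records: list[dict] = []
    raw: dict[tuple[int, str, str], dict[str, float]] = {}
    for (age_group, sex, category), grp in history.groupby(["age_group", "sex", "category"], sort=True):
        years = grp["year"].to_numpy(dtype=float)
        fracs = grp["fraction"].to_numpy(dtype=float)
        if len(np.unique(years)) < 2:
            raise ValueError(f"need >= 2 history years for {age_group}/{sex}/{category}, got {len(years)}")
        if mode == "linear":
            slope, intercept = np.polyfit(years, fracs, 1)
            predict = lambda y: intercept + slope * y  # noqa: E731
        else:
            if np.any(fracs <= 0):
                raise ValueError(
                    f"proportional mode needs strictly positive history for {age_group}/{sex}/{category}"
                )
            slope, intercept = np.polyfit(years, np.log(fracs), 1)
            predict = lambda y: float(np.exp(intercept + slope * y))  # noqa: E731
        for year in target_years:
            raw.setdefault((year, age_group, sex), {})[category] = float(predict(year))
    for (year, age_group, sex), by_cat in sorted(raw.items()):
        capped = cap_fractions(by_cat)
        for category in SMOKING_CATEGORIES:
            if category in by_cat:
                records.append(
                    {
                        "year": year,
                        "age_group": age_group,
                        "sex": sex,
                        "category": category,
                        "fraction": capped[category],
                    }
                )
    return pd.DataFrame.from_records(records, columns=["year", "age_group", "sex", "category", "fraction"])


@dataclass(frozen=True)
class ProjectionResult:
    """Projected per-year costs, real and nominal (inflation-applied)."""

    table: pd.DataFrame  # indexed by year
    base_year: int
    inflation: float

    def __post_init__(self) -> None:
        t = self.table
        if not np.allclose(t["total_real"], t["direct_real"] + t["indirect_real"]):
            raise ValueError("total_real must equal direct_real + indirect_real")


def _fractions_lookup(fractions: pd.DataFrame) -> dict[tuple[int, str, str], dict[str, float]]:
    out: dict[tuple[int, str, str], dict[str, float]] = {}
    for row in fractions.itertuples(index=False):
        out.setdefault((int(row.year), row.age_group, row.sex), {})[row.category] = float(row.fraction)
    return out


def project_costs(
    std: StandardisedCost,
    fractions: pd.DataFrame,
    population: pd.DataFrame,
    weights: SmokingWeights = DEFAULT_WEIGHTS,
    inflation: float = 0.02,
    retirement_age: int = 65,
) -> ProjectionResult:
    """Project annual direct/indirect costs over the years covered by ``population``.

    ``fractions``: long prevalence table (year, age_group, sex, category,
    fraction); ``population``: long counts (year, age_group, sex, count).
    Every (year, stratum) with a positive standardised cost must be covered
    by both tables. Nominal = real x (1+inflation)^(year - base_year).
    """
    frac = _fractions_lookup(fractions)
    years = sorted(population["year"].unique())
    if not years:
        raise ValueError("population projection covers no years")
    strata = std.strata()
    rows = {}
    for year in years:
        pop_year = population[population["year"] == year]
        pop = {(r.age_group, r.sex): float(r.count) for r in pop_year.itertuples(index=False)}
        direct_real = 0.0
        indirect_real = 0.0
        for age_group, sex in strata:
            std_direct = std.lookup(age_group, sex, "direct")
            std_indirect = std.lookup(age_group, sex, "indirect")
            if std_direct == 0.0 and std_indirect == 0.0:
                continue
            if (age_group, sex) not in pop:
                raise ValueError(f"population projection missing stratum {age_group}/{sex} in {year}")
            if (int(year), age_group, sex) not in frac:
                raise ValueError(f"smoking fractions missing stratum {age_group}/{sex} in {year}")
            eq = weighted_equivalents(frac[(int(year), age_group, sex)], pop[(age_group, sex)], weights)
            direct_real += eq * std_direct
            if parse_age_lower(age_group) < retirement_age:
                indirect_real += eq * std_indirect
        factor = (1.0 + inflation) ** (year - std.base_year)
        rows[int(year)] = {
            "direct_real": direct_real,
            "indirect_real": indirect_real,
            "total_real": direct_real + indirect_real,
            "direct_nominal": direct_real * factor,
            "indirect_nominal": indirect_real * factor,
            "total_nominal": (direct_real + indirect_real) * factor,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "year"
    return ProjectionResult(table, std.base_year, inflation)


def summarise_projection(result: ProjectionResult) -> dict:
    """First-year and last-year nominal totals plus the percentage change between them."""
    t = result.table
    if t.empty:
        raise ValueError("empty projection result")
    first_year, last_year = int(t.index.min()), int(t.index.max())
    first_total = float(t.loc[first_year, "total_nominal"])
    last_total = float(t.loc[last_year, "total_nominal"])
    change = None
    if last_year != first_year and first_total > 0:
        change = float(percent_change(first_total, last_total))
    return {
        "first_year": first_year,
        "last_year": last_year,
        "first_total_eur": first_total,
        "last_total_eur": last_total,
        "percent_change": change,
    }
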