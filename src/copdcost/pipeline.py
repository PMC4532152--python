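"""End-to-end pipeline: simulate (optional) -> cost accounting -> projection -> summary.

Every stage writes its tables as tab-separated text plus a JSON report, so a
run is fully reproducible and diffable. Stage failures abort with the stage
name and the underlying cause.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import accounting, projection, synth, tables
from .accounting import PriceIndexSeries, UnitCostTable
from .datasets import load_unit_costs
from .smoking import SmokingWeights

logger = logging.getLogger(__name__)

REGISTER_FILES = {
    "care": ("phc_hospital_day", "shc_hospital_day", "shc_outpatient_visit"),
    "medication": ("drug_purchase",),
    "allowances": ("sickness_allowance_day",),
    "pensions": ("disability_pension",),
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class PipelineConfig(BaseModel):
    """Everything one run needs: input paths or a simulation block, plus parameters."""

    registers_dir: str | None = None
    unit_costs_path: str | None = None
    price_index_path: str | None = None
    smoking_path: str | None = None
    population_path: str | None = None

    simulate: synth.SimulationConfig | None = None
    price_index_rate: float = 0.02
    smoking_slopes_pp: dict[str, float] | None = None
    population_growth_rate: float = 0.0

    base_year: int = 2006
    projection_years: tuple[int, int] | None = None
    inflation: float = 0.02
    retirement_age: int = 65
    weights: tuple[float, float, float, float] = (1.0, 1.0, 0.75, 0.5)
    days_per_man_year: float = Field(default=260.0, gt=0)
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def smoking_weights(self) -> SmokingWeights:
        a, q13, q35, q510 = self.weights
        return SmokingWeights(active=a, quit_1_3=q13, quit_3_5=q35, quit_5_10=q510)


def write_registers(events: pd.DataFrame, outdir: str | Path) -> dict[str, Path]:
    """Split an event table into one file per source register."""
    outdir = Path(outdir)
    paths = {}
    for name, categories in REGISTER_FILES.items():
        subset = events[events["category"].isin(categories)]
        paths[name] = tables.write_table(subset, outdir / f"{name}.tsv", tables.REGISTER_EVENTS)
    return paths


def read_registers(directory: str | Path) -> pd.DataFrame:
    """Read and concatenate every register file in a directory."""
    directory = Path(directory)
    files = sorted(directory.glob("*.tsv"))
    if not files:
        raise FileNotFoundError(f"no register files (*.tsv) in {directory}")
    frames = [tables.read_table(p, tables.REGISTER_EVENTS) for p in files]
    return pd.concat(frames, ignore_index=True)


def _load_unit_costs(config: PipelineConfig) -> UnitCostTable:
    if config.unit_costs_path is None:
        return load_unit_costs()
    raw = json.loads(Path(config.unit_costs_path).read_text(encoding="utf-8"))
    return UnitCostTable(**raw)


def run_cost_stage(
    events: pd.DataFrame,
    costs: UnitCostTable,
    index: PriceIndexSeries,
    days_per_man_year: float,
    population_by_year: pd.Series | None = None,
) -> dict[str, Any]:
    """Filter, summarise and price one event table into a cost breakdown bundle."""
    care = accounting.filter_copd_events(events)
    meds = accounting.filter_copd_medication(events)
    filtered = pd.concat([care, meds], ignore_index=True)
    utilisation = accounting.summarise_utilisation(filtered)
    direct = accounting.compute_direct_costs(utilisation, costs, index)
    indirect = accounting.compute_indirect_costs(utilisation, costs, days_per_man_year, index)
    breakdown = accounting.assemble_breakdown(direct, indirect)
    tidy_records = []
    for year in breakdown.index:
        pop = None
        if population_by_year is not None and year in population_by_year.index:
            pop = float(population_by_year.loc[year])
        for component in accounting.BREAKDOWN_COLUMNS:
            eur = int(breakdown.loc[year, component])
            tidy_records.append(
                {
                    "year": int(year),
                    "component": component,
                    "euros": eur,
                    "euros_per_100k": accounting.per_capita(eur, pop) if pop else "",
                }
            )
    tidy = pd.DataFrame.from_records(tidy_records, columns=["year", "component", "euros", "euros_per_100k"])
    return {
        "care_events": care,
        "medication_events": meds,
        "utilisation": utilisation,
        "breakdown": breakdown,
        "tidy": tidy,
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute simulate (optional) -> cost -> project -> summarise, writing all tables.

    Returns the bundle of frames and summaries. Identical config (including
    seed) produces byte-identical output files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Any] = {}
    weights = config.smoking_weights()

    # --- stage: simulate or load -------------------------------------------------
    stage = "simulate" if config.simulate is not None else "load"
    try:
        if config.simulate is not None:
            sim = config.simulate
            if config.seed is not None:
                sim = sim.model_copy(update={"seed": config.seed})
            events = synth.generate_registers(sim, weights)
            smoking = synth.generate_smoking_series(sim, config.smoking_slopes_pp)
            population = synth.generate_population_table(sim)
            index_series = synth.generate_price_index(
                sim.year_range(), config.price_index_rate, base_year=config.base_year
            )
            write_registers(events, outdir / "registers")
            tables.write_table(smoking, outdir / "smoking.tsv", tables.SMOKING_PREVALENCE)
            tables.write_table(population, outdir / "population.tsv", tables.POPULATION)
            tables.write_table(
                index_series.rename("index").rename_axis("year").reset_index(), outdir / "price_index.tsv", tables.PRICE_INDEX
            )
        else:
            if config.registers_dir is None:
                raise ValueError("either 'simulate' or 'registers_dir' must be configured")
            events = read_registers(config.registers_dir)
            smoking = (
                tables.read_table(config.smoking_path, tables.SMOKING_PREVALENCE)
                if config.smoking_path
                else None
            )
            population = (
                tables.read_table(config.population_path, tables.POPULATION) if config.population_path else None
            )
            if config.price_index_path:
                idx_df = tables.read_table(config.price_index_path, tables.PRICE_INDEX)
                index_series = pd.Series(idx_df["index"].values, index=idx_df["year"].values, name="index")
            else:
                raise ValueError("price_index_path required when not simulating")
        logger.info("stage %s: %d events", stage, len(events))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc
    bundle["events"] = events
    bundle["smoking"] = smoking
    bundle["population"] = population

    # --- stage: cost -------------------------------------------------------------
    try:
        costs = _load_unit_costs(config)
        index = PriceIndexSeries.from_series(index_series, reference_year=config.base_year)
        pop_by_year = population.groupby("year")["count"].sum() if population is not None else None
        cost_bundle = run_cost_stage(events, costs, index, config.days_per_man_year, pop_by_year)
        tables.write_table(cost_bundle["utilisation"], outdir / "utilisation.tsv")
        tables.write_table(cost_bundle["breakdown"], outdir / "cost_breakdown.tsv")
        tables.write_table(cost_bundle["tidy"], outdir / "costs_tidy.tsv")
        accounting.validate_breakdown(cost_bundle["breakdown"])
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("cost", exc) from exc
    bundle.update(cost_bundle)

    # --- stage: project ----------------------------------------------------------
    summary: dict[str, Any] = {
        "base_year": config.base_year,
        "years_covered": [int(y) for y in cost_bundle["breakdown"].index],
        "totals_eur": {int(y): int(cost_bundle["breakdown"].loc[y, "total"]) for y in cost_bundle["breakdown"].index},
    }
    if config.projection_years is not None:
        try:
            if smoking is None or population is None:
                raise ValueError("projection requires smoking and population tables")
            first, last = config.projection_years
            stratum_costs = accounting.compute_stratum_costs(
                cost_bundle["care_events"],
                cost_bundle["medication_events"],
                costs,
                index,
                config.base_year,
                config.days_per_man_year,
            )
            base_frac = smoking[smoking["year"] == config.base_year]
            base_pop = population[population["year"] == config.base_year]
            eq_records = []
            for row in base_pop.itertuples(index=False):
                f = base_frac[(base_frac["age_group"] == row.age_group) & (base_frac["sex"] == row.sex)]
                fractions = dict(zip(f["category"], f["fraction"]))
                eq_records.append(
                    {
                        "age_group": row.age_group,
                        "sex": row.sex,
                        "equivalents": projection.weighted_equivalents(fractions, row.count, weights),
                    }
                )
            equivalents = pd.DataFrame.from_records(eq_records, columns=["age_group", "sex", "equivalents"])
            std = projection.standardise_costs(stratum_costs, equivalents, config.base_year)
            history = smoking[smoking["year"] <= config.base_year]
            future_years = range(first, last + 1)
            future_frac = projection.extrapolate_fractions(history, future_years)
            future_pop_records = []
            for row in base_pop.itertuples(index=False):
                for year in future_years:
                    grown = row.count * (1.0 + config.population_growth_rate) ** (year - config.base_year)
                    future_pop_records.append(
                        {"year": year, "age_group": row.age_group, "sex": row.sex, "count": grown}
                    )
            future_pop = pd.DataFrame.from_records(future_pop_records, columns=["year", "age_group", "sex", "count"])
            result = projection.project_costs(
                std, future_frac, future_pop, weights, config.inflation, config.retirement_age
            )
            tables.write_table(
                std.table, outdir / "standardised_costs.tsv", tables.STANDARDISED_COST
            )
            tables.write_table(result.table, outdir / "projection.tsv")
            proj_summary = projection.summarise_projection(result)
            summary["projection"] = proj_summary
            bundle["standardised_costs"] = std
            bundle["projection"] = result
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("project", exc) from exc

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    bundle["summary"] = summary
    return bundle
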