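"""Loaders for the reference tables shipped with the package.

The packaged fixtures are the published Finnish national figures for 1996
and 2006: reference-year unit costs, register utilisation counts (with the
medication Euro total), and the per-component cost breakdown with its
per-100,000 column.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .accounting import UnitCostTable
from .tables import COST_REFERENCE, UTILISATION, read_table


def _data_path(name: str):
    return resources.files("copdcost").joinpath("data", name)


def load_unit_costs() -> UnitCostTable:
    """Published 2006 unit costs (142/590/200 € services, 24,600 € per lost man-year)."""
    with resources.as_file(_data_path("unit_costs_2006.json")) as p:
        raw = json.loads(p.read_text(encoding="utf-8"))
    return UnitCostTable(**raw)


def load_utilisation_reference() -> pd.DataFrame:
    """National register utilisation counts for 1996 and 2006, indexed by year."""
    with resources.as_file(_data_path("utilisation_fi.tsv")) as p:
        df = read_table(p, UTILISATION)
    return df.set_index("year")


def load_cost_reference() -> pd.DataFrame:
    """National cost breakdown for 1996 and 2006 (long format: year, component, eur, eur_per_100k)."""
    with resources.as_file(_data_path("cost_reference_fi.tsv")) as p:
        return read_table(p, COST_REFERENCE)


def cost_reference_wide() -> pd.DataFrame:
    """Cost breakdown pivoted to the breakdown-table layout (year index, component columns)."""
    long = load_cost_reference()
    wide = long.pivot(index="year", columns="component", values="eur")
    wide.columns.name = None
    return wide
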