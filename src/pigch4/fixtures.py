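"""Bundled fixture tables: feedstuffs, diets, management, storage.

The feed-ingredient compositions reproduce published Danish table values;
digestibility coefficients and growing-pig performance constants are
documented plausible defaults (the original normative sources are not
redistributable) and are meant to be edited for local conditions.  Diet
formulations cover the average Danish diet per pig category plus the
fiber-substitution variants: part of the wheat (or barley) inclusion is
swapped for sugar beet pulp, wheat bran, oats, soy hulls, or extra wheat.
Substituted-diet energy densities are derived from the reported intakes of
those diets.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .diet_composition import substitute
from .feed_data import (DietSpec, FeedTable, PigCategoryConfig, StorageConfig,
                        load_feed_table, load_management)

CATEGORIES = ("weaned", "grower_finisher", "gestating_sow", "lactating_sow")

#: (diet name, removed ingredient, added ingredient, as-fed points swapped)
_SUBSTITUTIONS = {
    "weaned": (("sugar_beet_pulp", "wheat", "sugar beet pulp", 0.05),
               ("wheat_bran", "wheat", "wheat bran", 0.05),
               ("oat", "wheat", "oats", 0.10),
               ("wheat", "barley", "wheat", 0.10)),
    "grower_finisher": (("sugar_beet_pulp", "wheat", "sugar beet pulp", 0.05),
                        ("wheat_bran", "wheat", "wheat bran", 0.05),
                        ("oat", "wheat", "oats", 0.10),
                        ("wheat", "barley", "wheat", 0.10)),
    "lactating_sow": (("sugar_beet_pulp", "wheat", "sugar beet pulp", 0.05),
                      ("wheat_bran", "wheat", "wheat bran", 0.05),
                      ("oat", "wheat", "oats", 0.10),
                      ("wheat", "barley", "wheat", 0.10)),
    "gestating_sow": (("sugar_beet_pulp", "wheat", "sugar beet pulp", 0.10),
                      ("wheat_bran", "wheat", "wheat bran", 0.10),
                      ("oat", "wheat", "oats", 0.10),
                      ("wheat", "barley", "wheat", 0.10),
                      ("soy_hull", "wheat", "soy hulls", 0.10)),
}


def data_path(name: str) -> Path:
    return Path(resources.files("pigch4").joinpath("data", name))


def feed_table() -> FeedTable:
    return load_feed_table(data_path("feedstuffs.csv"), data_path("digestibility.csv"))


def management() -> tuple[dict[str, PigCategoryConfig], StorageConfig]:
    return load_management(data_path("management.yaml"))


def category_config(category: str) -> PigCategoryConfig:
    return management()[0][category]


def storage_config() -> StorageConfig:
    return management()[1]


def _energy_densities() -> dict[tuple[str, str], float]:
    df = pd.read_csv(data_path("diet_energy.csv"))
    return {(r["category"], r["diet"]): float(r["fu_per_kg_asfed"])
            for _, r in df.iterrows()}


def average_diet(category: str) -> DietSpec:
    """The average Danish diet for one pig category."""
    df = pd.read_csv(data_path("diets.csv"))
    rows = df[(df["category"] == category) & (df["diet"] == "average")]
    if rows.empty:
        raise KeyError(f"no bundled diet for category {category!r}")
    fu = _energy_densities()[(category, "average")]
    items = tuple((str(r["ingredient"]), float(r["proportion_asfed"]))
                  for _, r in rows.iterrows())
    return DietSpec(name="average", items=items, fu_per_kg_asfed=fu, category=category)


def standard_diets(category: str) -> dict[str, DietSpec]:
    """Average diet plus all fiber-substitution variants for one category."""
    base = average_diet(category)
    fu = _energy_densities()
    diets = {"average": base}
    for name, remove, add, points in _SUBSTITUTIONS[category]:
        diets[name] = substitute(base, remove, add, points,
                                 fu_per_kg_asfed=fu[(category, name)], name=name)
    return diets
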