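"""Orchestration of the full estimation chain for one category and diet.

``run_scenario`` composes diet mixing, intake, excretion, the enteric
regression and the barn + storage manure simulation into one deterministic
result with every intermediate exposed, and emits report rows mirroring the
study's summary tables (nutrient intake, excreta, emission per source).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import fixtures
from .diet_composition import DietComposition, mix_composition
from .enteric import EntericResult, enteric_emission
from .excretion import ExcretaProfile, build_excreta
from .feed_data import (DietSpec, FeedDataError, FeedTable, PigCategoryConfig,
                        StorageConfig)
from .intake import IntakeResult, daily_intake
from .manure_sim import (EmissionLedger, KineticParams, excreta_to_influent,
                         simulate_barn, simulate_storage, spillage_sweep)

DEFAULT_SPILLAGE = 0.02  # fraction of feed intake spilled into the pit
#: default simulation horizon: one spin-up year plus one reported year
DEFAULT_HORIZON = 730


@dataclass(frozen=True)
class ScenarioResult:
    category: str
    diet: str
    composition: DietComposition
    intake: IntakeResult
    excreta: ExcretaProfile
    enteric: EntericResult
    barn: EmissionLedger
    storage: EmissionLedger

    @property
    def barn_kg_yr(self) -> float:
        return self.barn.annual_ch4_kg

    @property
    def storage_kg_yr(self) -> float:
        return self.storage.annual_ch4_kg

    @property
    def enteric_kg_yr(self) -> float:
        return self.enteric.ch4_kg_yr

    @property
    def manure_kg_yr(self) -> float:
        return self.barn_kg_yr + self.storage_kg_yr

    @property
    def total_kg_yr(self) -> float:
        return self.enteric_kg_yr + self.manure_kg_yr

    @property
    def shares(self) -> dict[str, float]:
        return summarize_shares(self.enteric_kg_yr, self.barn_kg_yr, self.storage_kg_yr)


def summarize_shares(enteric: float, barn: float, storage: float) -> dict[str, float]:
    """Percentage contribution of each source to the total CH4 emission."""
    total = enteric + barn + storage
    if total <= 0:
        raise FeedDataError("summarize_shares: total emission must be positive")
    return {
        "enteric": enteric / total * 100.0,
        "barn": barn / total * 100.0,
        "storage": storage / total * 100.0,
        "manure": (barn + storage) / total * 100.0,
    }


def run_scenario(config: PigCategoryConfig, diet: DietSpec, table: FeedTable,
                 storage: StorageConfig, params: KineticParams | None = None, *,
                 spillage: float = DEFAULT_SPILLAGE, horizon: int = DEFAULT_HORIZON,
                 dt: float = 0.05) -> ScenarioResult:
    """Run the whole chain: diet -> intake -> excreta -> enteric + manure CH4."""
    params = params or KineticParams()
    composition = mix_composition(diet, table)
    intake = daily_intake(config, composition, diet.fu_per_kg_asfed)
    excreta = build_excreta(intake, composition, table, config)
    enteric = enteric_emission(
        config.category,
        snsp_intake=intake.nutrient("snsp"),
        ff_intake=excreta.ff_intake,
        body_weight=config.body_weight,
        feed_asfed=intake.feed_asfed,
    )
    influent = excreta_to_influent(excreta, spillage, composition, intake)
    barn, batches = simulate_barn(config, influent, params, horizon, dt=dt)
    store = simulate_storage(batches, storage, params, horizon, dt=dt)
    return ScenarioResult(category=config.category, diet=diet.name,
                          composition=composition, intake=intake, excreta=excreta,
                          enteric=enteric, barn=barn, storage=store)


def run_standard_scenario(category: str, diet_name: str = "average", *,
                          spillage: float = DEFAULT_SPILLAGE, horizon: int = DEFAULT_HORIZON,
                          dt: float = 0.05,
                          params: KineticParams | None = None) -> ScenarioResult:
    """Convenience wrapper over the bundled fixtures."""
    table = fixtures.feed_table()
    configs, storage = fixtures.management()
    diet = fixtures.standard_diets(category)[diet_name]
    return run_scenario(configs[category], diet, table, storage, params,
                        spillage=spillage, horizon=horizon, dt=dt)


def run_spillage_sweep(category: str, fractions=(0.0, 0.02, 0.04, 0.06, 0.08), *,
                       horizon: int = DEFAULT_HORIZON, dt: float = 0.05,
                       params: KineticParams | None = None) -> dict[float, ScenarioResult]:
    """Average-diet scenario of one category at several spillage levels."""
    return spillage_sweep(
        lambda f: run_standard_scenario(category, spillage=f, horizon=horizon,
                                        dt=dt, params=params),
        tuple(fractions))


# ---------------------------------------------------------------------------
# report rows (printed precision mirrors the field's summary tables;
# internal values stay full precision)

def intake_row(r: ScenarioResult) -> dict[str, float]:
    c = r.composition
    return {"category": r.category, "diet": r.diet,
            "feed_intake_g_d": round(r.intake.feed_asfed),
            "dm_g_kg": round(c.dm),
            "cp": round(c.cp), "cf": round(c.cf), "starch": round(c.starch),
            "sugar": round(c.sugar), "snsp": round(c.snsp), "rf": round(c.rf),
            "indf": round(c.indf), "ash": round(c.ash)}


def excreta_row(r: ScenarioResult) -> dict[str, float]:
    e = r.excreta
    fc = e.feces_composition
    return {"category": r.category, "diet": r.diet,
            "feces_cp": round(fc["cp"]), "feces_cf": round(fc["cf"]),
            "feces_rf": round(fc["rf"]), "feces_indf": round(fc["indf"]),
            "feces_starch": round(fc["starch"], 1),
            "ff_g_kg_dm": round(e.ff),
            "feces_dm_g_d": round(e.feces_dm),
            "feces_mass_g_d": round(e.feces_mass),
            "urine_g_d": round(e.urine_volume)}


def emission_row(r: ScenarioResult) -> dict[str, float]:
    return {"category": r.category, "diet": r.diet,
            "enteric_g_d": round(r.enteric.ch4_g_d, 2),
            "enteric_g_kg_feed": round(r.enteric.ch4_g_per_kg_feed, 2),
            "enteric_kg_yr": round(r.enteric_kg_yr, 2),
            "barn_kg_yr": round(r.barn_kg_yr, 2),
            "storage_kg_yr": round(r.storage_kg_yr, 2),
            "total_kg_yr": round(r.total_kg_yr, 2)}


def report_tables(results: list[ScenarioResult]) -> dict[str, pd.DataFrame]:
    """Three summary tables (intake, excreta, emissions) from scenario runs."""
    return {
        "intake": pd.DataFrame([intake_row(r) for r in results]),
        "excreta": pd.DataFrame([excreta_row(r) for r in results]),
        "emissions": pd.DataFrame([emission_row(r) for r in results]),
    }
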