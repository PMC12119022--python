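"""Digestion and excretion: feces, urine, fermentable and degradable fiber.

Apparent total-tract digestibility coefficients are applied per ingredient
(growing-pig coefficients for weaned and grower-finisher pigs, sow
coefficients for gestating and lactating sows; crude-fat and starch+sugar
coefficients shared across classes).  Starch and sugar are digested as one
pool.  Everything not digested is excreted; excreted residual fiber follows
by difference, and its potentially degradable part is what remains after
removing the indigestible NDF, which passes through the gut unchanged.

Empirical excretion relations:

* urine N (g/d)       = -21.20 + 0.134 x dietary CP (g/kg DM) + 10.15 x DMI (kg/d)
  (grower-finisher pigs and sows; weaned pigs use an N balance instead)
* feces mass (kg/d)   = 5.405 - 6.31 x diet OM digestibility + 0.505 x DMI (kg/d)
  (weaned pigs instead use feces DM / 0.25, i.e. 25% DM in feces)
* urine volume        = 2.0 (growing) or 2.5 (sows) kg per kg DM intake
* fecal VFA           = 2.87 g per kg excreted feces mass
* urea N              = 75% of urine N
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .diet_composition import DietComposition
from .feed_data import (FeedDataError, FeedTable, GrowingIntakeParams,
                        PigCategoryConfig, animal_class_for)
from .intake import IntakeResult

UREA_FRACTION = 0.75  # urea N / total urine N
FECAL_VFA_G_PER_KG_FECES = 2.87
WEANED_FECES_DM_FRACTION = 0.25
#: g body N per kg live-weight gain, used in the weaned-pig N balance
BODY_N_PER_KG_GAIN = 25.6
#: apparent "digestibility" (absorption) of dietary ash; feces ash closure term
ASH_ABSORPTION = 0.50
N_PER_CP = 1.0 / 6.25

DIGESTED_POOLS = ("om", "cp", "cf", "starch_sugar")


@dataclass(frozen=True)
class DigestionResult:
    """Per-pool digested/excreted flows (g/day) and diet-level coefficients."""

    digested: dict[str, float]  # g/day per pool
    excreted: dict[str, float]  # g/day per pool
    digested_per_kg_dm: dict[str, float]  # g per kg diet DM
    d_om_diet: float  # intake-weighted whole-diet OM digestibility


@dataclass(frozen=True)
class ExcretaProfile:
    feces_dm: float  # g/day
    feces_mass: float  # g/day
    urine_volume: float  # g/day
    urine_n: float  # g N/day
    urea_n: float  # g N/day
    fecal_vfa: float  # g/day
    ff: float  # fermentable fiber, g/kg DM of feed
    ff_intake: float  # g/day
    feces_composition: dict[str, float]  # g/kg feces DM: cp, cf, rf, indf, starch, degradable_rf
    excreted: dict[str, float]  # g/day: om, cp, cf, starch_sugar, rf, indf, degradable_rf, ash


def digest_nutrients(intake: IntakeResult, dm_proportions, table: FeedTable,
                     animal_class: str) -> DigestionResult:
    """Apply per-ingredient digestibility coefficients to the daily intake.

    Mineral ingredients carry no organic matter and need no coefficients.
    """
    digested = {k: 0.0 for k in DIGESTED_POOLS}
    excreted = {k: 0.0 for k in DIGESTED_POOLS}
    om_intake = 0.0
    for name, a in dm_proportions:
        ing = table.ingredient(name)
        if ing.is_mineral:
            continue
        rec = table.digestibility_for(name, animal_class)
        ing_dm = intake.dmi * a  # g DM/day of this ingredient
        flows = {
            "om": (ing.om, rec.d_om),
            "cp": (ing.cp, rec.d_cp),
            "cf": (ing.cf, rec.d_cf),
            "starch_sugar": (ing.starch + ing.sugar, rec.d_starch_sugar),
        }
        om_intake += ing_dm * ing.om / 1000.0
        for pool, (conc, coeff) in flows.items():
            amount = ing_dm * conc / 1000.0
            digested[pool] += amount * coeff
            excreted[pool] += amount * (1.0 - coeff)
    per_kg = {k: digested[k] / (intake.dmi / 1000.0) for k in DIGESTED_POOLS}
    d_om_diet = digested["om"] / om_intake if om_intake > 0 else 0.0
    return DigestionResult(digested=digested, excreted=excreted,
                           digested_per_kg_dm=per_kg, d_om_diet=d_om_diet)


def digested_rf(d_om: float, d_cp: float, d_cf: float, d_ss: float) -> float:
    """Digested residual fiber (g/kg DM) by difference, clamped at zero."""
    value = d_om - d_cp - d_cf - d_ss
    if value < 0:
        warnings.warn("digested RF negative; clamped to 0", stacklevel=2)
        return 0.0
    return value


def fermentable_fiber(d_om: float, d_cp: float, d_cf: float, d_ss: float) -> float:
    """Fermentable fiber (g/kg DM feed): the substrate of the sow enteric
    regression; same by-difference form as digested residual fiber."""
    return digested_rf(d_om, d_cp, d_cf, d_ss)


def degradable_rf(rf: float, indf: float) -> float:
    """Potentially degradable residual fiber: rf - indf, clamped at zero."""
    if rf < 0 or indf < 0:
        raise FeedDataError("degradable_rf: negative input")
    value = rf - indf
    if value < 0:
        warnings.warn("degradable RF negative (indf > rf); clamped to 0", stacklevel=2)
        return 0.0
    return value


def urine_nitrogen(cp_diet: float, dmi_kg: float) -> float:
    """Urine N (g/day) from dietary CP (g/kg DM) and DM intake (kg/day)."""
    if dmi_kg <= 0:
        raise FeedDataError("urine_nitrogen: dmi must be positive")
    value = -21.20 + 0.134 * cp_diet + 10.15 * dmi_kg
    if value <= 0:
        raise FeedDataError(
            f"urine_nitrogen: nonpositive prediction ({value:.2f} g/d); "
            "use the nitrogen-balance route for this animal")
    return value


def urine_nitrogen_balance(n_intake: float, n_feces: float, n_retained: float) -> float:
    """Urine N (g/day) as intake minus fecal and retained N (weaned pigs)."""
    for v, label in ((n_intake, "n_intake"), (n_feces, "n_feces"), (n_retained, "n_retained")):
        if v < 0:
            raise FeedDataError(f"urine_nitrogen_balance: {label} < 0")
    value = n_intake - n_feces - n_retained
    if value < 0:
        raise FeedDataError(
            f"urine_nitrogen_balance: infeasible balance ({value:.2f} g/d)")
    return value


def feces_mass(d_om_coeff: float, dmi_kg: float) -> float:
    """Feces fresh mass (kg/day) from diet OM digestibility and DM intake."""
    if not 0.0 <= d_om_coeff <= 1.0:
        raise FeedDataError("feces_mass: d_om_coeff outside [0, 1]")
    value = 5.405 - 6.31 * d_om_coeff + 0.505 * dmi_kg
    if value <= 0:
        raise FeedDataError(f"feces_mass: nonpositive prediction ({value:.3f} kg/d)")
    return value


def feces_mass_weaned(feces_dm: float, dm_fraction: float = WEANED_FECES_DM_FRACTION) -> float:
    """Feces fresh mass (g/day) for weaned pigs from feces DM at fixed DM%."""
    if not 0.0 < dm_fraction < 1.0:
        raise FeedDataError("feces_mass_weaned: dm_fraction outside (0, 1)")
    if feces_dm < 0:
        raise FeedDataError("feces_mass_weaned: negative feces_dm")
    return feces_dm / dm_fraction


def urine_volume(dmi_kg: float, config: PigCategoryConfig) -> float:
    """Urine volume (kg/day): 2.0 (growing) or 2.5 (sows) kg per kg DMI."""
    if dmi_kg < 0:
        raise FeedDataError("urine_volume: negative dmi")
    return config.urine_per_dmi * dmi_kg


def build_excreta(intake: IntakeResult, composition: DietComposition,
                  table: FeedTable, config: PigCategoryConfig,
                  body_n_per_kg_gain: float = BODY_N_PER_KG_GAIN) -> ExcretaProfile:
    """Run the full digestion/excretion chain for one category and diet."""
    animal_class = animal_class_for(config.category)
    digestion = digest_nutrients(intake, composition.dm_proportions, table, animal_class)
    dmi_kg = intake.dmi / 1000.0

    exc = dict(digestion.excreted)
    # by-difference excreted residual fiber (g/day)
    exc_rf = max(exc["om"] - exc["cp"] - exc["cf"] - exc["starch_sugar"], 0.0)
    indf_excreted = intake.nutrient("indf")  # indigestible by definition
    exc_deg_rf = max(exc_rf - indf_excreted, 0.0)
    ash_excreted = intake.nutrient("ash") * (1.0 - ASH_ABSORPTION)
    feces_dm_g = exc["om"] + ash_excreted

    if config.category == "weaned":
        feces_mass_g = feces_mass_weaned(feces_dm_g)
    else:
        feces_mass_g = feces_mass(digestion.d_om_diet, dmi_kg) * 1000.0

    urine_kg = urine_volume(dmi_kg, config)

    if config.category == "weaned":
        p = config.intake_params
        if not isinstance(p, GrowingIntakeParams):
            raise FeedDataError("weaned category requires growing intake parameters")
        gain_per_day = p.gain_per_cycle / p.cycle_days
        urine_n = urine_nitrogen_balance(
            n_intake=intake.nutrient("cp") * N_PER_CP,
            n_feces=exc["cp"] * N_PER_CP,
            n_retained=gain_per_day * body_n_per_kg_gain)
    else:
        urine_n = urine_nitrogen(composition.cp, dmi_kg)

    per_kg = digestion.digested_per_kg_dm
    ff = fermentable_fiber(per_kg["om"], per_kg["cp"], per_kg["cf"], per_kg["starch_sugar"])

    def per_kg_feces(g_per_day: float) -> float:
        return g_per_day / feces_dm_g * 1000.0 if feces_dm_g > 0 else 0.0

    composition_feces = {
        "cp": per_kg_feces(exc["cp"]),
        "cf": per_kg_feces(exc["cf"]),
        "rf": per_kg_feces(exc_rf),
        "indf": per_kg_feces(indf_excreted),
        "starch": per_kg_feces(exc["starch_sugar"]),
        "degradable_rf": per_kg_feces(exc_deg_rf),
    }
    excreted = {**exc, "rf": exc_rf, "indf": indf_excreted,
                "degradable_rf": exc_deg_rf, "ash": ash_excreted}
    return ExcretaProfile(
        feces_dm=feces_dm_g,
        feces_mass=feces_mass_g,
        urine_volume=urine_kg * 1000.0,
        urine_n=urine_n,
        urea_n=UREA_FRACTION * urine_n,
        fecal_vfa=FECAL_VFA_G_PER_KG_FECES * feces_mass_g / 1000.0,
        ff=ff,
        ff_intake=ff * dmi_kg,
        feces_composition=composition_feces,
        excreted=excreted,
    )
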