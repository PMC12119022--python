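"""Data model, validation and file I/O for feed tables, diets and management.

Feed ingredients carry dry matter (g DM/kg as-fed) and nutrient concentrations
per kg DM: organic matter (om), crude protein (cp), crude fat (cf), starch,
sugar, residual fiber (rf), indigestible NDF (indf), non-starch
polysaccharides (nsp) and their soluble fraction (snsp), plus ash.  Residual
fiber is the by-difference fraction om - cp - cf - starch - sugar; printed
tables round to the gram, so a 2 g/kg tolerance separates rounding noise from
genuine inconsistency.

All files are plain comma-separated UTF-8 with a mandatory header row.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

NUTRIENTS = ("om", "cp", "cf", "starch", "sugar", "rf", "indf", "nsp", "snsp", "ash")

#: animal classes used for digestibility lookups
GROWING_CATEGORIES = ("weaned", "grower_finisher")
SOW_CATEGORIES = ("gestating_sow", "lactating_sow")

FEEDSTUFF_COLUMNS = ("name", "dm") + NUTRIENTS
DIGESTIBILITY_COLUMNS = ("ingredient", "animal_class", "d_om", "d_cp", "d_cf", "d_starch_sugar")
DIET_COLUMNS = ("ingredient", "proportion_asfed")

#: tolerance (g/kg DM) for printed-table rounding on rf and om+ash closure
ROUNDING_TOL = 2.0


class FeedDataError(ValueError):
    """Raised for schema violations, unresolvable references or invalid values."""


def animal_class_for(category: str) -> str:
    """Map a pig category to its digestibility class (growing or sow)."""
    if category in GROWING_CATEGORIES:
        return "growing"
    if category in SOW_CATEGORIES:
        return "sow"
    raise FeedDataError(f"unknown pig category {category!r}")


@dataclass(frozen=True)
class FeedIngredient:
    name: str
    dm: float  # g DM per kg as-fed
    om: float
    cp: float
    cf: float
    starch: float
    sugar: float
    rf: float
    indf: float
    nsp: float
    snsp: float
    ash: float

    @property
    def is_mineral(self) -> bool:
        """Pure mineral/additive carriers contribute no organic matter."""
        return self.om == 0.0

    def nutrient(self, key: str) -> float:
        return getattr(self, key)


@dataclass(frozen=True)
class Finding:
    """One validation finding; ``severity`` is 'error' or 'warning'."""

    severity: str
    rule: str
    message: str

    @property
    def is_error(self) -> bool:
        return self.severity == "error"


@dataclass(frozen=True)
class DigestibilityRecord:
    ingredient: str
    animal_class: str  # 'growing' or 'sow'
    d_om: float
    d_cp: float
    d_cf: float
    d_starch_sugar: float

    def coefficient(self, key: str) -> float:
        return getattr(self, f"d_{key}")


@dataclass
class FeedTable:
    """Feed-ingredient compositions plus per-class digestibility coefficients."""

    ingredients: dict[str, FeedIngredient]
    digestibility: dict[tuple[str, str], DigestibilityRecord]

    def ingredient(self, name: str) -> FeedIngredient:
        try:
            return self.ingredients[name]
        except KeyError:
            raise FeedDataError(f"unknown ingredient {name!r}") from None

    def digestibility_for(self, name: str, animal_class: str) -> DigestibilityRecord:
        try:
            return self.digestibility[(name, animal_class)]
        except KeyError:
            raise FeedDataError(
                f"no digestibility record for ingredient {name!r}, class {animal_class!r}"
            ) from None

    def validate(self) -> None:
        for name, ing in self.ingredients.items():
            errors = [f for f in validate_ingredient(ing) if f.is_error]
            if errors:
                raise FeedDataError(
                    f"ingredient {name!r}: " + "; ".join(f.message for f in errors)
                )
            if not ing.is_mineral:
                for cls in ("growing", "sow"):
                    self.digestibility_for(name, cls)


@dataclass(frozen=True)
class DietSpec:
    """A diet as an as-fed inclusion list plus its net-energy density.

    ``fu_per_kg_asfed`` is the Danish feed-unit density (FUsv for growing
    pigs, FUso for sows) per kg as-fed feed; diets within a category are
    compared at equal daily FU intake, so a fiber-diluted diet (lower FU/kg)
    implies a higher as-fed intake.
    """

    name: str
    items: tuple[tuple[str, float], ...]  # (ingredient, as-fed kg/kg)
    fu_per_kg_asfed: float
    category: str

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.items)
        if abs(total - 1.0) > 1e-3:
            raise FeedDataError(
                f"diet {self.name!r}: inclusion proportions sum to {total:.4f}, not 1"
            )
        for ing, p in self.items:
            if p < 0:
                raise FeedDataError(f"diet {self.name!r}: negative inclusion for {ing!r}")
        if self.fu_per_kg_asfed <= 0:
            raise FeedDataError(f"diet {self.name!r}: nonpositive energy density")


@dataclass(frozen=True)
class GrowingIntakeParams:
    gain_per_cycle: float  # kg gain per batch cycle
    feed_efficiency: float  # FU per kg gain
    cycle_days: float


@dataclass(frozen=True)
class SowIntakeParams:
    fu_stages: tuple[float, ...]  # FU/year/sow per production stage
    feeding_days: float  # feeding days per year


@dataclass(frozen=True)
class PigCategoryConfig:
    category: str
    body_weight: float  # kg
    manure_temp_barn: float  # deg C
    removal_interval: int  # days
    floor_area: float  # m2 per animal place
    pit_area: float  # m2 per animal place
    cycle_period: int  # days
    empty_days: int  # days per cycle
    wash_water: float  # kg per animal place per cycle
    urine_per_dmi: float  # kg urine per kg DM intake
    intake_params: GrowingIntakeParams | SowIntakeParams

    def __post_init__(self) -> None:
        if self.empty_days >= self.cycle_period:
            raise FeedDataError("empty_days must be smaller than cycle_period")
        expected = 2.0 if self.category in GROWING_CATEGORIES else 2.5
        if self.urine_per_dmi != expected:
            raise FeedDataError(
                f"urine_per_dmi for {self.category} should be {expected}"
            )
        for key in ("body_weight", "removal_interval", "floor_area", "pit_area",
                    "cycle_period"):
            if getattr(self, key) <= 0:
                raise FeedDataError(f"{key} must be positive")


@dataclass(frozen=True)
class StorageConfig:
    """Covered outdoor slurry tank with a seasonal temperature series."""

    monthly_temps: tuple[float, ...]
    removal_schedule: tuple[tuple[int, float], ...] = ((105, 0.80), (288, 0.20))
    height: float = 5.5  # m
    diameter: float = 36.0  # m
    covered: bool = True

    def __post_init__(self) -> None:
        if len(self.monthly_temps) != 12:
            raise FeedDataError("monthly_temps must have 12 values")
        days = [d for d, _ in self.removal_schedule]
        if days != sorted(days):
            raise FeedDataError("removal_schedule must be sorted by day")
        for d, frac in self.removal_schedule:
            if not 0 < frac <= 1:
                raise FeedDataError(f"removal fraction {frac} not in (0, 1]")


# ---------------------------------------------------------------------------
# validation

def recomputed_rf(ing: FeedIngredient) -> float:
    """Residual fiber implied by the by-difference definition, clamped at 0."""
    return max(ing.om - ing.cp - ing.cf - ing.starch - ing.sugar, 0.0)


def validate_ingredient(ing: FeedIngredient) -> list[Finding]:
    """Check one ingredient against the composition invariants.

    Returns findings rather than raising: a deviation of the printed rf from
    the by-difference recomputation within the table-rounding tolerance is a
    warning, anything larger an error.
    """
    findings: list[Finding] = []
    for key in ("dm",) + NUTRIENTS:
        if ing.nutrient(key) < 0:
            findings.append(Finding("error", "nonnegative", f"{ing.name}: {key} < 0"))
    if ing.dm > 1000:
        findings.append(Finding("error", "dm_range", f"{ing.name}: dm > 1000 g/kg"))
    closure = ing.om + ing.ash
    if abs(closure - 1000.0) > ROUNDING_TOL:
        findings.append(
            Finding("error", "om_ash_closure",
                    f"{ing.name}: om + ash = {closure:.1f}, expected 1000 +/- {ROUNDING_TOL}")
        )
    dev = ing.rf - recomputed_rf(ing)
    if abs(dev) > ROUNDING_TOL:
        findings.append(
            Finding("error", "rf_consistency",
                    f"{ing.name}: rf {ing.rf:.0f} deviates {dev:+.0f} g/kg from the "
                    "by-difference value")
        )
    elif abs(dev) > 1e-9:
        findings.append(
            Finding("warning", "rf_rounding",
                    f"{ing.name}: rf differs from by-difference value by {dev:+.1f} g/kg "
                    "(printed-table rounding)")
        )
    if ing.indf > ing.rf:
        findings.append(Finding("error", "indf_le_rf", f"{ing.name}: indf > rf"))
    if ing.snsp > ing.nsp:
        findings.append(Finding("error", "snsp_le_nsp", f"{ing.name}: snsp > nsp"))
    return findings


# ---------------------------------------------------------------------------
# file I/O

def _require_columns(df: pd.DataFrame, columns: Sequence[str], path: Path | str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FeedDataError(f"{path}: missing column(s) {missing}")


def load_feedstuffs(path: Path | str) -> dict[str, FeedIngredient]:
    df = pd.read_csv(path)
    if df.empty:
        raise FeedDataError(f"{path}: no ingredients")
    _require_columns(df, FEEDSTUFF_COLUMNS, path)
    ingredients: dict[str, FeedIngredient] = {}
    for i, row in df.iterrows():
        ing = FeedIngredient(name=str(row["name"]),
                             **{k: float(row[k]) for k in ("dm",) + NUTRIENTS})
        if ing.name in ingredients:
            raise FeedDataError(f"{path}: duplicate ingredient {ing.name!r} (row {i})")
        errors = [f for f in validate_ingredient(ing) if f.is_error]
        if errors:
            raise FeedDataError(f"{path} row {i}: " + "; ".join(f.message for f in errors))
        ingredients[ing.name] = ing
    return ingredients


def load_digestibility(path: Path | str) -> dict[tuple[str, str], DigestibilityRecord]:
    df = pd.read_csv(path)
    _require_columns(df, DIGESTIBILITY_COLUMNS, path)
    records: dict[tuple[str, str], DigestibilityRecord] = {}
    for i, row in df.iterrows():
        rec = DigestibilityRecord(
            ingredient=str(row["ingredient"]),
            animal_class=str(row["animal_class"]),
            d_om=float(row["d_om"]), d_cp=float(row["d_cp"]),
            d_cf=float(row["d_cf"]), d_starch_sugar=float(row["d_starch_sugar"]),
        )
        if rec.animal_class not in ("growing", "sow"):
            raise FeedDataError(f"{path} row {i}: animal_class must be growing or sow")
        for key in ("d_om", "d_cp", "d_cf", "d_starch_sugar"):
            v = getattr(rec, key)
            if not 0.0 <= v <= 1.0:
                raise FeedDataError(f"{path} row {i}: {key} = {v} outside [0, 1]")
        records[(rec.ingredient, rec.animal_class)] = rec
    return records


def load_feed_table(feedstuffs: Path | str, digestibility: Path | str | None = None) -> FeedTable:
    """Load and validate a feed table.

    ``feedstuffs`` may be a directory holding ``feedstuffs.csv`` and
    ``digestibility.csv``, or the feedstuff CSV path with the digestibility
    CSV passed separately.
    """
    p = Path(feedstuffs)
    if p.is_dir():
        feedstuffs, digestibility = p / "feedstuffs.csv", p / "digestibility.csv"
    elif digestibility is None:
        raise FeedDataError("digestibility CSV required when not loading from a directory")
    table = FeedTable(load_feedstuffs(feedstuffs), load_digestibility(digestibility))
    table.validate()
    return table


def write_feed_table(table: FeedTable, directory: Path | str) -> None:
    """Write ``feedstuffs.csv`` and ``digestibility.csv`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([dataclasses.asdict(i) for i in table.ingredients.values()]).to_csv(
        directory / "feedstuffs.csv", index=False)
    pd.DataFrame([dataclasses.asdict(r) for r in table.digestibility.values()]).to_csv(
        directory / "digestibility.csv", index=False)


def load_diet(path: Path | str, *, name: str, fu_per_kg_asfed: float, category: str) -> DietSpec:
    """Read a single diet CSV (ingredient, proportion_asfed)."""
    df = pd.read_csv(path)
    _require_columns(df, DIET_COLUMNS, path)
    items = tuple((str(r["ingredient"]), float(r["proportion_asfed"])) for _, r in df.iterrows())
    return DietSpec(name=name, items=items, fu_per_kg_asfed=fu_per_kg_asfed, category=category)


def write_diet(diet: DietSpec, path: Path | str) -> None:
    pd.DataFrame(diet.items, columns=list(DIET_COLUMNS)).to_csv(path, index=False)


def load_temperature_series(path: Path | str) -> tuple[float, ...]:
    """Read a monthly slurry-temperature CSV with a ``temp_c`` column."""
    df = pd.read_csv(path)
    _require_columns(df, ("temp_c",), path)
    temps = tuple(float(v) for v in df["temp_c"])
    if len(temps) != 12:
        raise FeedDataError(f"{path}: expected 12 monthly values, got {len(temps)}")
    return temps


def _category_config_from_mapping(data: Mapping) -> PigCategoryConfig:
    intake = data["intake"]
    if "fu_stages" in intake:
        params: GrowingIntakeParams | SowIntakeParams = SowIntakeParams(
            fu_stages=tuple(float(v) for v in intake["fu_stages"]),
            feeding_days=float(intake["feeding_days"]),
        )
    else:
        params = GrowingIntakeParams(
            gain_per_cycle=float(intake["gain_per_cycle"]),
            feed_efficiency=float(intake["feed_efficiency"]),
            cycle_days=float(intake["cycle_days"]),
        )
    keys = ("category", "body_weight", "manure_temp_barn", "removal_interval",
            "floor_area", "pit_area", "cycle_period", "empty_days", "wash_water",
            "urine_per_dmi")
    return PigCategoryConfig(**{k: data[k] for k in keys}, intake_params=params)


def load_management(path: Path | str) -> tuple[dict[str, PigCategoryConfig], StorageConfig]:
    """Read the management YAML: per-category configs plus the storage tank."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    categories = {k: _category_config_from_mapping(v) for k, v in data["categories"].items()}
    s = data["storage"]
    storage = StorageConfig(
        monthly_temps=tuple(float(v) for v in s["monthly_temps"]),
        removal_schedule=tuple((int(d), float(f)) for d, f in s["removal_schedule"]),
        height=float(s.get("height", 5.5)),
        diameter=float(s.get("diameter", 36.0)),
        covered=bool(s.get("covered", True)),
    )
    return categories, storage
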