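"""Whole-diet nutrient concentrations from ingredient inclusions.

A diet is a list of as-fed inclusion proportions.  Nutrient concentrations
are expressed per kg DM, so mixing happens on a DM basis: the DM proportion
of ingredient j is a_j = incl_j * dm_j / sum_k incl_k * dm_k, and every
nutrient concentration of the diet is the a-weighted sum of the ingredient
concentrations.  The diet's dry matter itself (g/kg as-fed) is the as-fed
weighted sum of ingredient DM values.

Residual fiber can be formed two ways: by mixing the ingredients' tabulated
rf values (canonical here) or by the by-difference rule on the mixed om, cp,
cf, starch and sugar.  The two disagree only through printed-table rounding;
``DietComposition.rf_by_difference`` exposes the second route.
"""

from __future__ import annotations

from dataclasses import dataclass

from .feed_data import DietSpec, FeedDataError, FeedTable, NUTRIENTS


@dataclass(frozen=True)
class DietComposition:
    name: str
    dm: float  # g/kg as-fed
    om: float  # all nutrients g/kg DM
    cp: float
    cf: float
    starch: float
    sugar: float
    rf: float
    indf: float
    nsp: float
    snsp: float
    ash: float
    dm_proportions: tuple[tuple[str, float], ...]  # kg DM ingredient / kg DM diet

    def nutrient(self, key: str) -> float:
        return getattr(self, key)

    @property
    def rf_by_difference(self) -> float:
        """Residual fiber recomputed from the mixed proximate fractions."""
        return residual_fiber(self.om, self.cp, self.cf, self.starch, self.sugar)


def residual_fiber(om: float, cp: float, cf: float, starch: float, sugar: float) -> float:
    """By-difference residual fiber (g/kg DM): om - cp - cf - starch - sugar.

    A negative result signals inconsistent proximate inputs and raises.
    """
    for v, label in ((om, "om"), (cp, "cp"), (cf, "cf"), (starch, "starch"), (sugar, "sugar")):
        if v < 0:
            raise FeedDataError(f"residual_fiber: {label} < 0")
    rf = om - cp - cf - starch - sugar
    if rf < 0:
        raise FeedDataError(f"residual_fiber: negative result {rf:.1f} g/kg DM")
    return rf


def asfed_to_dm_proportions(diet: DietSpec, table: FeedTable) -> tuple[tuple[str, float], ...]:
    """Convert as-fed inclusion proportions to DM proportions (sum exactly 1)."""
    weights = [(name, incl * table.ingredient(name).dm) for name, incl in diet.items]
    denom = sum(w for _, w in weights)
    if denom <= 0:
        raise FeedDataError(f"diet {diet.name!r}: zero dry matter")
    return tuple((name, w / denom) for name, w in weights)


def diet_dry_matter(diet: DietSpec, table: FeedTable) -> float:
    """Diet DM in g/kg as-fed: the as-fed-weighted mean of ingredient DM."""
    return sum(incl * table.ingredient(name).dm for name, incl in diet.items) / sum(
        incl for _, incl in diet.items)


def mix_composition(diet: DietSpec, table: FeedTable) -> DietComposition:
    """Mix ingredient compositions into the whole-diet composition."""
    props = asfed_to_dm_proportions(diet, table)
    values = {
        key: sum(a * table.ingredient(name).nutrient(key) for name, a in props)
        for key in NUTRIENTS
    }
    return DietComposition(name=diet.name, dm=diet_dry_matter(diet, table),
                           dm_proportions=props, **values)


def substitute(diet: DietSpec, remove: str, add: str, points: float,
               *, fu_per_kg_asfed: float, name: str | None = None) -> DietSpec:
    """Replace ``points`` (as-fed kg/kg) of one ingredient by another.

    Emulates the study design where a slice of wheat (or barley) in the
    average diet is swapped for a fiber source; the substituted diet carries
    its own energy density.
    """
    items = dict(diet.items)
    if remove not in items:
        raise FeedDataError(f"diet {diet.name!r} has no ingredient {remove!r}")
    if items[remove] < points:
        raise FeedDataError(
            f"diet {diet.name!r}: cannot remove {points} of {remove!r} "
            f"(inclusion {items[remove]})")
    items[remove] -= points
    items[add] = items.get(add, 0.0) + points
    return DietSpec(name=name or f"{diet.name}_{add}", category=diet.category,
                    fu_per_kg_asfed=fu_per_kg_asfed,
                    items=tuple((k, v) for k, v in items.items() if v > 0))
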