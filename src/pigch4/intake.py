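"""Daily feed, DM and nutrient intake per pig category.

Growing pigs (weaned, grower-finisher) eat to a batch-cycle gain target:
feed = gain x feed-efficiency / energy-density / cycle-days.  Sows eat a
fixed yearly feed-unit budget spread over their feeding days.  The sow
budget is printed per year but consumed only on feeding days (285/year for
gestating, 80/year for lactating sows), so the daily intake divides by
feeding days, not 365; this is the only reading that reproduces the
reported daily intakes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .diet_composition import DietComposition
from .feed_data import (FeedDataError, GrowingIntakeParams, PigCategoryConfig,
                        SowIntakeParams, NUTRIENTS)


@dataclass(frozen=True)
class IntakeResult:
    feed_asfed: float  # g/day
    dmi: float  # g DM/day
    nutrients: dict[str, float]  # g/day per nutrient key

    def nutrient(self, key: str) -> float:
        return self.nutrients[key]


def growing_feed_intake(gain_per_cycle: float, feed_efficiency: float,
                        fu_per_kg: float, cycle_days: float) -> float:
    """As-fed intake (kg/day) of a growing pig from its batch-cycle targets."""
    for v, label in ((gain_per_cycle, "gain_per_cycle"), (fu_per_kg, "fu_per_kg"),
                     (cycle_days, "cycle_days")):
        if v <= 0:
            raise FeedDataError(f"growing_feed_intake: {label} must be positive")
    if feed_efficiency < 0:
        raise FeedDataError("growing_feed_intake: negative feed_efficiency")
    return gain_per_cycle * feed_efficiency / fu_per_kg / cycle_days


def sow_feed_intake(fu_stages: tuple[float, ...] | list[float], feeding_days: float,
                    fu_per_kg: float) -> float:
    """As-fed intake (kg/day) of a sow from its yearly feed-unit stages."""
    if not fu_stages:
        raise FeedDataError("sow_feed_intake: empty stage list")
    if not 0 < feeding_days <= 365:
        raise FeedDataError("sow_feed_intake: feeding_days must be in (0, 365]")
    if fu_per_kg <= 0:
        raise FeedDataError("sow_feed_intake: fu_per_kg must be positive")
    return sum(fu_stages) / feeding_days / fu_per_kg


def daily_intake(config: PigCategoryConfig, composition: DietComposition,
                 fu_per_kg: float) -> IntakeResult:
    """Daily feed, DM and per-nutrient intake for one category on one diet."""
    p = config.intake_params
    if isinstance(p, GrowingIntakeParams):
        feed_kg = growing_feed_intake(p.gain_per_cycle, p.feed_efficiency,
                                      fu_per_kg, p.cycle_days)
    elif isinstance(p, SowIntakeParams):
        feed_kg = sow_feed_intake(p.fu_stages, p.feeding_days, fu_per_kg)
    else:  # pragma: no cover - config construction forbids this
        raise FeedDataError("unknown intake parameter type")
    feed_asfed = feed_kg * 1000.0
    dmi = feed_asfed * composition.dm / 1000.0
    nutrients = {key: dmi * composition.nutrient(key) / 1000.0 for key in NUTRIENTS}
    return IntakeResult(feed_asfed=feed_asfed, dmi=dmi, nutrients=nutrients)
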