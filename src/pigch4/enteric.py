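"""Enteric methane prediction from diet and intake.

Two empirical regressions, one per animal class:

* growing pigs (weaned, grower-finisher), driven by soluble NSP intake and
  body weight:  CH4 (L/d) = -0.62 + 0.032 x sNSP intake (g/d) + 0.025 x BW (kg)
* sows, driven by fermentable-fiber intake:
  CH4 (L/d) = 0.440 + 0.0206 x FF intake (g/d)

Litres are converted to grams with a configurable gas density; the default
0.716 g/L is CH4 at 0 degC and 1 atm (0.654 g/L at 25 degC is the common
alternative).  Annualization multiplies by 365 days without an occupancy
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .feed_data import FeedDataError

CH4_DENSITY_STP = 0.716  # g/L at 0 degC, 1 atm
CH4_DENSITY_25C = 0.654  # g/L at 25 degC, 1 atm


@dataclass(frozen=True)
class EntericResult:
    ch4_l_d: float
    ch4_g_d: float
    ch4_g_per_kg_feed: float
    ch4_kg_yr: float  # kg/year/animal place
    gas_density: float  # g/L used for the conversion


def enteric_ch4_growing(snsp_intake: float, body_weight: float) -> float:
    """Enteric CH4 (L/day) for weaned and grower-finisher pigs."""
    if snsp_intake < 0 or body_weight < 0:
        raise FeedDataError("enteric_ch4_growing: negative input")
    value = -0.62 + 0.032 * snsp_intake + 0.025 * body_weight
    if value < 0:
        warnings.warn("enteric CH4 prediction below zero; clamped", stacklevel=2)
        return 0.0
    return value


def enteric_ch4_sow(ff_intake: float) -> float:
    """Enteric CH4 (L/day) for gestating and lactating sows."""
    if ff_intake < 0:
        raise FeedDataError("enteric_ch4_sow: negative fermentable-fiber intake")
    return 0.440 + 0.0206 * ff_intake


def litres_to_grams(l_d: float, density: float = CH4_DENSITY_STP) -> float:
    if density <= 0:
        raise FeedDataError("litres_to_grams: density must be positive")
    return l_d * density


def per_kg_feed(g_d: float, feed_asfed: float) -> float:
    """CH4 per kg as-fed feed intake (g/kg) from g/day and g feed/day."""
    if feed_asfed <= 0:
        raise FeedDataError("per_kg_feed: feed intake must be positive")
    return g_d / (feed_asfed / 1000.0)


def annualize_enteric(g_d: float) -> float:
    """kg CH4 per year per animal place from g/day (365 days, no occupancy)."""
    if g_d < 0:
        raise FeedDataError("annualize_enteric: negative emission")
    return g_d * 365.0 / 1000.0


def enteric_emission(category: str, *, snsp_intake: float = 0.0,
                     ff_intake: float = 0.0, body_weight: float = 0.0,
                     feed_asfed: float, density: float = CH4_DENSITY_STP) -> EntericResult:
    """Full enteric result for one category; picks the class regression."""
    if category in ("weaned", "grower_finisher"):
        l_d = enteric_ch4_growing(snsp_intake, body_weight)
    elif category in ("gestating_sow", "lactating_sow"):
        l_d = enteric_ch4_sow(ff_intake)
    else:
        raise FeedDataError(f"unknown category {category!r}")
    g_d = litres_to_grams(l_d, density)
    return EntericResult(ch4_l_d=l_d, ch4_g_d=g_d,
                         ch4_g_per_kg_feed=per_kg_feed(g_d, feed_asfed),
                         ch4_kg_yr=annualize_enteric(g_d), gas_density=density)
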