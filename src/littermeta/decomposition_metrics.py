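"""Unit conversions from reported decomposition quantities to analysis variables.

Source studies report decomposition as a mass-loss percentage, a mass-remaining
percentage, or a single-pool negative-exponential decay constant k; nutrient
dynamics are reported as concentrations at harvest. Everything is normalised
here to mass loss (%), relative nutrient release (% of the initial amount;
negative = net immobilization), and absolute release (mg per g initial litter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "NutrientMode",
    "NutrientRelease",
    "mass_loss_from_k",
    "mass_loss_from_remaining",
    "nutrient_release",
]


class NutrientMode(str, Enum):
    """How the remaining nutrient fraction is computed.

    ``amount_based`` (default) multiplies the concentration ratio by the mass
    remaining fraction — the standard litterbag nutrient budget. The
    ``concentration_based`` mode uses the bare concentration ratio
    conc_t / conc_0, for sources that define release that way.
    """

    amount_based = "amount_based"
    concentration_based = "concentration_based"


@dataclass(frozen=True)
class NutrientRelease:
    nutrient: str  # "N" or "P"
    remaining_fraction: float  # fraction of initial nutrient amount remaining
    relative_release: float  # % of initial amount released; negative = immobilization
    absolute_release: float  # mg released per g initial litter
    immobilized: bool


def mass_loss_from_k(k: float, t: float) -> float:
    """Mass loss (%) after *t* years under single-pool exponential decay with
    constant *k* (per year): ``(1 - exp(-k t)) * 100``."""
    if k < 0 or t < 0:
        raise ValueError(f"k and t must be >= 0, got k={k}, t={t}")
    return (1.0 - math.exp(-k * t)) * 100.0


def mass_loss_from_remaining(remaining: float) -> float:
    """Convert mass remaining (%) to mass loss (%)."""
    if not 0.0 <= remaining <= 100.0:
        raise ValueError(f"remaining must be in [0, 100], got {remaining}")
    return 100.0 - remaining


def nutrient_release(
    conc_0: float,
    conc_t: float,
    mass_remaining_frac: float,
    mode: NutrientMode | str = NutrientMode.amount_based,
    nutrient: str = "N",
) -> NutrientRelease:
    """Remaining fraction and release of a nutrient at one harvest.

    Parameters
    ----------
    conc_0, conc_t
        Initial and at-harvest nutrient concentration, mg per g litter.
    mass_remaining_frac
        Fraction of initial dry mass remaining at the harvest, in (0, 1].
    mode
        See :class:`NutrientMode`.

    A remaining fraction above one means the litter holds more of the
    nutrient than it started with: net immobilization.
    """
    if conc_0 <= 0:
        raise ValueError(f"conc_0 must be > 0, got {conc_0}")
    if conc_t < 0:
        raise ValueError(f"conc_t must be >= 0, got {conc_t}")
    if not 0.0 < mass_remaining_frac <= 1.0:
        raise ValueError(
            f"mass_remaining_frac must be in (0, 1], got {mass_remaining_frac}")
    mode = NutrientMode(mode)
    if mode is NutrientMode.amount_based:
        remaining = (conc_t * mass_remaining_frac) / conc_0
    else:
        remaining = conc_t / conc_0
    return NutrientRelease(
        nutrient=nutrient,
        remaining_fraction=remaining,
        relative_release=(1.0 - remaining) * 100.0,
        absolute_release=conc_0 * (1.0 - remaining),
        immobilized=remaining > 1.0,
    )
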