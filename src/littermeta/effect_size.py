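"""Log response ratio effect sizes and their sampling variances.

The effect size for one paired observation is

    lnRR = ln(X̄_e) - ln(X̄_c)

with X̄_e the observed mixture mean and X̄_c the additive-null expectation;
positive values mean the mixture decomposes (or releases) faster than
predicted from its component species (synergistic), negative slower
(antagonistic). Its sampling variance is

    v = s_e^2 / (N_e X̄_e^2) + s_c^2 / (N_c X̄_c^2),

the delta-method variance of a log ratio of independent group means.

Non-positive means — possible for nutrient release under net immobilization —
cannot enter a log ratio; such pairs are excluded with a logged reason and
counted in the run report, never silently dropped or offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .mixture_null import PairedObservation, Response
from .records_io import GroupLabels

__all__ = [
    "EffectSize",
    "ln_response_ratio",
    "lnrr_variance",
    "percent_effect",
    "compute_effects",
    "effects_to_frame",
]


@dataclass(frozen=True)
class EffectSize:
    """One lnRR with its sampling variance; the atomic meta-analysis unit."""

    lnrr: float
    variance: float
    response: Response
    study_id: str
    treatment_id: str
    harvest_index: int
    is_final_harvest: bool
    expected_mass_loss: float  # % additive-null mass loss, carried for staging
    labels: GroupLabels


def ln_response_ratio(observed_mean: float, expected_mean: float) -> float:
    """lnRR = ln(observed) - ln(expected); both means must be positive."""
    if observed_mean <= 0 or expected_mean <= 0:
        raise ValueError(
            f"means must be > 0 for a log ratio, got "
            f"({observed_mean}, {expected_mean})")
    return math.log(observed_mean) - math.log(expected_mean)


def lnrr_variance(
    sd_e: float, n_e: int, mean_e: float,
    sd_c: float, n_c: int, mean_c: float,
) -> float:
    """Sampling variance of lnRR from group summaries (treatment = observed
    mixture, control = additive null)."""
    if mean_e <= 0 or mean_c <= 0:
        raise ValueError("means must be > 0")
    if sd_e < 0 or sd_c < 0:
        raise ValueError("sds must be >= 0")
    if n_e < 1 or n_c < 1:
        raise ValueError("ns must be >= 1")
    v = sd_e**2 / (n_e * mean_e**2) + sd_c**2 / (n_c * mean_c**2)
    if v == 0.0:
        raise ValueError("degenerate pair: zero variance on both sides")
    return v


def percent_effect(lnrr: float) -> float:
    """Back-transform lnRR to the percent scale: (e^lnRR - 1) * 100."""
    return (math.exp(lnrr) - 1.0) * 100.0


def compute_effects(
    pairs: Sequence[PairedObservation],
) -> tuple[list[EffectSize], list[dict]]:
    """Turn paired observations into effect sizes, excluding (with reasons)
    pairs whose means cannot enter a log ratio or whose variance is
    degenerate."""
    effects: list[EffectSize] = []
    exclusions: list[dict] = []
    for p in pairs:
        if p.observed_mean <= 0 or p.expected_mean <= 0:
            exclusions.append({
                "treatment_id": p.treatment_id, "harvest_index": p.harvest_index,
                "response": p.response.value,
                "reason": "non-positive mean (net immobilization or zero loss); "
                          "log ratio undefined"})
            continue
        try:
            v = lnrr_variance(p.observed_sd, p.observed_n, p.observed_mean,
                              p.expected_sd, p.expected_n, p.expected_mean)
        except ValueError as err:
            exclusions.append({
                "treatment_id": p.treatment_id, "harvest_index": p.harvest_index,
                "response": p.response.value, "reason": str(err)})
            continue
        effects.append(EffectSize(
            lnrr=ln_response_ratio(p.observed_mean, p.expected_mean),
            variance=v,
            response=p.response,
            study_id=p.study_id,
            treatment_id=p.treatment_id,
            harvest_index=p.harvest_index,
            is_final_harvest=p.is_final_harvest,
            expected_mass_loss=p.expected_mass_loss,
            labels=p.labels,
        ))
    return effects, exclusions


def effects_to_frame(effects: Sequence[EffectSize]) -> pd.DataFrame:
    rows = []
    for e in effects:
        lab = e.labels
        rows.append({
            "study_id": e.study_id, "treatment_id": e.treatment_id,
            "response": e.response.value, "harvest_index": e.harvest_index,
            "is_final_harvest": e.is_final_harvest,
            "lnrr": e.lnrr, "variance": e.variance,
            "percent_effect": percent_effect(e.lnrr),
            "expected_mass_loss": e.expected_mass_loss,
            "biome": lab.biome.value, "richness": lab.richness,
            "evenness": lab.evenness.value, "forest_type": lab.forest_type.value,
            "mesh_class": lab.mesh_class.value,
            "functional_composition": (lab.functional_composition.value
                                       if lab.functional_composition else None),
            "stand_structure": (lab.stand_structure.value
                                if lab.stand_structure else None),
        })
    return pd.DataFrame(rows)
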