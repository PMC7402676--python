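"""Additive-null expectations for mixture observations.

For every mixture treatment x harvest x response, the expected ("control")
value is built from the component species' single-species observations at the
same sampling occasion: the mass-proportion-weighted mean for mass loss, and a
nutrient-mass-weighted mean for N and P release. Observed (mixture) and
expected summaries are paired into :class:`PairedObservation` records, the
input of the effect-size stage.

Component matching is by ``harvest_index`` (same sampling occasion), never by
interpolating harvest times. A pair whose components are missing at a harvest
is skipped with a logged reason — never silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import math

import pandas as pd

from .decomposition_metrics import NutrientMode, nutrient_release
from .records_io import Dataset, GroupLabels, build_group_labels

__all__ = [
    "Response",
    "NullWeights",
    "PairedObservation",
    "expected_value",
    "expected_dispersion",
    "build_pairs",
    "pairs_to_frame",
]


class Response(str, Enum):
    mass_loss = "mass_loss"
    N_release = "N_release"
    P_release = "P_release"


class NullWeights(str, Enum):
    """Weighting of component release values in the nutrient additive null.

    ``nutrient_mass`` (default) weights component i by its share of the
    mixture's initial nutrient pool, p_i * conc0_i / sum_j p_j * conc0_j — a
    nutrient rather than dry-mass budget. ``dry_mass`` falls back to the bare
    mass proportions p_i.
    """

    nutrient_mass = "nutrient_mass"
    dry_mass = "dry_mass"


_RESPONSE_NUTRIENT = {Response.N_release: "N", Response.P_release: "P"}


@dataclass(frozen=True)
class PairedObservation:
    """Observed (mixture) vs expected (additive null) summary pair for one
    response variable at one harvest."""

    study_id: str
    treatment_id: str
    response: Response
    harvest_time: float  # days
    harvest_index: int
    is_final_harvest: bool
    observed_mean: float
    observed_sd: float
    observed_n: int
    expected_mean: float
    expected_sd: float
    expected_n: int
    #: additive-null mass loss (%) at this harvest; drives stage binning for
    #: every response, including the nutrients
    expected_mass_loss: float
    labels: GroupLabels


def expected_value(component_means: Sequence[float], proportions: Sequence[float]) -> float:
    """Mass-proportion-weighted additive null: sum_i p_i * x_i."""
    if len(component_means) != len(proportions):
        raise ValueError("component_means and proportions differ in length")
    if len(component_means) < 2:
        raise ValueError("need >= 2 components")
    total = math.fsum(proportions)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {total}")
    return math.fsum(p * x for p, x in zip(proportions, component_means))


def expected_dispersion(
    component_sds: Sequence[float],
    component_ns: Sequence[int],
    proportions: Sequence[float],
) -> tuple[float, int]:
    """Dispersion of the additive null under component independence.

    Returns ``(sqrt(sum_i p_i^2 sd_i^2), min_i n_i)``. The minimum replicate
    count is the conservative choice for the composite sample size.
    """
    if not (len(component_sds) == len(component_ns) == len(proportions)):
        raise ValueError("length mismatch among sds, ns, proportions")
    if any(sd < 0 for sd in component_sds):
        raise ValueError("sds must be >= 0")
    if any(n < 1 for n in component_ns):
        raise ValueError("ns must be >= 1")
    var = math.fsum((p * sd) ** 2 for p, sd in zip(proportions, component_sds))
    return math.sqrt(var), int(min(component_ns))


def _release_stats(c0: float, conc: float, conc_sd: float, mass_loss: float,
                   mode: NutrientMode, nutrient: str) -> tuple[float, float]:
    """Relative release (%) and its SD for one observation."""
    m = (100.0 - mass_loss) / 100.0
    rel = nutrient_release(c0, conc, m, mode=mode, nutrient=nutrient).relative_release
    scale = m if NutrientMode(mode) is NutrientMode.amount_based else 1.0
    sd = (conc_sd * scale / c0) * 100.0
    return rel, sd


def build_pairs(
    ds: Dataset,
    nutrient_mode: NutrientMode | str = NutrientMode.amount_based,
    null_weights: NullWeights | str = NullWeights.nutrient_mass,
) -> tuple[list[PairedObservation], list[dict]]:
    """Pair every mixture observation with its additive-null expectation.

    Returns the pairs plus an exclusion log (one dict per skipped
    mixture x harvest x response, with a reason).
    """
    nutrient_mode = NutrientMode(nutrient_mode)
    null_weights = NullWeights(null_weights)
    labels, label_log = build_group_labels(ds)
    exclusions: list[dict] = [
        {"treatment_id": e["treatment_id"], "harvest_index": None,
         "response": None, "reason": e["reason"]}
        for e in label_log
    ]
    pairs: list[PairedObservation] = []
    obs = ds.observations
    if obs.empty:
        return pairs, exclusions
    records = obs.to_dict("records")
    singles: dict[tuple, dict] = {}
    mix_by_tid: dict[str, list[dict]] = {}
    for r in records:
        if r["is_mixture"]:
            mix_by_tid.setdefault(r["treatment_id"], []).append(r)
        else:
            singles[(r["study_id"], r["species_id"], r["harvest_index"])] = r
    comp_by_tid: dict[str, list[tuple[str, float]]] = {}
    for r in ds.compositions.to_dict("records"):
        comp_by_tid.setdefault(r["treatment_id"], []).append(
            (r["species_id"], float(r["proportion"])))
    species_traits = {r["species_id"]: r for r in ds.species.to_dict("records")}

    for tid in ds.mixture_treatments(selected_only=True):
        components = comp_by_tid[tid]
        species_ids = [s for s, _ in components]
        props = [p for _, p in components]
        mix_rows = sorted(mix_by_tid[tid], key=lambda r: r["harvest_index"])
        study_id = mix_rows[0]["study_id"]
        for mrow in mix_rows:
            h = int(mrow["harvest_index"])
            comp_rows = []
            missing = None
            for sid in species_ids:
                key = (study_id, sid, h)
                if key not in singles:
                    missing = sid
                    break
                comp_rows.append(singles[key])
            if missing is not None:
                exclusions.append({
                    "treatment_id": tid, "harvest_index": h, "response": None,
                    "reason": f"missing single-species observation for {missing!r} "
                              f"at harvest {h}"})
                continue

            exp_ml = expected_value([float(r["mass_loss"]) for r in comp_rows], props)
            exp_sd, exp_n = expected_dispersion(
                [float(r["mass_loss_sd"]) for r in comp_rows],
                [int(r["n_reps"]) for r in comp_rows], props)
            common = dict(
                study_id=study_id, treatment_id=tid,
                harvest_time=float(mrow["harvest_time"]), harvest_index=h,
                is_final_harvest=bool(mrow["is_final_harvest"]),
                expected_mass_loss=exp_ml, labels=labels[tid],
            )
            pairs.append(PairedObservation(
                response=Response.mass_loss,
                observed_mean=float(mrow["mass_loss"]),
                observed_sd=float(mrow["mass_loss_sd"]),
                observed_n=int(mrow["n_reps"]),
                expected_mean=exp_ml, expected_sd=exp_sd, expected_n=exp_n,
                **common))

            for resp, nut in _RESPONSE_NUTRIENT.items():
                ccol, scol = f"conc_{nut}", f"conc_{nut}_sd"
                if pd.isna(mrow[ccol]):
                    continue  # nutrient simply not measured for this mixture
                c0s = []
                for sid in species_ids:
                    v = species_traits.get(sid, {}).get(nut, float("nan"))
                    c0s.append(float(v) if pd.notna(v) else float("nan"))
                if any(math.isnan(c) for c in c0s):
                    exclusions.append({
                        "treatment_id": tid, "harvest_index": h, "response": resp.value,
                        "reason": f"initial {nut} concentration missing for a component"})
                    continue
                if any(pd.isna(r[ccol]) for r in comp_rows):
                    exclusions.append({
                        "treatment_id": tid, "harvest_index": h, "response": resp.value,
                        "reason": f"{nut} concentration missing for a component observation"})
                    continue
                if pd.isna(mrow[scol]) or any(pd.isna(r[scol]) for r in comp_rows):
                    exclusions.append({
                        "treatment_id": tid, "harvest_index": h, "response": resp.value,
                        "reason": f"{nut} concentration dispersion missing"})
                    continue
                c0_mix = math.fsum(p * c for p, c in zip(props, c0s))
                obs_rel, obs_sd = _release_stats(
                    c0_mix, float(mrow[ccol]), float(mrow[scol]),
                    float(mrow["mass_loss"]), nutrient_mode, nut)
                rels, sds = [], []
                for r, c0 in zip(comp_rows, c0s):
                    rel, sd = _release_stats(
                        c0, float(r[ccol]), float(r[scol]), float(r["mass_loss"]),
                        nutrient_mode, nut)
                    rels.append(rel)
                    sds.append(sd)
                if null_weights is NullWeights.nutrient_mass:
                    wsum = math.fsum(p * c for p, c in zip(props, c0s))
                    w = [p * c / wsum for p, c in zip(props, c0s)]
                else:
                    w = props
                exp_rel = math.fsum(wi * r for wi, r in zip(w, rels))
                exp_rel_sd = math.sqrt(math.fsum((wi * s) ** 2 for wi, s in zip(w, sds)))
                pairs.append(PairedObservation(
                    response=resp,
                    observed_mean=obs_rel, observed_sd=obs_sd,
                    observed_n=int(mrow["n_reps"]),
                    expected_mean=exp_rel, expected_sd=exp_rel_sd,
                    expected_n=min(int(r["n_reps"]) for r in comp_rows),
                    **common))
    return pairs, exclusions


def pairs_to_frame(pairs: Sequence[PairedObservation]) -> pd.DataFrame:
    """Flatten pairs (labels included) into a DataFrame for audit output."""
    rows = []
    for p in pairs:
        lab = p.labels
        rows.append({
            "study_id": p.study_id, "treatment_id": p.treatment_id,
            "response": p.response.value, "harvest_time": p.harvest_time,
            "harvest_index": p.harvest_index,
            "is_final_harvest": p.is_final_harvest,
            "observed_mean": p.observed_mean, "observed_sd": p.observed_sd,
            "observed_n": p.observed_n, "expected_mean": p.expected_mean,
            "expected_sd": p.expected_sd, "expected_n": p.expected_n,
            "expected_mass_loss": p.expected_mass_loss,
            "biome": lab.biome.value, "richness": lab.richness,
            "evenness": lab.evenness.value,
            "forest_type": lab.forest_type.value,
            "mesh_class": lab.mesh_class.value,
            "functional_composition": (lab.functional_composition.value
                                       if lab.functional_composition else None),
            "stand_structure": (lab.stand_structure.value
                                if lab.stand_structure else None),
        })
    return pd.DataFrame(rows)
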