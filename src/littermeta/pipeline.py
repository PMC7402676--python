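"""End-to-end orchestration: dataset -> pairs -> effects -> meta-analyses ->
staging -> regressions -> run report.

The analysis convention throughout: categorical meta-analyses (overall,
per-biome, richness, evenness, functional composition, forest type x stand
structure, mesh class) use final-harvest observations only; decomposition-
stage binning uses all harvests; the trait-divergence regressions use
study-averaged effects inside the 10-40% null-mass-loss window; climate
regressions use one point per final-harvest paired observation. Subgroups
with fewer than ``min_group_k`` effects are reported flagged (sample size too
low for inference) without a CI. No multiplicity correction is applied across
subgroups — inference is per-CI, and deliberately so.

Every input observation is accounted for exactly once per response: analyzed,
or excluded with a reason in the report's counts section.
"""

from __future__ import annotations

import json
from collections import Counter
from pathlib import Path
import numpy as np
import pandas as pd
from pydantic import BaseModel
from scipy import stats as sp_stats

from . import divergence as div
from .decomposition_metrics import NutrientMode, nutrient_release
from .effect_size import EffectSize, compute_effects, effects_to_frame
from .meta_model import SubgroupResult, meta_analysis, subgroup_analysis
from .mixture_null import Response, build_pairs, pairs_to_frame
from .records_io import Dataset
from .staging import staged_meta, staging_table

__all__ = ["RunConfig", "run", "write_report", "nutrient_summary"]

_RESPONSES = (Response.mass_loss, Response.N_release, Response.P_release)


class RunConfig(BaseModel):
    """Analysis configuration (echoed into the report for provenance)."""

    seed: int = 0
    bootstrap_reps: int = 4999
    ci_method: str = "bias_corrected"  # or "percentile"
    tau_estimator: str = "DL"  # or "REML"
    nutrient_mode: str = "amount_based"  # or "concentration_based"
    null_weights: str = "nutrient_mass"  # or "dry_mass"
    staging_collapse_per_study: bool = False
    #: subgroups below this effect count are flagged, no CI
    min_group_k: int = 3
    divergence_window: tuple[float, float] = (10.0, 40.0)
    weighted_regressions: bool = False


def _subgroup(effects: list[EffectSize], label_fn, cfg: RunConfig,
              rng: np.random.Generator) -> SubgroupResult | None:
    labelled = [(e, label_fn(e)) for e in effects]
    labelled = [(e, lab) for e, lab in labelled if lab is not None]
    if not labelled:
        return None
    evs = [e for e, _ in labelled]
    labs = [lab for _, lab in labelled]
    return subgroup_analysis(evs, labs, reps=cfg.bootstrap_reps, seed=rng,
                             method=cfg.ci_method, min_k_ci=cfg.min_group_k)


def nutrient_summary(
    ds: Dataset,
    nutrient_mode: NutrientMode | str = NutrientMode.amount_based,
    final_only: bool = True,
) -> dict:
    """Mixture vs single-species mean relative (%) and absolute (mg g^-1)
    nutrient release, with a Welch two-sample test on the observation-level
    values. Net-immobilization observations enter with negative release."""
    mode = NutrientMode(nutrient_mode)
    trait_by_sid = {r["species_id"]: r for r in ds.species.to_dict("records")}
    comp_by_tid: dict[str, list[tuple[str, float]]] = {}
    for r in ds.compositions.to_dict("records"):
        comp_by_tid.setdefault(r["treatment_id"], []).append(
            (r["species_id"], float(r["proportion"])))
    selected = set(ds.studies.loc[ds.studies["selected"], "study_id"])
    out: dict = {}
    for nut in ("N", "P"):
        rel = {"mixture": [], "single": []}
        absr = {"mixture": [], "single": []}
        for r in ds.observations.to_dict("records"):
            if r["study_id"] not in selected:
                continue
            if final_only and not r["is_final_harvest"]:
                continue
            if pd.isna(r[f"conc_{nut}"]):
                continue
            if r["is_mixture"]:
                comps = comp_by_tid.get(r["treatment_id"])
                if comps is None:
                    continue
                c0s = [trait_by_sid[s].get(nut, float("nan")) for s, _ in comps]
                c0s = [float(c) if pd.notna(c) else float("nan") for c in c0s]
                if any(np.isnan(c) for c in c0s):
                    continue
                c0 = sum(p * c for (_, p), c in zip(comps, c0s))
                group = "mixture"
            else:
                c0 = trait_by_sid[r["species_id"]].get(nut, float("nan"))
                if pd.isna(c0):
                    continue
                c0 = float(c0)
                group = "single"
            m_frac = max((100.0 - float(r["mass_loss"])) / 100.0, 1e-6)
            nr = nutrient_release(c0, float(r[f"conc_{nut}"]), m_frac,
                                  mode=mode, nutrient=nut)
            rel[group].append(nr.relative_release)
            absr[group].append(nr.absolute_release)
        entry: dict = {}
        for kind, vals in (("relative", rel), ("absolute", absr)):
            mix, sing = vals["mixture"], vals["single"]
            if not mix or not sing:
                entry[kind] = {"mixture_mean": float(np.mean(mix)) if mix else None,
                               "single_mean": float(np.mean(sing)) if sing else None,
                               "n_mixture": len(mix), "n_single": len(sing),
                               "welch_p": None}
                continue
            if len(mix) >= 2 and len(sing) >= 2:
                p = float(sp_stats.ttest_ind(mix, sing, equal_var=False).pvalue)
            else:
                p = None
            entry[kind] = {"mixture_mean": float(np.mean(mix)),
                           "single_mean": float(np.mean(sing)),
                           "n_mixture": len(mix), "n_single": len(sing),
                           "welch_p": p}
        out[nut] = entry
    return out


def _forest_structure_label(e: EffectSize) -> str | None:
    if e.labels.stand_structure is None:
        return None
    return f"{e.labels.forest_type.value}:{e.labels.stand_structure.value}"


def run(ds: Dataset, config: RunConfig | None = None) -> dict:
    """Execute the full analysis; deterministic given ``config.seed``."""
    cfg = config or RunConfig()
    rng = np.random.default_rng(cfg.seed)

    pairs, pair_exclusions = build_pairs(
        ds, nutrient_mode=cfg.nutrient_mode, null_weights=cfg.null_weights)
    final_pairs = [p for p in pairs if p.is_final_harvest]

    counts: dict = {
        "mixture_observations": int(
            ds.observations.loc[ds.observations["is_mixture"]].shape[0])
        if not ds.observations.empty else 0,
        "pairs_built": dict(Counter(p.response.value for p in pairs)),
        "pairs_built_final_harvest": dict(
            Counter(p.response.value for p in final_pairs)),
        "pair_exclusions": dict(Counter(
            str(e["reason"]).split(";")[0] for e in pair_exclusions)),
    }

    overall: dict = {}
    per_biome: dict = {}
    effects_final: dict[Response, list[EffectSize]] = {}
    effect_excl_counts: dict = {}
    for resp in _RESPONSES:
        evs, excl = compute_effects([p for p in final_pairs if p.response is resp])
        effects_final[resp] = evs
        effect_excl_counts[resp.value] = dict(Counter(
            str(e["reason"]).split(";")[0] for e in excl))
        if evs:
            overall[resp.value] = meta_analysis(
                evs, reps=cfg.bootstrap_reps, seed=rng, method=cfg.ci_method,
                tau_estimator=cfg.tau_estimator).to_dict()
            sg = _subgroup(evs, lambda e: e.labels.biome.value, cfg, rng)
            per_biome[resp.value] = sg.to_dict() if sg else None
        else:
            overall[resp.value] = None
            per_biome[resp.value] = None
    counts["effects_final_harvest"] = {r.value: len(v)
                                       for r, v in effects_final.items()}
    counts["effect_exclusions_final_harvest"] = effect_excl_counts

    ml = effects_final[Response.mass_loss]
    subgroups: dict = {}
    for name, fn in [
        ("richness", lambda e: str(e.labels.richness)),
        ("evenness", lambda e: e.labels.evenness.value),
        ("functional_composition",
         lambda e: (e.labels.functional_composition.value
                    if e.labels.functional_composition else None)),
        ("forest_type", lambda e: e.labels.forest_type.value),
        ("forest_structure", _forest_structure_label),
        ("mesh_class", lambda e: e.labels.mesh_class.value),
    ]:
        sg = _subgroup(ml, fn, cfg, rng)
        subgroups[name] = sg.to_dict() if sg else None

    staging: dict = {}
    staging_excl: dict = {}
    staging_frames = []
    for resp in _RESPONSES:
        res, excl = staged_meta(
            pairs, response=resp, reps=cfg.bootstrap_reps, seed=rng,
            method=cfg.ci_method,
            collapse_per_study=cfg.staging_collapse_per_study)
        staging[resp.value] = {lab: r.to_dict() for lab, r in res.items()}
        staging_excl[resp.value] = len(excl)
        staging_frames.append(staging_table(res).assign(response=resp.value))
    counts["staging_effect_exclusions"] = staging_excl

    # trait-divergence regressions on study-averaged in-window effects
    all_ml_effects, _ = compute_effects(
        [p for p in pairs if p.response is Response.mass_loss])
    window_effects = div.window_effect_per_study(
        all_ml_effects, window=cfg.divergence_window)
    divergences, div_log = div.dataset_divergences(ds)
    in_window_tids: dict[str, set] = {}
    lo, hi = cfg.divergence_window
    for e in all_ml_effects:
        if lo <= e.expected_mass_loss <= hi:
            in_window_tids.setdefault(e.study_id, set()).add(e.treatment_id)
    regressions: dict = {}
    divergence_rows = []
    from .records_io import TRAIT_NAMES
    for trait in TRAIT_NAMES:
        xs, ys = [], []
        for study, eff in window_effects.items():
            vals = [divergences[t][trait] for t in sorted(in_window_tids[study])
                    if trait in divergences.get(t, {})]
            if not vals:
                continue
            xs.append(float(np.mean(vals)))
            ys.append(eff)
        for study, eff in window_effects.items():
            for t in sorted(in_window_tids[study]):
                if trait in divergences.get(t, {}):
                    divergence_rows.append({"treatment_id": t, "trait": trait,
                                            "rao": divergences[t][trait]})
        if len(xs) >= 3 and len(set(xs)) > 1:
            r = div.moderator_regression(xs, ys)
            regressions[f"divergence_{trait}"] = {
                "slope": r.slope, "intercept": r.intercept,
                "r_squared": r.r_squared, "p_value": r.p_value,
                "n_points": r.n_points}
        else:
            regressions[f"divergence_{trait}"] = None

    # climate regressions: one point per final-harvest paired observation
    mat_by_study = dict(zip(ds.studies["study_id"], ds.studies["mat"]))
    map_by_study = dict(zip(ds.studies["study_id"], ds.studies["map"]))
    for name, lookup in (("mat", mat_by_study), ("map", map_by_study)):
        xs = [float(lookup[e.study_id]) for e in ml]
        ys = [e.lnrr for e in ml]
        if len(xs) >= 3 and len(set(xs)) > 1:
            r = div.moderator_regression(xs, ys)
            regressions[f"climate_{name}"] = {
                "slope": r.slope, "intercept": r.intercept,
                "r_squared": r.r_squared, "p_value": r.p_value,
                "n_points": r.n_points}
        else:
            regressions[f"climate_{name}"] = None

    report = {
        "config": cfg.model_dump(mode="json"),
        "counts": counts,
        "overall": overall,
        "per_biome": per_biome,
        "subgroups": subgroups,
        "staging": staging,
        "regressions": regressions,
        "divergence_exclusions": len(div_log),
        "nutrient_summary": nutrient_summary(ds, cfg.nutrient_mode),
    }
    # stash frames for write_report without polluting the JSON report
    report["_frames"] = {
        "pairs": pairs_to_frame(pairs),
        "effects": effects_to_frame(all_ml_effects
                                    + [e for r in (Response.N_release,
                                                   Response.P_release)
                                       for e in effects_final[r]]),
        "staging": pd.concat([f.astype(object) for f in staging_frames],
                             ignore_index=True),
        "divergence": pd.DataFrame(divergence_rows),
    }
    return report


def report_json(report: dict) -> str:
    """Deterministic JSON serialization of a run report."""
    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    return json.dumps(clean, indent=2, sort_keys=True) + "\n"


def write_report(report: dict, out_dir: str | Path) -> None:
    """Write report.json plus the per-module audit CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(report_json(report))
    frames = report.get("_frames", {})
    for name, frame in frames.items():
        frame.to_csv(out_dir / f"{name}.csv", index=False)
    regress = report.get("regressions", {})
    rows = [{"variable": k, **(v or {})} for k, v in regress.items()]
    pd.DataFrame(rows).to_csv(out_dir / "regressions.csv", index=False)
    meta = {"overall": report["overall"], "per_biome": report["per_biome"],
            "subgroups": report["subgroups"]}
    (out_dir / "meta_results.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n")
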