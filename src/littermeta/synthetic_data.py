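"""Synthetic litter-mixture decomposition datasets with recorded ground truth.

The generator emits complete four-table datasets in the input schema so the
whole pipeline can be exercised — and its estimates scored against known
truth — without any external data. It emulates the statistical structure the
analysis assumes:

* single-species mass loss follows single-pool exponential decay, with decay
  constants decreasing in lignin:N and scaled by a biome-level base rate;
* evergreen species carry higher lignin, lignin:N and C:N than deciduous
  species; trees dominate, shrubs and herbs occur at realistic frequencies;
* reported treatment means carry multiplicative lognormal measurement error
  with a configurable replicate-level coefficient of variation (positivity is
  thereby preserved, as the log response ratio requires);
* the observed mixture mass loss is the additive null multiplied by
  exp(theta) whenever the true null mass loss lies inside the interaction
  window, where theta = biome effect + N(0, tau^2) + sum_t beta_t * Rao_t is
  drawn once per mixture treatment. Because the interaction acts
  multiplicatively on the null, the configured theta *is* the true lnRR by
  construction;
* nutrient concentrations follow an immobilization-then-release trajectory
  (remaining fraction rises above one early, then declines), with a
  multiplicative mixture effect applied to the positive part of release.

Realized per-treatment effects, additive-null trajectories, per-interval mean
effects and the configured regression slopes are stored as ground truth next
to the tables (``truth.json``).

Component species are not shared between the mixture treatments of a study,
so every paired observation carries an independent interaction effect,
matching the meta-analysis' independence assumption.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .records_io import Dataset, validate_dataset, write_dataset
from .staging import assign_interval

__all__ = ["GeneratorConfig", "NutrientParams", "generate", "fixture_small",
           "write_generated"]

_BIOME_CLIMATE = {  # (MAT degC, MAP mm, |lat| band, base decay k per yr)
    "boreal": (-1.0, 450.0, (55.0, 65.0), 0.25),
    "temperate": (8.0, 800.0, (40.0, 55.0), 0.45),
    "mediterranean": (15.0, 550.0, (32.0, 42.0), 0.50),
    "subtropical": (18.0, 1400.0, (23.0, 33.0), 0.80),
    "tropical": (24.0, 2200.0, (0.0, 23.0), 1.20),
}

# habit -> trait -> (mean, sd); concentrations mg g^-1
_TRAIT_PARAMS = {
    "deciduous": {"N": (12.0, 2.5), "P": (0.55, 0.15), "K": (6.0, 1.8),
                  "Ca": (11.0, 3.0), "Mg": (2.0, 0.6),
                  "cellulose": (250.0, 40.0), "lignin": (180.0, 35.0)},
    "evergreen": {"N": (9.0, 2.0), "P": (0.42, 0.12), "K": (4.5, 1.5),
                  "Ca": (8.0, 2.5), "Mg": (1.6, 0.5),
                  "cellulose": (270.0, 40.0), "lignin": (240.0, 40.0)},
}
_CARBON_MEAN, _CARBON_SD = 480.0, 20.0
_TRAIT_MISSING_P = {"K": 0.12, "Ca": 0.12, "Mg": 0.15, "cellulose": 0.18,
                    "P": 0.08}
_MASS_LOSS_CAP = 99.5  # reported means truncated just below total loss
_RELEASE_CAP = 98.0  # relative release (%) cannot reach the full pool


class NutrientParams(BaseModel):
    """Immobilization-then-release trajectory for one nutrient.

    The remaining fraction of the initial nutrient amount at time t (days) is

        R(t) = (1 + amplitude * s * e^(1 - s)) * exp(-rate_ratio * k * t_yr)

    with s = t / phase_days: an early hump above one (net immobilization)
    followed by net release at a rate proportional to the litter's own decay
    constant k.
    """

    amplitude: float = 0.4
    phase_days: float = 150.0
    rate_ratio: float = 0.7  # nutrient release rate relative to mass decay

    def remaining_fraction(self, t_days: float, k_per_year: float) -> float:
        s = t_days / self.phase_days
        hump = 1.0 + self.amplitude * s * math.exp(1.0 - s)
        return hump * math.exp(-self.rate_ratio * k_per_year * t_days / 365.0)


class GeneratorConfig(BaseModel):
    """All knobs of the synthetic study population.

    Defaults are sized to the shape of the global litterbag corpus the
    analysis targets: 65 studies yielding roughly 280 final-harvest mixture
    observations (about two thirds of them two-species mixtures) and roughly
    650 all-harvest observations across five forest biomes.
    """

    n_studies: int = 65
    seed: int = 0
    biome_mix: dict[str, float] = Field(default_factory=lambda: {
        "boreal": 0.07, "temperate": 0.42, "mediterranean": 0.08,
        "subtropical": 0.25, "tropical": 0.18})
    #: true mass-loss lnRR per biome (applied inside the interaction window)
    true_effects: dict[str, float] = Field(default_factory=lambda: {
        "boreal": 0.0, "temperate": 0.08, "mediterranean": 0.0,
        "subtropical": 0.06, "tropical": 0.0})
    #: true lnRR on (positive) relative nutrient release for mixtures
    nutrient_effects: dict[str, float] = Field(default_factory=lambda: {
        "N": 0.50, "P": 0.10})
    #: between-observation SD of the realized interaction effect
    tau: float = 0.05
    #: (% lower, % upper) true-null mass loss where the interaction is active
    interaction_window: tuple[float, float] = (0.0, 100.0)
    #: added lnRR per unit Rao divergence, per trait
    divergence_slope: dict[str, float] = Field(default_factory=dict)
    n_reps: int = 4
    #: replicate-level coefficient of variation of reported quantities
    measurement_cv: float = 0.10
    harvest_schedule: list[float] = Field(
        default_factory=lambda: [91.0, 182.0, 365.0, 730.0])
    #: probability that a study runs 1, 2, ... harvests of the schedule
    n_harvest_probs: list[float] = Field(
        default_factory=lambda: [0.25, 0.35, 0.26, 0.14])
    mixtures_per_study_mean: float = 4.4
    richness_mix: dict[int, float] = Field(default_factory=lambda: {
        2: 0.69, 3: 0.145, 4: 0.12, 6: 0.045})
    evenness_fraction: float = 0.79  # share of equal-proportion mixtures
    evergreen_fraction: float = 0.45
    life_form_probs: dict[str, float] = Field(default_factory=lambda: {
        "tree": 0.80, "shrub": 0.08, "herb": 0.12})
    forest_natural_fraction: float = 0.70
    mesh_size_probs: dict[float, float] = Field(default_factory=lambda: {
        0.5: 0.22, 1.0: 0.10, 2.0: 0.35, 4.0: 0.33})
    frac_studies_n: float = 0.30  # share of studies measuring N
    frac_studies_p: float = 0.12
    nutrient_params: dict[str, NutrientParams] = Field(default_factory=lambda: {
        "N": NutrientParams(amplitude=0.4, phase_days=150.0, rate_ratio=0.85),
        "P": NutrientParams(amplitude=0.15, phase_days=80.0, rate_ratio=0.9)})

    @field_validator("biome_mix", "richness_mix", "life_form_probs",
                     "mesh_size_probs", "n_harvest_probs")
    @classmethod
    def _sums_to_one(cls, v):
        vals = list(v.values()) if isinstance(v, dict) else list(v)
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        if any(p < 0 for p in vals):
            raise ValueError("proportions must be >= 0")
        return v

    @model_validator(mode="after")
    def _feasible(self):
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.measurement_cv <= 0:
            raise ValueError("measurement_cv must be > 0")
        lo, hi = self.interaction_window
        if not (0.0 <= lo < hi <= 100.0):
            raise ValueError("interaction_window must satisfy 0 <= lo < hi <= 100")
        if len(self.n_harvest_probs) != len(self.harvest_schedule):
            raise ValueError("n_harvest_probs must match harvest_schedule length")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        return self


def _weighted_choice(rng: np.random.Generator, mapping: dict):
    keys = sorted(mapping)
    probs = np.array([mapping[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=probs))]


def _draw_species(rng: np.random.Generator, habit: str) -> dict[str, float]:
    params = _TRAIT_PARAMS[habit]
    traits: dict[str, float] = {}
    for name, (mu, sd) in params.items():
        val = -1.0
        while val <= 0:
            val = rng.normal(mu, sd)
        traits[name] = round(float(val), 4)
    carbon = max(rng.normal(_CARBON_MEAN, _CARBON_SD), 300.0)
    traits["C_N"] = round(carbon / traits["N"], 4)
    traits["N_P"] = round(traits["N"] / traits["P"], 4)
    traits["lignin_N"] = round(traits["lignin"] / traits["N"], 4)
    for name, p in _TRAIT_MISSING_P.items():
        if rng.random() < p:
            traits[name] = float("nan")
            if name == "P":
                traits["N_P"] = float("nan")
    return traits


def _decay_constant(rng: np.random.Generator, base_k: float, lignin_n: float) -> float:
    return base_k * (15.0 / lignin_n) ** 0.4 * math.exp(rng.normal(0.0, 0.15))


def _noisy(rng: np.random.Generator, value: float, cv: float, n_reps: int,
           cap: float | None = None) -> tuple[float, float]:
    """Reported (mean, sd) for a true value: the mean carries lognormal
    sampling error of the replicate mean; sd is the replicate-level spread."""
    mean = value * math.exp(rng.normal(0.0, cv / math.sqrt(n_reps)))
    if cap is not None:
        mean = min(mean, cap)
    mean = round(mean, 6)  # written precision; keeps stored truth exact
    return mean, round(cv * mean, 6)


def _proportions(rng: np.random.Generator, richness: int, equal: bool) -> list[float]:
    if equal:
        return [1.0 / richness] * richness
    while True:
        d = rng.dirichlet(np.full(richness, 2.0))
        d = np.clip(d, 0.05, None)
        d = d / d.sum()
        if float(d.max() - d.min()) > 0.05:
            break
    props = [float(x) for x in d[:-1]]
    props.append(1.0 - math.fsum(props))  # exact unit sum
    return props


def _rao(values: list[float], props: list[float]) -> float:
    total = 0.0
    for i in range(len(values) - 1):
        for j in range(i + 1, len(values)):
            total += abs(values[i] - values[j]) * props[i] * props[j]
    return total


def generate(config: GeneratorConfig) -> tuple[Dataset, dict]:
    """Generate one dataset plus its ground truth, reproducibly from
    ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    cv, n_reps = config.measurement_cv, config.n_reps
    lo_win, hi_win = config.interaction_window
    study_rows, species_rows, obs_rows, comp_rows = [], [], [], []
    treatments_truth: dict[str, dict] = {}
    sp_counter = 0

    for s in range(config.n_studies):
        study_id = f"S{s + 1:03d}"
        biome = _weighted_choice(rng, config.biome_mix)
        mat0, map0, lat_band, base_k = _BIOME_CLIMATE[biome]
        lat = float(rng.uniform(*lat_band)) * (1 if rng.random() < 0.7 else -1)
        study_rows.append({
            "study_id": study_id,
            "latitude": round(lat, 3),
            "longitude": round(float(rng.uniform(-180, 180)), 3),
            "biome": biome,
            "mat": round(mat0 + float(rng.normal(0, 1.5)), 2),
            "map": round(max(0.0, map0 * math.exp(rng.normal(0, 0.15))), 1),
            "forest_type": ("natural" if rng.random() < config.forest_natural_fraction
                            else "planted"),
            "mesh_size": _weighted_choice(rng, config.mesh_size_probs),
            "selected": True,
        })
        n_harv = int(rng.choice(len(config.harvest_schedule),
                                p=config.n_harvest_probs)) + 1
        times = config.harvest_schedule[:n_harv]
        measures = {"N": rng.random() < config.frac_studies_n,
                    "P": rng.random() < config.frac_studies_p}
        n_mix = 1 + int(rng.poisson(max(config.mixtures_per_study_mean - 1, 0.0)))

        for m in range(n_mix):
            tid = f"{study_id}_M{m + 1}"
            richness = _weighted_choice(rng, config.richness_mix)
            equal = rng.random() < config.evenness_fraction
            props = _proportions(rng, richness, equal)
            members = []
            for _ in range(richness):
                sp_counter += 1
                sid = f"sp{sp_counter:05d}"
                habit = ("evergreen" if rng.random() < config.evergreen_fraction
                         else "deciduous")
                life_form = _weighted_choice(rng, config.life_form_probs)
                traits = _draw_species(rng, habit)
                species_rows.append({"species_id": sid, "life_form": life_form,
                                     "leaf_habit": habit, **traits})
                k = _decay_constant(rng, base_k, traits["lignin_N"])
                members.append({"sid": sid, "traits": traits, "k": k})
            for sid_, p_ in zip((mb["sid"] for mb in members), props):
                comp_rows.append({"treatment_id": tid, "species_id": sid_,
                                  "proportion": p_})

            rao_by_trait = {}
            div_term = 0.0
            for trait, beta in sorted(config.divergence_slope.items()):
                vals = [mb["traits"].get(trait, float("nan")) for mb in members]
                if any(math.isnan(v) for v in vals):
                    continue
                rao_by_trait[trait] = _rao(vals, props)
                div_term += beta * rao_by_trait[trait]
            theta_mass = (config.true_effects.get(biome, 0.0)
                          + config.tau * float(rng.standard_normal())
                          + div_term)
            theta_nut = {nut: (config.nutrient_effects.get(nut, 0.0)
                               + config.tau * float(rng.standard_normal()))
                         for nut in ("N", "P")}

            null_true, null_obs, active_by_h = {}, {}, {}
            for h, t in enumerate(times):
                final = h == n_harv - 1
                losses_true, losses_obs = [], []
                for mb in members:
                    l_true = (1.0 - math.exp(-mb["k"] * t / 365.0)) * 100.0
                    mean, sd = _noisy(rng, l_true, cv, n_reps, cap=_MASS_LOSS_CAP)
                    losses_true.append(l_true)
                    losses_obs.append(mean)
                    row = {
                        "study_id": study_id,
                        "treatment_id": f"{study_id}_single_{mb['sid']}",
                        "species_id": mb["sid"], "is_mixture": False,
                        "harvest_time": t, "harvest_index": h,
                        "is_final_harvest": final,
                        "mass_loss": mean,
                        "mass_loss_sd": sd, "n_reps": n_reps,
                        "conc_N": np.nan, "conc_N_sd": np.nan,
                        "conc_P": np.nan, "conc_P_sd": np.nan,
                    }
                    for nut in ("N", "P"):
                        if not measures[nut] or math.isnan(mb["traits"].get(nut, float("nan"))):
                            continue
                        pars = config.nutrient_params[nut]
                        r_frac = pars.remaining_fraction(t, mb["k"])
                        m_frac = max(1.0 - l_true / 100.0, 1.0 - _MASS_LOSS_CAP / 100.0)
                        conc_true = mb["traits"][nut] * r_frac / m_frac
                        c_mean, c_sd = _noisy(rng, conc_true, cv, n_reps)
                        row[f"conc_{nut}"] = c_mean
                        row[f"conc_{nut}_sd"] = c_sd
                    obs_rows.append(row)

                nt = math.fsum(p * l for p, l in zip(props, losses_true))
                active = lo_win <= nt <= hi_win
                theta_applied = theta_mass if active else 0.0
                l_mix_true = min(nt * math.exp(theta_applied), _MASS_LOSS_CAP)
                mix_mean, mix_sd = _noisy(rng, l_mix_true, cv, n_reps,
                                          cap=_MASS_LOSS_CAP)
                null_true[h] = nt
                null_obs[h] = math.fsum(p * l for p, l in zip(props, losses_obs))
                active_by_h[h] = active
                mrow = {
                    "study_id": study_id, "treatment_id": tid,
                    "species_id": np.nan, "is_mixture": True,
                    "harvest_time": t, "harvest_index": h,
                    "is_final_harvest": final,
                    "mass_loss": mix_mean,
                    "mass_loss_sd": mix_sd, "n_reps": n_reps,
                    "conc_N": np.nan, "conc_N_sd": np.nan,
                    "conc_P": np.nan, "conc_P_sd": np.nan,
                }
                for nut in ("N", "P"):
                    if not measures[nut]:
                        continue
                    c0s = [mb["traits"].get(nut, float("nan")) for mb in members]
                    if any(math.isnan(c) for c in c0s):
                        continue
                    pars = config.nutrient_params[nut]
                    c0_mix = math.fsum(p * c for p, c in zip(props, c0s))
                    weights = [p * c / c0_mix for p, c in zip(props, c0s)]
                    rel_null = math.fsum(
                        w * (1.0 - pars.remaining_fraction(t, mb["k"])) * 100.0
                        for w, mb in zip(weights, members))
                    if active and rel_null > 0:
                        rel_mix = min(rel_null * math.exp(theta_nut[nut]),
                                      _RELEASE_CAP)
                    else:
                        rel_mix = rel_null
                    r_mix = 1.0 - rel_mix / 100.0
                    m_frac_mix = max(1.0 - l_mix_true / 100.0,
                                     1.0 - _MASS_LOSS_CAP / 100.0)
                    conc_true = c0_mix * r_mix / m_frac_mix
                    c_mean, c_sd = _noisy(rng, conc_true, cv, n_reps)
                    mrow[f"conc_{nut}"] = c_mean
                    mrow[f"conc_{nut}_sd"] = c_sd
                obs_rows.append(mrow)

            treatments_truth[tid] = {
                "study_id": study_id, "biome": biome,
                "theta_mass": theta_mass,
                "theta_N": theta_nut["N"], "theta_P": theta_nut["P"],
                "rao": rao_by_trait,
                "null_mass_loss_true": {str(h): v for h, v in null_true.items()},
                "null_mass_loss_from_observed": {str(h): v
                                                 for h, v in null_obs.items()},
                "interaction_active": {str(h): bool(a)
                                       for h, a in active_by_h.items()},
            }

    ds = _to_dataset(study_rows, species_rows, obs_rows, comp_rows)
    validate_dataset(ds)
    truth = {
        "seed": config.seed,
        "config": config.model_dump(mode="json"),
        "treatments": treatments_truth,
        "per_interval_true_effect": _interval_truth(treatments_truth),
        "true_slopes": {"divergence": dict(config.divergence_slope),
                        "mat": 0.0, "map": 0.0},
    }
    return ds, truth


def _interval_truth(treatments_truth: dict) -> dict[str, float | None]:
    """True mean applied effect per stage interval (by true null mass loss)."""
    sums: dict[str, list[float]] = {}
    for t in treatments_truth.values():
        for h, nt in t["null_mass_loss_true"].items():
            label = assign_interval(min(nt, 100.0)).label
            eff = t["theta_mass"] if t["interaction_active"][h] else 0.0
            sums.setdefault(label, []).append(eff)
    return {label: (float(np.mean(v)) if v else None)
            for label, v in sorted(sums.items())}


_OBS_COLUMNS = ["study_id", "treatment_id", "species_id", "is_mixture",
                "harvest_time", "harvest_index", "is_final_harvest",
                "mass_loss", "mass_loss_sd", "n_reps",
                "conc_N", "conc_N_sd", "conc_P", "conc_P_sd"]


def _to_dataset(study_rows, species_rows, obs_rows, comp_rows) -> Dataset:
    studies = pd.DataFrame(study_rows, columns=[
        "study_id", "latitude", "longitude", "biome", "mat", "map",
        "forest_type", "mesh_size", "selected"])
    species = pd.DataFrame(species_rows, columns=[
        "species_id", "life_form", "leaf_habit", "N", "P", "K", "Ca", "Mg",
        "cellulose", "lignin", "C_N", "N_P", "lignin_N"])
    observations = pd.DataFrame(obs_rows, columns=_OBS_COLUMNS)
    compositions = pd.DataFrame(comp_rows,
                                columns=["treatment_id", "species_id", "proportion"])
    if observations.empty:
        observations = observations.astype({
            "is_mixture": bool, "is_final_harvest": bool})
    return Dataset(studies=studies, species=species,
                   observations=observations, compositions=compositions)


def fixture_small(seed: int = 0) -> tuple[Dataset, dict]:
    """Deterministic miniature dataset: 3 temperate studies, two-species
    mixtures, 2 harvests, nutrient data everywhere; includes at least one
    early-harvest N immobilization case and one missing-trait species."""
    config = GeneratorConfig(
        n_studies=3, seed=seed,
        biome_mix={"temperate": 1.0},
        true_effects={"temperate": 0.08},
        richness_mix={2: 1.0},
        harvest_schedule=[120.0, 365.0],
        n_harvest_probs=[0.0, 1.0],
        mixtures_per_study_mean=2.0,
        frac_studies_n=1.0, frac_studies_p=0.5,
        nutrient_params={
            "N": NutrientParams(amplitude=1.0, phase_days=60.0, rate_ratio=0.7),
            "P": NutrientParams(amplitude=0.15, phase_days=80.0, rate_ratio=0.9)},
    )
    ds, truth = generate(config)
    # guarantee a missing-trait species for exclusion-path coverage
    ds.species.loc[ds.species.index[0], ["K", "Ca"]] = np.nan
    return ds, truth


def write_generated(ds: Dataset, truth: dict, out_dir: str | Path) -> None:
    """Write the four CSV tables plus truth.json under *out_dir*."""
    out_dir = Path(out_dir)
    write_dataset(ds, out_dir)
    (out_dir / "truth.json").write_text(
        json.dumps(truth, indent=2, sort_keys=True) + "\n")
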