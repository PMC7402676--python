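"""Dataset schema, CSV round-trip, and categorical classifiers.

The curated input is four CSV tables (UTF-8, comma separated, ``.`` decimal
mark, empty cell = missing):

``studies.csv``
    study_id, latitude, longitude, biome, mat, map, forest_type, mesh_size,
    selected
``species.csv``
    species_id, life_form, leaf_habit, then one column per initial chemical
    trait (N, P, K, Ca, Mg, cellulose, lignin in mg g^-1; C_N, N_P, lignin_N
    unitless)
``observations.csv``
    study_id, treatment_id, species_id (blank for mixtures), is_mixture,
    harvest_time (days), harvest_index, is_final_harvest, mass_loss (%),
    mass_loss_sd, n_reps, conc_N, conc_N_sd, conc_P, conc_P_sd (mg g^-1,
    optional)
``compositions.csv``
    treatment_id, species_id, proportion (initial dry-mass fraction)

Rows with ``selected = False`` are retained on read but flagged for exclusion
from analysis; nothing is ever dropped silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Biome",
    "ForestType",
    "LifeForm",
    "LeafHabit",
    "MeshClass",
    "Evenness",
    "FunctionalComposition",
    "StandStructure",
    "TRAIT_NAMES",
    "SchemaError",
    "StudyMeta",
    "LitterSpecies",
    "DecompObservation",
    "MixtureComposition",
    "GroupLabels",
    "Dataset",
    "read_dataset",
    "write_dataset",
    "classify_mesh",
    "classify_evenness",
    "classify_functional_composition",
    "classify_stand_structure",
    "build_group_labels",
]


class Biome(str, Enum):
    boreal = "boreal"
    temperate = "temperate"
    mediterranean = "mediterranean"
    subtropical = "subtropical"
    tropical = "tropical"


class ForestType(str, Enum):
    natural = "natural"
    planted = "planted"


class LifeForm(str, Enum):
    tree = "tree"
    shrub = "shrub"
    herb = "herb"


class LeafHabit(str, Enum):
    deciduous = "deciduous"
    evergreen = "evergreen"


class MeshClass(str, Enum):
    lt1 = "lt1"
    one_to_two = "1to2"
    gt2 = "gt2"


class Evenness(str, Enum):
    equal = "equal"
    non_equal = "non_equal"


class FunctionalComposition(str, Enum):
    decid_decid = "decid_decid"
    ever_ever = "ever_ever"
    decid_ever = "decid_ever"


class StandStructure(str, Enum):
    canopy_only = "canopy_only"
    plus_understory = "plus_understory"


#: Initial chemical traits carried per species. Concentrations in mg g^-1,
#: ratios unitless. Missing values are permitted (empty CSV cell).
TRAIT_NAMES = ("N", "P", "K", "Ca", "Mg", "cellulose", "lignin", "C_N", "N_P", "lignin_N")

_EVENNESS_TOL = 1e-9
_PROPORTION_TOL = 1e-9


class SchemaError(ValueError):
    """A table failed validation; the message names file, row, and field."""


@dataclass(frozen=True)
class StudyMeta:
    study_id: str
    latitude: float
    longitude: float
    biome: Biome
    mat: float  # mean annual temperature, degC
    map: float  # mean annual precipitation, mm
    forest_type: ForestType
    mesh_size: float  # litterbag mesh aperture, mm
    selected: bool = True


@dataclass(frozen=True)
class LitterSpecies:
    species_id: str
    life_form: LifeForm
    leaf_habit: LeafHabit
    traits: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class DecompObservation:
    study_id: str
    treatment_id: str
    is_mixture: bool
    harvest_time: float  # days since deployment
    harvest_index: int
    is_final_harvest: bool
    mass_loss: float  # mean % of initial dry mass lost
    mass_loss_sd: float
    n_reps: int
    nutrient_conc: Mapping[str, float] = field(default_factory=dict)
    nutrient_conc_sd: Mapping[str, float] = field(default_factory=dict)
    species_id: str | None = None  # set for single-species treatments


@dataclass(frozen=True)
class MixtureComposition:
    treatment_id: str
    components: tuple[tuple[str, float], ...]  # (species_id, mass fraction)

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.components)

    @property
    def proportions(self) -> tuple[float, ...]:
        return tuple(p for _, p in self.components)


@dataclass(frozen=True)
class GroupLabels:
    """Categorical labels attached to one mixture treatment.

    Fields that cannot be determined (e.g. a component with unknown leaf
    habit) are ``None``; the treatment is then excluded from that grouping
    only, with a logged reason.
    """

    biome: Biome
    richness: int
    evenness: Evenness
    forest_type: ForestType
    mesh_class: MeshClass
    functional_composition: FunctionalComposition | None = None
    stand_structure: StandStructure | None = None


_STUDY_COLS = ["study_id", "latitude", "longitude", "biome", "mat", "map",
               "forest_type", "mesh_size", "selected"]
_SPECIES_COLS = ["species_id", "life_form", "leaf_habit", *TRAIT_NAMES]
_OBS_COLS = ["study_id", "treatment_id", "species_id", "is_mixture",
             "harvest_time", "harvest_index", "is_final_harvest",
             "mass_loss", "mass_loss_sd", "n_reps",
             "conc_N", "conc_N_sd", "conc_P", "conc_P_sd"]
_COMP_COLS = ["treatment_id", "species_id", "proportion"]


@dataclass
class Dataset:
    """The four validated tables, plus typed accessors."""

    studies: pd.DataFrame
    species: pd.DataFrame
    observations: pd.DataFrame
    compositions: pd.DataFrame

    def study_meta(self, study_id: str) -> StudyMeta:
        row = self.studies.loc[self.studies["study_id"] == study_id].iloc[0]
        return StudyMeta(
            study_id=row["study_id"], latitude=float(row["latitude"]),
            longitude=float(row["longitude"]), biome=Biome(row["biome"]),
            mat=float(row["mat"]), map=float(row["map"]),
            forest_type=ForestType(row["forest_type"]),
            mesh_size=float(row["mesh_size"]), selected=bool(row["selected"]),
        )

    def litter_species(self, species_id: str) -> LitterSpecies:
        row = self.species.loc[self.species["species_id"] == species_id].iloc[0]
        traits = {t: float(row[t]) for t in TRAIT_NAMES if pd.notna(row[t])}
        return LitterSpecies(
            species_id=row["species_id"],
            life_form=LifeForm(row["life_form"]),
            leaf_habit=LeafHabit(row["leaf_habit"]),
            traits=traits,
        )

    def composition(self, treatment_id: str) -> MixtureComposition:
        sub = self.compositions.loc[self.compositions["treatment_id"] == treatment_id]
        if sub.empty:
            raise KeyError(f"no composition for treatment {treatment_id!r}")
        comps = tuple((r["species_id"], float(r["proportion"])) for _, r in sub.iterrows())
        return MixtureComposition(treatment_id=treatment_id, components=comps)

    def mixture_treatments(self, selected_only: bool = True) -> list[str]:
        obs = self.observations
        mix = obs.loc[obs["is_mixture"], ["study_id", "treatment_id"]].drop_duplicates()
        if selected_only:
            sel = set(self.studies.loc[self.studies["selected"], "study_id"])
            mix = mix.loc[mix["study_id"].isin(sel)]
        return sorted(mix["treatment_id"].tolist())


def _require_columns(df: pd.DataFrame, cols: Sequence[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{fname}: missing column(s) {missing}")


def _check_mask(bad: pd.Series, fname: str, field_name: str, msg: str,
                values: pd.Series | None = None) -> None:
    """Raise on the first True entry of *bad*, naming file, row, field."""
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        detail = msg if values is None else f"{msg} (got {values.iloc[i]!r})"
        raise SchemaError(f"{fname} row {i} field {field_name!r}: {detail}")


def validate_dataset(ds: Dataset) -> None:
    """Enforce all schema invariants; raise :class:`SchemaError` on the first
    violation, naming file, row, and field."""
    st, sp, obs, comp = ds.studies, ds.species, ds.observations, ds.compositions
    _require_columns(st, _STUDY_COLS, "studies.csv")
    _require_columns(sp, _SPECIES_COLS, "species.csv")
    _require_columns(obs, _OBS_COLS, "observations.csv")
    _require_columns(comp, _COMP_COLS, "compositions.csv")

    if not st.empty:
        _check_mask(~st["biome"].isin([b.value for b in Biome]), "studies.csv",
                    "biome", "not a recognised biome", st["biome"])
        _check_mask(~st["forest_type"].isin([f.value for f in ForestType]),
                    "studies.csv", "forest_type", "bad value", st["forest_type"])
        _check_mask(~(st["mesh_size"] > 0), "studies.csv", "mesh_size",
                    "must be > 0", st["mesh_size"])
        _check_mask(~(st["map"] >= 0), "studies.csv", "map", "must be >= 0",
                    st["map"])

    if not sp.empty:
        _check_mask(~sp["life_form"].isin([f.value for f in LifeForm]),
                    "species.csv", "life_form", "bad value", sp["life_form"])
        _check_mask(~sp["leaf_habit"].isin([h.value for h in LeafHabit]),
                    "species.csv", "leaf_habit", "bad value", sp["leaf_habit"])
        for t in TRAIT_NAMES:
            vals = pd.to_numeric(sp[t], errors="coerce")
            _check_mask(sp[t].notna() & ~(vals > 0), "species.csv", t,
                        "trait values must be > 0", sp[t])

    study_ids = set(st["study_id"])
    species_ids = set(sp["species_id"])
    if not obs.empty:
        _check_mask(~obs["study_id"].isin(study_ids), "observations.csv",
                    "study_id", "dangling identifier", obs["study_id"])
        _check_mask(~((obs["mass_loss"] >= 0) & (obs["mass_loss"] <= 100)),
                    "observations.csv", "mass_loss", "must be in [0, 100]",
                    obs["mass_loss"])
        _check_mask(~(obs["mass_loss_sd"] >= 0), "observations.csv",
                    "mass_loss_sd", "must be >= 0", obs["mass_loss_sd"])
        _check_mask(~(obs["n_reps"] >= 1), "observations.csv", "n_reps",
                    "must be >= 1", obs["n_reps"])
        _check_mask(~(obs["harvest_time"] > 0), "observations.csv",
                    "harvest_time", "must be > 0", obs["harvest_time"])
        single = ~obs["is_mixture"]
        _check_mask(single & ~obs["species_id"].isin(species_ids),
                    "observations.csv", "species_id",
                    "single-species row must reference a known species",
                    obs["species_id"])

    mixture_ids = set(obs.loc[obs["is_mixture"], "treatment_id"]) if not obs.empty else set()
    if not comp.empty:
        _check_mask(~comp["species_id"].isin(species_ids), "compositions.csv",
                    "species_id", "dangling identifier", comp["species_id"])
        _check_mask(~comp["treatment_id"].isin(mixture_ids), "compositions.csv",
                    "treatment_id", "dangling identifier", comp["treatment_id"])
        _check_mask(~((comp["proportion"] > 0) & (comp["proportion"] <= 1)),
                    "compositions.csv", "proportion", "must be in (0, 1]",
                    comp["proportion"])
        sums = comp.groupby("treatment_id")["proportion"].agg(["sum", "size"])
        bad_sum = sums.loc[(sums["sum"] - 1.0).abs() > _PROPORTION_TOL]
        if not bad_sum.empty:
            tid = bad_sum.index[0]
            raise SchemaError(
                f"compositions.csv treatment {tid!r} field 'proportion': "
                f"proportions sum != 1 (got {float(bad_sum['sum'].iloc[0])!r})")
        too_few = sums.loc[sums["size"] < 2]
        if not too_few.empty:
            raise SchemaError(
                f"compositions.csv treatment {too_few.index[0]!r}: "
                f"a mixture needs >= 2 components")
    orphans = mixture_ids - (set(comp["treatment_id"]) if not comp.empty else set())
    if orphans:
        raise SchemaError(
            f"compositions.csv: mixture treatment {sorted(orphans)[0]!r} "
            f"has no composition rows")


_TABLE_FILES = {
    "studies": "studies.csv",
    "species": "species.csv",
    "observations": "observations.csv",
    "compositions": "compositions.csv",
}


def read_dataset(path: str | Path, se_to_sd: bool = False) -> Dataset:
    """Read and validate the four-table dataset from directory *path*.

    Parameters
    ----------
    path
        Directory containing studies.csv, species.csv, observations.csv,
        compositions.csv.
    se_to_sd
        If the source observations table reports standard errors rather than
        standard deviations, convert via ``sd = se * sqrt(n_reps)``.
    """
    path = Path(path)
    frames: dict[str, pd.DataFrame] = {}
    for key, fname in _TABLE_FILES.items():
        f = path / fname
        if not f.exists():
            raise SchemaError(f"{fname}: file not found under {path}")
        frames[key] = pd.read_csv(f, dtype={"study_id": str, "treatment_id": str,
                                            "species_id": str})
    obs = frames["observations"]
    if not obs.empty:
        obs["is_mixture"] = obs["is_mixture"].astype(bool)
        obs["is_final_harvest"] = obs["is_final_harvest"].astype(bool)
        obs["harvest_index"] = obs["harvest_index"].astype(int)
        obs["n_reps"] = obs["n_reps"].astype(int)
        if se_to_sd:
            obs["mass_loss_sd"] = obs["mass_loss_sd"] * np.sqrt(obs["n_reps"])
            for c in ("conc_N_sd", "conc_P_sd"):
                obs[c] = obs[c] * np.sqrt(obs["n_reps"])
    st = frames["studies"]
    if not st.empty:
        st["selected"] = st["selected"].astype(bool)
    ds = Dataset(studies=st, species=frames["species"], observations=obs,
                 compositions=frames["compositions"])
    validate_dataset(ds)
    return ds


def write_dataset(ds: Dataset, path: str | Path) -> None:
    """Write the four tables under directory *path* (created if needed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ds.studies.to_csv(path / "studies.csv", index=False)
    ds.species.to_csv(path / "species.csv", index=False)
    ds.observations.to_csv(path / "observations.csv", index=False)
    ds.compositions.to_csv(path / "compositions.csv", index=False)


# ---------------------------------------------------------------------------
# Categorical classifiers
# ---------------------------------------------------------------------------

def classify_mesh(mesh_size: float) -> MeshClass:
    """Assign a litterbag mesh aperture (mm) to one of three decomposer-access
    classes: < 1 mm, [1, 2] mm, > 2 mm.

    The middle class is the closed interval so the three classes partition
    the positive line.
    """
    if not mesh_size > 0:
        raise ValueError(f"mesh_size must be > 0, got {mesh_size}")
    if mesh_size < 1.0:
        return MeshClass.lt1
    if mesh_size <= 2.0:
        return MeshClass.one_to_two
    return MeshClass.gt2


def classify_evenness(proportions: Iterable[float] | MixtureComposition) -> Evenness:
    """Equal iff all mass proportions are identical within 1e-9."""
    if isinstance(proportions, MixtureComposition):
        props = proportions.proportions
    else:
        props = tuple(proportions)
    if len(props) < 2:
        raise ValueError("a mixture needs >= 2 components")
    target = 1.0 / len(props)
    if all(abs(p - target) <= _EVENNESS_TOL for p in props):
        return Evenness.equal
    return Evenness.non_equal


def classify_functional_composition(
    habits: Iterable[LeafHabit | str],
) -> FunctionalComposition:
    """Deciduous-only / evergreen-only / mixed leaf-habit composition."""
    hs = [LeafHabit(h) for h in habits]
    if len(hs) < 2:
        raise ValueError("need >= 2 components with known leaf habit")
    if all(h is LeafHabit.deciduous for h in hs):
        return FunctionalComposition.decid_decid
    if all(h is LeafHabit.evergreen for h in hs):
        return FunctionalComposition.ever_ever
    return FunctionalComposition.decid_ever


def classify_stand_structure(life_forms: Iterable[LifeForm | str]) -> StandStructure:
    """Canopy-only (all trees) vs vertically stratified (any shrub/herb)."""
    fs = [LifeForm(f) for f in life_forms]
    if len(fs) < 2:
        raise ValueError("need >= 2 components with known life form")
    if all(f is LifeForm.tree for f in fs):
        return StandStructure.canopy_only
    return StandStructure.plus_understory


def build_group_labels(
    ds: Dataset,
) -> tuple[dict[str, GroupLabels], list[dict[str, str]]]:
    """Build a :class:`GroupLabels` record for every mixture treatment of
    every selected study.

    Returns the mapping treatment_id -> labels plus a log of partial-label
    exclusions (treatments whose components have unknown habit/life form are
    still labelled, with the affected field set to ``None``).
    """
    labels: dict[str, GroupLabels] = {}
    log: list[dict[str, str]] = []
    sp_info = {r["species_id"]: (r["leaf_habit"], r["life_form"])
               for r in ds.species.to_dict("records")}
    study_by_treatment = dict(zip(ds.observations["treatment_id"],
                                  ds.observations["study_id"]))
    meta_by_study = {r["study_id"]: r for r in ds.studies.to_dict("records")}
    comp_by_tid: dict[str, list[tuple[str, float]]] = {}
    for r in ds.compositions.to_dict("records"):
        comp_by_tid.setdefault(r["treatment_id"], []).append(
            (r["species_id"], float(r["proportion"])))
    for tid in ds.mixture_treatments(selected_only=True):
        comp = MixtureComposition(treatment_id=tid,
                                  components=tuple(comp_by_tid[tid]))
        srow = meta_by_study[study_by_treatment[tid]]
        habits: list[str] = []
        forms: list[str] = []
        known = True
        for sid in comp.species_ids:
            if sid not in sp_info:
                known = False
                break
            habit, form = sp_info[sid]
            habits.append(habit)
            forms.append(form)
        fc = ss = None
        if known:
            fc = classify_functional_composition(habits)
            ss = classify_stand_structure(forms)
        else:
            log.append({"treatment_id": tid,
                        "reason": "unknown leaf habit or life form; excluded from "
                                  "functional-composition and stand-structure groupings"})
        labels[tid] = GroupLabels(
            biome=Biome(srow["biome"]),
            richness=len(comp.components),
            evenness=classify_evenness(comp),
            forest_type=ForestType(srow["forest_type"]),
            mesh_class=classify_mesh(float(srow["mesh_size"])),
            functional_composition=fc,
            stand_structure=ss,
        )
    return labels, log
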