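import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import littermeta as lm

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_fixture():
    """Deterministic miniature dataset + ground truth."""
    return lm.fixture_small(0)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-sized (65-study) synthetic dataset + truth."""
    return lm.generate(lm.GeneratorConfig(seed=1))


def make_tiny_dataset(with_nutrients: bool = True) -> lm.Dataset:
    """Hand-built dataset: one study, two species, one 50:50 mixture,
    one harvest, with explicit round numbers for oracle arithmetic."""
    studies = pd.DataFrame([{
        "study_id": "S1", "latitude": 45.0, "longitude": 7.0,
        "biome": "temperate", "mat": 8.0, "map": 800.0,
        "forest_type": "natural", "mesh_size": 2.0, "selected": True}])
    species = pd.DataFrame([
        {"species_id": "spA", "life_form": "tree", "leaf_habit": "deciduous",
         "N": 10.0, "P": 0.5, "K": 6.0, "Ca": 10.0, "Mg": 2.0,
         "cellulose": 250.0, "lignin": 180.0, "C_N": 48.0, "N_P": 20.0,
         "lignin_N": 18.0},
        {"species_id": "spB", "life_form": "tree", "leaf_habit": "evergreen",
         "N": 20.0, "P": 0.8, "K": 4.0, "Ca": 8.0, "Mg": 1.5,
         "cellulose": 270.0, "lignin": 240.0, "C_N": 24.0, "N_P": 25.0,
         "lignin_N": 12.0},
    ])
    base = {"study_id": "S1", "harvest_time": 365.0, "harvest_index": 0,
            "is_final_harvest": True, "n_reps": 4,
            "conc_P": np.nan, "conc_P_sd": np.nan}
    nut_a = {"conc_N": 12.0, "conc_N_sd": 1.2} if with_nutrients else \
        {"conc_N": np.nan, "conc_N_sd": np.nan}
    nut_b = {"conc_N": 25.0, "conc_N_sd": 2.5} if with_nutrients else \
        {"conc_N": np.nan, "conc_N_sd": np.nan}
    nut_m = {"conc_N": 20.0, "conc_N_sd": 2.0} if with_nutrients else \
        {"conc_N": np.nan, "conc_N_sd": np.nan}
    observations = pd.DataFrame([
        {**base, "treatment_id": "S1_single_spA", "species_id": "spA",
         "is_mixture": False, "mass_loss": 40.0, "mass_loss_sd": 4.0, **nut_a},
        {**base, "treatment_id": "S1_single_spB", "species_id": "spB",
         "is_mixture": False, "mass_loss": 60.0, "mass_loss_sd": 6.0, **nut_b},
        {**base, "treatment_id": "S1_M1", "species_id": np.nan,
         "is_mixture": True, "mass_loss": 55.0, "mass_loss_sd": 5.0, **nut_m},
    ])
    compositions = pd.DataFrame([
        {"treatment_id": "S1_M1", "species_id": "spA", "proportion": 0.5},
        {"treatment_id": "S1_M1", "species_id": "spB", "proportion": 0.5},
    ])
    return lm.Dataset(studies=studies, species=species,
                      observations=observations, compositions=compositions)


@pytest.fixture()
def tiny_dataset():
    return make_tiny_dataset()
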