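"""Schema validation, CSV round-trips, and categorical classifiers."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import littermeta as lm
from littermeta.records_io import validate_dataset

from conftest import make_tiny_dataset


@pytest.mark.parametrize("mesh, expected", [
    (0.5, lm.MeshClass.lt1),
    (0.999, lm.MeshClass.lt1),
    (1.0, lm.MeshClass.one_to_two),
    (1.5, lm.MeshClass.one_to_two),
    (2.0, lm.MeshClass.one_to_two),
    (2.001, lm.MeshClass.gt2),
    (5.0, lm.MeshClass.gt2),
])
def test_classify_mesh(mesh, expected):
    assert lm.classify_mesh(mesh) is expected


def test_classify_mesh_rejects_nonpositive():
    with pytest.raises(ValueError):
        lm.classify_mesh(0.0)


@given(st.floats(min_value=0.001, max_value=50.0,
                 allow_nan=False, allow_infinity=False))
@settings(max_examples=200, deadline=None)
def test_mesh_classes_partition_positive_line(mesh):
    """Every aperture maps to exactly one of the three classes."""
    assert lm.classify_mesh(mesh) in set(lm.MeshClass)


@pytest.mark.parametrize("props, expected", [
    ((0.5, 0.5), lm.Evenness.equal),
    ((0.75, 0.25), lm.Evenness.non_equal),
    ((1 / 3, 1 / 3, 1 / 3), lm.Evenness.equal),
    ((0.25, 0.25, 0.25, 0.25), lm.Evenness.equal),
    ((0.4, 0.3, 0.3), lm.Evenness.non_equal),
])
def test_classify_evenness(props, expected):
    assert lm.classify_evenness(props) is expected


@pytest.mark.parametrize("habits, expected", [
    (("deciduous", "deciduous"), lm.FunctionalComposition.decid_decid),
    (("evergreen", "evergreen", "evergreen"), lm.FunctionalComposition.ever_ever),
    (("deciduous", "evergreen"), lm.FunctionalComposition.decid_ever),
    (("evergreen", "deciduous", "deciduous"), lm.FunctionalComposition.decid_ever),
])
def test_classify_functional_composition(habits, expected):
    assert lm.classify_functional_composition(habits) is expected


@pytest.mark.parametrize("forms, expected", [
    (("tree", "tree"), lm.StandStructure.canopy_only),
    (("tree", "shrub"), lm.StandStructure.plus_understory),
    (("shrub", "herb"), lm.StandStructure.plus_understory),
    (("tree", "tree", "herb"), lm.StandStructure.plus_understory),
])
def test_classify_stand_structure(forms, expected):
    assert lm.classify_stand_structure(forms) is expected


def test_roundtrip_tiny(tmp_path, tiny_dataset):
    lm.write_dataset(tiny_dataset, tmp_path)
    back = lm.read_dataset(tmp_path)
    for name in ("studies", "species", "observations", "compositions"):
        pd.testing.assert_frame_equal(getattr(back, name),
                                      getattr(tiny_dataset, name),
                                      check_dtype=False)


def test_roundtrip_generated(tmp_path, default_dataset):
    """A full 65-study generated dataset survives write -> read
    field-for-field."""
    ds, _ = default_dataset
    lm.write_dataset(ds, tmp_path)
    back = lm.read_dataset(tmp_path)
    for name in ("studies", "species", "observations", "compositions"):
        pd.testing.assert_frame_equal(getattr(back, name), getattr(ds, name),
                                      check_dtype=False)


def test_bad_proportion_sum_raises(tmp_path, tiny_dataset):
    tiny_dataset.compositions.loc[1, "proportion"] = 0.4
    with pytest.raises(lm.SchemaError, match="sum != 1"):
        validate_dataset(tiny_dataset)


def test_missing_column_raises(tmp_path, tiny_dataset):
    lm.write_dataset(tiny_dataset, tmp_path)
    df = pd.read_csv(tmp_path / "observations.csv")
    df.drop(columns=["mass_loss"]).to_csv(tmp_path / "observations.csv",
                                          index=False)
    with pytest.raises(lm.SchemaError, match="missing column"):
        lm.read_dataset(tmp_path)


def test_dangling_identifier_raises(tiny_dataset):
    tiny_dataset.observations.loc[0, "study_id"] = "S999"
    with pytest.raises(lm.SchemaError, match="dangling identifier"):
        validate_dataset(tiny_dataset)


def test_invariant_violation_names_row_and_field(tiny_dataset):
    tiny_dataset.observations.loc[2, "mass_loss"] = 120.0
    with pytest.raises(lm.SchemaError, match=r"row 2 field 'mass_loss'"):
        validate_dataset(tiny_dataset)


def test_se_to_sd_conversion(tmp_path, tiny_dataset):
    lm.write_dataset(tiny_dataset, tmp_path)
    back = lm.read_dataset(tmp_path, se_to_sd=True)
    # sd = se * sqrt(n): 4 replicates double the dispersion column
    assert back.observations["mass_loss_sd"].iloc[0] == pytest.approx(8.0)


def test_unselected_rows_retained_but_excluded():
    ds = make_tiny_dataset()
    ds.studies.loc[0, "selected"] = False
    assert len(ds.observations) == 3  # nothing dropped
    assert ds.mixture_treatments(selected_only=True) == []
    pairs, _ = lm.build_pairs(ds)
    assert pairs == []


def test_group_labels_complete_or_logged(default_dataset):
    """Every analysis-eligible mixture carries labels; partial labels only
    with a logged reason."""
    from littermeta.records_io import build_group_labels
    ds, _ = default_dataset
    labels, log = build_group_labels(ds)
    assert set(labels) == set(ds.mixture_treatments())
    for lab in labels.values():
        assert lab.richness >= 2
        assert lab.mesh_class in set(lm.MeshClass)
        if lab.functional_composition is None:
            assert log  # partial labels imply a logged reason
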