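"""Additive-null expectations and pair construction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import littermeta as lm

from conftest import make_tiny_dataset


@pytest.mark.parametrize("means, props, expected", [
    ((40.0, 60.0), (0.5, 0.5), 50.0),
    ((40.0, 60.0), (0.75, 0.25), 45.0),
    ((55.0, 55.0), (0.3, 0.7), 55.0),
])
def test_expected_value(means, props, expected):
    assert lm.expected_value(means, props) == pytest.approx(expected, abs=1e-10)


def test_expected_value_rejects_mismatch():
    with pytest.raises(ValueError):
        lm.expected_value([1.0, 2.0, 3.0], [0.5, 0.5])


@given(st.integers(2, 6).flatmap(lambda n: st.tuples(
    st.lists(st.floats(1.0, 99.0), min_size=n, max_size=n),
    st.lists(st.floats(0.05, 1.0), min_size=n, max_size=n))))
@settings(max_examples=150, deadline=None)
def test_expected_value_convex_and_permutation_invariant(means_weights):
    means, raw = means_weights
    total = sum(raw)
    props = [w / total for w in raw]
    props[-1] = 1.0 - math.fsum(props[:-1])
    val = lm.expected_value(means, props)
    assert min(means) - 1e-9 <= val <= max(means) + 1e-9
    perm = np.random.default_rng(0).permutation(len(means))
    val2 = lm.expected_value([means[i] for i in perm], [props[i] for i in perm])
    assert val2 == pytest.approx(val, abs=1e-9)


@pytest.mark.parametrize("sds, ns, props, exp_sd, exp_n", [
    ((5.0, 5.0), (4, 4), (0.5, 0.5), math.sqrt(12.5), 4),
    ((0.0, 0.0), (3, 3), (0.5, 0.5), 0.0, 3),
    ((6.0, 0.0), (3, 5), (0.5, 0.5), 3.0, 3),
])
def test_expected_dispersion(sds, ns, props, exp_sd, exp_n):
    sd, n = lm.expected_dispersion(sds, ns, props)
    assert sd == pytest.approx(exp_sd, abs=1e-10)
    assert n == exp_n


def test_build_pairs_counts(tiny_dataset):
    """One two-species mixture at one harvest with N everywhere gives one
    mass-loss pair and one N-release pair."""
    pairs, excl = lm.build_pairs(tiny_dataset)
    assert not excl
    by_resp = {p.response.value: p for p in pairs}
    assert set(by_resp) == {"mass_loss", "N_release"}
    ml = by_resp["mass_loss"]
    assert ml.expected_mean == pytest.approx(50.0)  # 0.5*40 + 0.5*60
    assert ml.observed_mean == pytest.approx(55.0)
    assert ml.expected_n == 4
    assert ml.expected_sd == pytest.approx(math.sqrt(0.25 * 16 + 0.25 * 36))


def test_build_pairs_mass_loss_only():
    pairs, _ = lm.build_pairs(make_tiny_dataset(with_nutrients=False))
    assert [p.response.value for p in pairs] == ["mass_loss"]


def test_build_pairs_nutrient_null_uses_nutrient_mass_weights(tiny_dataset):
    """Component releases are weighted by their share of the initial
    nutrient pool, not by dry-mass fractions."""
    pairs, _ = lm.build_pairs(tiny_dataset)
    nr = next(p for p in pairs if p.response.value == "N_release")
    # spA: c0=10, remaining = 12*0.6/10 = 0.72 -> release 28%
    # spB: c0=20, remaining = 25*0.4/20 = 0.50 -> release 50%
    # nutrient-mass weights: (0.5*10, 0.5*20)/15 = (1/3, 2/3)
    assert nr.expected_mean == pytest.approx(28.0 / 3 + 100.0 / 3, abs=1e-9)
    # dry-mass fallback weights evenly
    pairs_dm, _ = lm.build_pairs(tiny_dataset, null_weights="dry_mass")
    nr_dm = next(p for p in pairs_dm if p.response.value == "N_release")
    assert nr_dm.expected_mean == pytest.approx((28.0 + 50.0) / 2, abs=1e-9)


def test_build_pairs_missing_component_logged(tiny_dataset):
    """A mixture whose component lacks a single-species observation at the
    matching harvest is skipped with a logged reason, never silently."""
    ds = tiny_dataset
    ds.observations.drop(
        ds.observations.index[ds.observations["species_id"] == "spB"],
        inplace=True)
    pairs, excl = lm.build_pairs(ds)
    assert pairs == []
    assert any("missing single-species observation" in e["reason"]
               for e in excl)


def test_build_pairs_expected_matches_generator_truth(small_fixture):
    ds, truth = small_fixture
    pairs, _ = lm.build_pairs(ds)
    for p in pairs:
        if p.response is lm.Response.mass_loss:
            stored = truth["treatments"][p.treatment_id][
                "null_mass_loss_from_observed"][str(p.harvest_index)]
            assert p.expected_mean == pytest.approx(stored, abs=1e-12)
            assert p.expected_mass_loss == pytest.approx(stored, abs=1e-12)


def test_no_interaction_setting_gives_zero_mean_lnrr():
    """With all true effects and tau at zero the observed-expected contrast
    averages to ~0 lnRR."""
    cfg = lm.GeneratorConfig(seed=3, n_studies=40, tau=0.0,
                             true_effects={b: 0.0 for b in (
                                 "boreal", "temperate", "mediterranean",
                                 "subtropical", "tropical")})
    ds, _ = lm.generate(cfg)
    pairs, _ = lm.build_pairs(ds)
    evs, _ = lm.compute_effects(
        [p for p in pairs if p.response is lm.Response.mass_loss])
    mean = np.mean([e.lnrr for e in evs])
    assert abs(mean) < 0.01
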