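"""Rao divergence, windowed study effects, and moderator regressions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import littermeta as lm


@pytest.mark.parametrize("ti, tj, expected", [
    ((10.0,), (10.0,), 0.0),
    ((10.0,), (2.0,), 8.0),
    ((4.0, 6.0), (2.0, 10.0), 3.0),
])
def test_mean_character_difference(ti, tj, expected):
    assert lm.mean_character_difference(ti, tj) == pytest.approx(
        expected, abs=1e-10)


def test_mean_character_difference_rejects_mismatch():
    with pytest.raises(ValueError):
        lm.mean_character_difference((1.0,), (1.0, 2.0))


@pytest.mark.parametrize("values, props, expected", [
    ((10.0, 2.0), (0.5, 0.5), 2.0),
    ((7.0, 7.0, 7.0), (0.2, 0.3, 0.5), 0.0),
    ((10.0, 2.0), (0.75, 0.25), 1.5),
])
def test_rao_q(values, props, expected):
    assert lm.rao_q(values, props) == pytest.approx(expected, abs=1e-10)


def test_rao_q_missing_value_undefined():
    with pytest.raises(ValueError, match="missing trait"):
        lm.rao_q((10.0, float("nan")), (0.5, 0.5))


@given(st.integers(2, 6).flatmap(lambda n: st.tuples(
    st.lists(st.floats(0.1, 300.0), min_size=n, max_size=n),
    st.lists(st.floats(0.05, 1.0), min_size=n, max_size=n),
    st.floats(0.1, 10.0))))
@settings(max_examples=150, deadline=None)
def test_rao_q_brute_force_permutation_homogeneity(args):
    """Upper-triangle Rao equals the full ordered double sum halved, is
    permutation invariant, and scales linearly with trait units."""
    values, raw, scale = args
    total = sum(raw)
    props = [w / total for w in raw]
    props[-1] = 1.0 - math.fsum(props[:-1])
    rao = lm.rao_q(values, props)
    full = sum(abs(values[i] - values[j]) * props[i] * props[j]
               for i in range(len(values)) for j in range(len(values))
               if i != j)
    assert rao == pytest.approx(full / 2.0, rel=1e-9, abs=1e-12)
    perm = np.random.default_rng(1).permutation(len(values))
    assert lm.rao_q([values[i] for i in perm],
                    [props[i] for i in perm]) == pytest.approx(rao, rel=1e-9,
                                                               abs=1e-12)
    assert lm.rao_q([v * scale for v in values], props) == pytest.approx(
        rao * scale, rel=1e-9, abs=1e-12)


def _effect(study, lnrr, eml):
    labels = lm.GroupLabels(
        biome=lm.Biome.temperate, richness=2, evenness=lm.Evenness.equal,
        forest_type=lm.ForestType.natural, mesh_class=lm.MeshClass.one_to_two)
    return lm.EffectSize(lnrr=lnrr, variance=0.01, response=lm.Response.mass_loss,
                         study_id=study, treatment_id=f"{study}_M1",
                         harvest_index=0, is_final_harvest=True,
                         expected_mass_loss=eml, labels=labels)


def test_window_effect_per_study():
    effects = [_effect("S1", 0.08, 25.0),
               _effect("S2", 0.06, 15.0), _effect("S2", 0.10, 35.0),
               _effect("S3", 0.50, 9.0), _effect("S3", 0.50, 41.0)]
    out = lm.window_effect_per_study(effects)
    assert out["S1"] == pytest.approx(0.08)
    assert out["S2"] == pytest.approx(0.08)
    assert "S3" not in out  # both harvests fall outside 10-40%


def test_moderator_regression_exact_fit():
    r = lm.moderator_regression([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
    assert r.slope == pytest.approx(1.0, abs=1e-12)
    assert r.r_squared == pytest.approx(1.0, abs=1e-12)
    assert r.n_points == 3


def test_moderator_regression_flat_response():
    r = lm.moderator_regression([0.0, 1.0, 2.0, 3.0], [0.5, 0.5, 0.5, 0.5])
    assert r.slope == 0.0
    assert r.r_squared == 0.0


def test_moderator_regression_degenerate_x():
    with pytest.raises(ValueError, match="degenerate regressor"):
        lm.moderator_regression([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


def test_moderator_regression_matches_weighted_closed_form():
    rng = np.random.default_rng(8)
    x = rng.uniform(0, 4, 40)
    y = 0.03 * x + rng.normal(0, 0.05, 40)
    w = rng.uniform(0.5, 2.0, 40)
    r = lm.moderator_regression(x, y, weights=w)
    sw = w.sum()
    xm, ym = (w * x).sum() / sw, (w * y).sum() / sw
    slope = ((w * (x - xm) * (y - ym)).sum() / (w * (x - xm) ** 2).sum())
    assert r.slope == pytest.approx(slope, rel=1e-12)


def test_leverage_filter_drops_extreme_cluster():
    """The sensitivity harness removes high-leverage points and can change
    the fitted slope."""
    x = np.concatenate([np.linspace(0, 1, 20), [8.0, 8.2]])
    y = np.concatenate([np.zeros(20), [0.5, 0.55]])
    full = lm.moderator_regression(x, y)
    trimmed = lm.moderator_regression(x, y, exclude_leverage_above=4 / x.size)
    assert trimmed.n_points < full.n_points
    assert abs(trimmed.slope) < abs(full.slope)


def test_dataset_divergences_skips_missing_traits(small_fixture):
    ds, _ = small_fixture
    divs, log = lm.dataset_divergences(ds)
    # fixture_small forces one species' K and Ca to be missing
    assert any(e["trait"] in ("K", "Ca") for e in log)
    for tid, by_trait in divs.items():
        for trait, rao in by_trait.items():
            assert rao >= 0.0


def test_divergence_slope_recovery_small():
    """A configured divergence-effect slope is recovered by the regression
    harness (single mixture per study isolates the slope)."""
    cfg = lm.GeneratorConfig(
        seed=2, n_studies=40, biome_mix={"temperate": 1.0},
        true_effects={"temperate": 0.0}, tau=0.01, measurement_cv=0.05,
        richness_mix={2: 1.0}, mixtures_per_study_mean=1.0,
        divergence_slope={"N": 0.02})
    ds, _ = lm.generate(cfg)
    pairs, _ = lm.build_pairs(ds)
    evs, _ = lm.compute_effects(
        [p for p in pairs if p.response is lm.Response.mass_loss])
    weff = lm.window_effect_per_study(evs)
    divs, _ = lm.dataset_divergences(ds, traits=("N",))
    tid_by_study = {}
    for e in evs:
        if 10 <= e.expected_mass_loss <= 40:
            tid_by_study.setdefault(e.study_id, e.treatment_id)
    xs = [divs[tid_by_study[s]]["N"] for s in weff]
    ys = list(weff.values())
    r = lm.moderator_regression(xs, ys)
    assert r.slope == pytest.approx(0.02, abs=0.015)
    assert r.slope > 0
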