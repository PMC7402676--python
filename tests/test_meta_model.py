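"""Random-effects pooling, bootstrap CIs, and subgroup heterogeneity."""

import subprocess

import numpy as np
import pytest

import littermeta as lm
from littermeta.meta_model import _q_statistic, heterogeneity_partition


def test_dl_worked_example():
    """Two effects (0.2, 0.01), (0.0, 0.01): Q = 2, tau^2 = 0.01, RE mean 0.1."""
    effects = [(0.2, 0.01), (0.0, 0.01)]
    y = np.array([0.2, 0.0])
    v = np.array([0.01, 0.01])
    q, _ = _q_statistic(y, v)
    assert q == pytest.approx(2.0, abs=1e-12)
    tau2 = lm.dl_tau_squared(effects)
    assert tau2 == pytest.approx(0.01, abs=1e-12)
    assert lm.pooled_effect(effects, tau2) == pytest.approx(0.1, abs=1e-12)


def test_dl_zero_for_identical_effects():
    assert lm.dl_tau_squared([(0.1, 0.01)] * 5) == 0.0


def test_dl_single_effect_is_zero_with_warning(caplog):
    assert lm.dl_tau_squared([(0.3, 0.01)]) == 0.0


def test_dl_recovers_simulated_heterogeneity():
    rng = np.random.default_rng(11)
    v = np.full(50, 0.01)
    y = rng.normal(0.0, np.sqrt(v + 0.04))
    tau2 = lm.dl_tau_squared(np.column_stack([y, v]))
    assert 0.02 <= tau2 <= 0.06


def test_reml_close_to_dl_on_clean_data():
    rng = np.random.default_rng(5)
    v = np.full(200, 0.01)
    y = rng.normal(0.1, np.sqrt(v + 0.02))
    pairs = np.column_stack([y, v])
    assert lm.reml_tau_squared(pairs) == pytest.approx(
        lm.dl_tau_squared(pairs), abs=0.01)


@pytest.mark.parametrize("effects, tau2, expected", [
    ([(0.2, 0.01), (0.0, 0.01)], 0.01, 0.1),
    ([(0.42, 0.03)], 0.0, 0.42),
    ([(0.3, 0.01), (0.0, 0.04)], 0.0, 0.24),
])
def test_pooled_effect(effects, tau2, expected):
    assert lm.pooled_effect(effects, tau2) == pytest.approx(expected, abs=1e-12)


def test_pooled_effect_invariant_to_order_and_duplication():
    rng = np.random.default_rng(2)
    y = rng.normal(0.1, 0.1, size=12)
    v = rng.uniform(0.005, 0.02, size=12)
    pairs = np.column_stack([y, v])
    tau2 = lm.dl_tau_squared(pairs)
    base = lm.pooled_effect(pairs, tau2)
    perm = rng.permutation(12)
    assert lm.pooled_effect(pairs[perm], tau2) == pytest.approx(base, abs=1e-12)
    doubled = np.vstack([pairs, pairs])
    assert lm.pooled_effect(doubled, lm.dl_tau_squared(doubled)) == \
        pytest.approx(base, abs=1e-12)


def test_bootstrap_degenerate_identical_effects():
    ci = lm.bootstrap_ci([(0.1, 0.01)] * 8, reps=999, seed=0)
    assert ci == (pytest.approx(0.1), pytest.approx(0.1))


def test_bootstrap_deterministic_given_seed():
    rng = np.random.default_rng(4)
    pairs = np.column_stack([rng.normal(0.1, 0.1, 30),
                             rng.uniform(0.005, 0.02, 30)])
    a = lm.bootstrap_ci(pairs, reps=1999, seed=42)
    b = lm.bootstrap_ci(pairs, reps=1999, seed=42)
    assert a == b


def test_bootstrap_rejects_small_inputs():
    with pytest.raises(ValueError, match="single observation"):
        lm.bootstrap_ci([(0.1, 0.01)], reps=999, seed=0)
    with pytest.raises(ValueError, match="reps"):
        lm.bootstrap_ci([(0.1, 0.01)] * 5, reps=99, seed=0)


def test_bootstrap_ci_brackets_estimate():
    rng = np.random.default_rng(9)
    pairs = np.column_stack([rng.normal(0.05, 0.1, 40),
                             rng.uniform(0.005, 0.02, 40)])
    lo, hi = lm.bootstrap_ci(pairs, reps=1999, seed=1, method="percentile")
    est = lm.pooled_effect(pairs, lm.dl_tau_squared(pairs))
    assert lo <= est <= hi


def test_meta_analysis_direction_mapping():
    """CI excluding zero from above = synergistic; overlapping = additive."""
    rng = np.random.default_rng(3)
    strong = np.column_stack([rng.normal(0.2, 0.02, 30),
                              np.full(30, 0.0004)])
    res = lm.meta_analysis(strong, reps=999, seed=0)
    assert res.significant and res.direction is lm.Direction.synergistic
    null = np.column_stack([rng.normal(0.0, 0.1, 30), np.full(30, 0.01)])
    res0 = lm.meta_analysis(null, reps=999, seed=0)
    if not res0.significant:
        assert res0.direction is lm.Direction.additive


def test_subgroup_identical_groups_have_zero_q_between():
    effects = [(0.2, 0.01), (0.1, 0.02), (0.0, 0.01)] * 2
    labels = ["a"] * 3 + ["b"] * 3
    res = lm.subgroup_analysis(effects, labels, reps=999, seed=0)
    assert res.q_between == pytest.approx(0.0, abs=1e-10)
    assert res.df_between == 1


def test_q_partition_matches_brute_force():
    """Q_between from the partition equals the direct weighted sum of squared
    group-mean deviations about the grand mean (fixed-effect weights)."""
    rng = np.random.default_rng(21)
    y = rng.normal(0.1, 0.15, 30)
    v = rng.uniform(0.004, 0.03, 30)
    labels = np.array(["g1"] * 10 + ["g2"] * 12 + ["g3"] * 8)
    q_total, q_between, q_within, df_b, df_w = heterogeneity_partition(
        y, v, labels)
    w = 1.0 / v
    grand = np.sum(w * y) / np.sum(w)
    qb_direct = 0.0
    for g in ("g1", "g2", "g3"):
        m = labels == g
        gm = np.sum(w[m] * y[m]) / np.sum(w[m])
        qb_direct += np.sum(w[m]) * (gm - grand) ** 2
    assert q_between == pytest.approx(qb_direct, abs=1e-8)
    assert q_total == pytest.approx(q_between + q_within, abs=1e-8)
    assert df_b + df_w == y.size - 1


def test_subgroup_detects_true_difference():
    """Groups with true means 0.10 vs 0.00 (v = 0.005, k = 40) separate at
    p < 0.05 in at least 90% of seeds."""
    hits = 0
    n_seeds = 40
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        y1 = rng.normal(0.10, np.sqrt(0.005), 40)
        y2 = rng.normal(0.00, np.sqrt(0.005), 40)
        effects = [(float(x), 0.005) for x in np.concatenate([y1, y2])]
        labels = ["a"] * 40 + ["b"] * 40
        res = lm.subgroup_analysis(effects, labels, reps=999, seed=seed)
        hits += res.p_between < 0.05
    assert hits >= 0.9 * n_seeds


def test_subgroup_singleton_group_flagged():
    effects = [(0.2, 0.01), (0.1, 0.01), (0.15, 0.01), (0.3, 0.02)]
    labels = ["a", "a", "a", "b"]
    res = lm.subgroup_analysis(effects, labels, reps=999, seed=0, min_k_ci=2)
    assert res.groups["b"].low_n
    assert res.groups["b"].ci_low is None
    assert not res.groups["a"].low_n


def test_dl_and_pooled_match_metafor():
    """Cross-check the DerSimonian-Laird estimates against metafor (R)."""
    y = [0.35, -0.10, 0.22, 0.05, 0.48, 0.02, 0.18, -0.25]
    v = [0.010, 0.020, 0.008, 0.015, 0.025, 0.012, 0.030, 0.018]
    script = (
        "suppressMessages(library(metafor));"
        f"yi <- c({','.join(map(str, y))});"
        f"vi <- c({','.join(map(str, v))});"
        'fit <- rma(yi=yi, vi=vi, method="DL");'
        'cat(sprintf("%.12f %.12f", fit$tau2, as.numeric(fit$beta)))'
    )
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, check=True)
    tau2_r, beta_r = map(float, out.stdout.split())
    pairs = list(zip(y, v))
    tau2 = lm.dl_tau_squared(pairs)
    assert tau2 == pytest.approx(tau2_r, abs=1e-8)
    assert lm.pooled_effect(pairs, tau2) == pytest.approx(beta_r, abs=1e-8)
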