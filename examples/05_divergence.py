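"""Trait divergence and the mixture effect: recovering a built-in slope.

Each mixture's nitrogen divergence is Rao's quadratic entropy of the
component species' initial N concentrations. The generator adds 0.02 lnRR
per unit Rao(N); the regression of study-averaged in-window effects on
divergence should recover that slope.
"""

import numpy as np

import littermeta as lm

cfg = lm.GeneratorConfig(
    seed=1, n_studies=60, biome_mix={"temperate": 1.0},
    true_effects={"temperate": 0.0}, tau=0.01, measurement_cv=0.05,
    richness_mix={2: 1.0}, mixtures_per_study_mean=1.0,
    divergence_slope={"N": 0.02})
ds, truth = lm.generate(cfg)
pairs, _ = lm.build_pairs(ds)
effects, _ = lm.compute_effects(
    [p for p in pairs if p.response is lm.Response.mass_loss])

window_eff = lm.window_effect_per_study(effects)  # 10-40% null mass loss
divs, _ = lm.dataset_divergences(ds, traits=("N",))
tid_by_study = {e.study_id: e.treatment_id for e in effects}
x = [divs[tid_by_study[s]]["N"] for s in window_eff]
y = list(window_eff.values())

r = lm.moderator_regression(x, y)
print(f"studies with in-window effects: {r.n_points}")
print(f"fitted slope : {r.slope:+.4f} lnRR per unit Rao(N)  (true +0.0200)")
print(f"r^2 = {r.r_squared:.3f}, p = {r.p_value:.2g}")
print("\nThe slope says how much faster-than-additive decomposition gets per")
print("unit of within-mixture nitrogen divergence (mg g^-1 scale).")
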