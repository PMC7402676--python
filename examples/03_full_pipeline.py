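"""The full pipeline on a miniature synthetic dataset.

fixture_small() builds three temperate studies of two-species mixtures with
two harvests and full N chemistry, including an early-harvest immobilization
case. run() takes the dataset to a complete report: pairs, effect sizes,
overall and per-biome pooling, staging, regressions, nutrient summaries.
"""

import littermeta as lm

ds, truth = lm.fixture_small(seed=0)
report = lm.run(ds, lm.RunConfig(seed=1, bootstrap_reps=1999))

c = report["counts"]
print(f"mixture observations: {c['mixture_observations']}")
print(f"pairs built: {c['pairs_built']}")
print(f"final-harvest effects: {c['effects_final_harvest']}")
print(f"all-harvest staging exclusions (immobilized N pairs cannot enter a "
      f"log ratio): {c['staging_effect_exclusions']}")

ml = report["overall"]["mass_loss"]
print(f"\noverall mass-loss effect: lnRR {ml['pooled_lnrr']:+.3f} "
      f"({ml['percent_effect']:+.1f} %), CI [{ml['ci_low']:+.3f}, "
      f"{ml['ci_high']:+.3f}] -> {ml['direction']}")
print(f"configured true effect was lnRR +0.08; every observation is")
print(f"accounted for as analyzed or excluded-with-reason.")
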