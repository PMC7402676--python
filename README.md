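# littermeta

Meta-analysis of **non-additive litter-mixture decomposition effects** in
forest ecosystems: from litterbag observations to additive-null
expectations, log-response-ratio effect sizes, random-effects pooling with
bootstrap confidence intervals, decomposition-stage analysis, and
trait-divergence regressions — with a synthetic-data generator so every step
can be exercised and validated against known ground truth without any
external download.

## The scientific problem

When leaf litters of several species decompose together, mass loss and
nutrient release often deviate from what the component species' individual
decay rates predict. Quantifying that deviation across many field studies is
a meta-analytic problem. For each mixture × harvest the package builds the
additive null

&nbsp;&nbsp;&nbsp;&nbsp;X̄_c = Σᵢ pᵢ·xᵢ

(the mass-proportion-weighted mean of the component species' single-species
responses; nutrient nulls weight by the initial nutrient pool), and scores
the mixture by the log response ratio with its sampling variance

&nbsp;&nbsp;&nbsp;&nbsp;lnRR = ln(X̄_e / X̄_c),&nbsp;&nbsp;
v = s_e²/(N_e·X̄_e²) + s_c²/(N_c·X̄_c²).

lnRR > 0 is synergy (faster than predicted), lnRR < 0 antagonism. Effect
sizes are pooled with the DerSimonian–Laird random-effects model; 95%
confidence intervals are bias-corrected bootstrap intervals (observation-
level resampling, τ² re-estimated per replicate). Categorical moderators
(biome, species richness, evenness, deciduous/evergreen composition, forest
type and stand structure, litterbag mesh class) are tested by partitioning
the heterogeneity Q into between- and within-group parts under fixed-effect
weights. Decomposition stage is handled by binning all-harvest pairs into
10% intervals of the *null* mass loss; chemical divergence within mixtures
is Rao's quadratic entropy Rao = Σ_{i<j} d_ij·pᵢ·pⱼ with d_ij the mean
absolute character difference, regressed against study-averaged effects by
OLS.

Intended users: ecologists and biostatisticians analysing litterbag
mixture experiments or reanalysing curated decomposition corpora.

## Worked example

```python
import littermeta as lm

expected = lm.expected_value([40.0, 60.0], [0.5, 0.5])   # 50.0 % mass loss
lnrr = lm.ln_response_ratio(55.0, expected)              # 0.0953
lm.percent_effect(lnrr)                                  # +10.0 %

effects = [(0.21, 0.010), (-0.05, 0.020), (0.13, 0.008),
           (0.02, 0.015), (0.30, 0.025), (0.11, 0.012)]
tau2 = lm.dl_tau_squared(effects)                        # 0.0000
pooled = lm.pooled_effect(effects, tau2)                 # 0.1231
lm.bootstrap_ci(effects, reps=4999, seed=1)              # (0.0441, 0.1888)
```

The pooled lnRR of 0.123 back-transforms to a +13.1% mixture effect; the
bootstrap CI excludes zero, so the set of mixtures decomposed synergistically.
The `examples/` directory holds five short scripts — effect sizes, pooling
and subgroups, the full pipeline on a miniature dataset, stage localisation,
and divergence-slope recovery — each printing the numbers it computes with a
note on what they mean.

Whole datasets go through the pipeline in one call (or via the CLI):

```python
ds, truth = lm.generate(lm.GeneratorConfig(seed=1))      # 65 synthetic studies
report = lm.run(ds, lm.RunConfig(seed=1))
report["overall"]["mass_loss"]["percent_effect"]         # +4.8 %
```

```bash
litter-mixmeta generate --out data/ --seed 1
litter-mixmeta run --data data/ --out report/ --seed 1
```

Real data enter as four CSV tables (studies, species, observations,
compositions) documented in `littermeta.records_io`; every row excluded at
any step is logged with a reason, never dropped silently.

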