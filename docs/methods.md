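# Methods

## Analysis variables

All responses are normalised to three variables. **Mass loss** (% of initial
dry mass) is taken as reported, converted from mass remaining
(`100 − remaining`), or from a single-pool negative-exponential decay
constant k (per year) via `(1 − e^(−k·t))·100`; double-pool fits are out of
scope and such studies must supply mass loss directly. **Relative nutrient
release** is `(1 − R)·100` where R is the remaining fraction of the initial
nutrient amount; **absolute release** is `conc₀·(1 − R)` in mg per g initial
litter. R defaults to the amount-based budget
`(conc_t · mass-remaining fraction) / conc₀`; a configuration switch
(`nutrient_mode="concentration_based"`) uses the bare concentration ratio
`conc_t / conc₀` instead, for sources that define release that way. R > 1 is
net immobilization; such observations carry negative release and are valid
data, but cannot enter a log ratio and are therefore excluded from nutrient
meta-analyses with a counted reason (they do enter the descriptive
mixture-vs-single release summaries).

## Additive null and pairing

The expected ("control") value of a mixture response is the
mass-proportion-weighted mean of the component species' single-species
values at the **same sampling occasion** (matching by harvest index, never by
interpolating times). For nutrient release the components are weighted by
their share of the mixture's initial nutrient pool, pᵢ·conc₀ᵢ / Σⱼ pⱼ·conc₀ⱼ
— a dimensionally consistent nutrient budget — with a dry-mass fallback
switch. The dispersion of the composite expectation is propagated under
component independence, sd_c = √(Σ pᵢ²·sdᵢ²), and its sample size is the
conservative minimum of the component replicate counts; both are declared
conventions, since no standard exists for composite "control" summaries.
Sources reporting standard errors are converted on read (sd = se·√n).

## Effect sizes

lnRR = ln X̄_e − ln X̄_c with sampling variance
s_e²/(N_e·X̄_e²) + s_c²/(N_c·X̄_c²), the delta-method variance of a log ratio
of independent group means. No small-sample bias correction is applied.
Results are reported on the percent scale (e^lnRR − 1)·100. Pairs with a
non-positive mean on either side are excluded with a logged reason —
offsetting values would bias the ratio.

## Random-effects pooling and bootstrap intervals

Between-observation variance τ² uses the DerSimonian–Laird moment estimator
(REML available behind a flag); the pooled effect is the inverse-variance
weighted mean with weights 1/(vᵢ + τ²). 95% CIs are nonparametric bootstrap
intervals: effects are resampled with replacement at the observation level,
τ² and the pooled effect recomputed per replicate (fully vectorised), and
the interval read off the replicate distribution with the bias-corrected
percentile adjustment (plain percentile available). Defaults: 4999
replicates, explicit seed, deterministic output. Observations are treated as
independent; no study-level nesting is modelled.

Known property: percentile-family bootstrap intervals of a pooled weighted
mean are mildly liberal at small k (measured ≈8–9% type-I at k ≈ 20–50 on
ideal normal effects, ≈5–6% at k ≥ 100). At the corpus scale of the overall
analyses (k ≈ 300) calibration is nominal (measured 3% over 200 null runs).

## Subgroup heterogeneity

Q statistics use fixed-effect weights 1/vᵢ so that
Q_total = Q_between + Q_within holds exactly; p_between comes from χ² with
(groups − 1) df. Per-group pooled effects use random-effects weights with a
single within-group pooled τ² (the classical mixed-model convention). The
joint bootstrap resamples every group per replicate and re-estimates the
pooled τ² from the whole resample, so the per-group intervals share the
variance structure. Groups below the configurable floor (default k < 3) are
reported flagged, point estimate only. No multiplicity correction is applied
across subgroups; inference is per-CI, deliberately.

## Decomposition staging

All-harvest pairs are binned by their **additive-null** mass loss (so stage
assignment is independent of the effect being estimated) into half-open 10%
intervals [0,10) … [60,70) plus a closed terminal 70–100 bin, and each bin
is pooled as its own meta-analysis. A study legitimately appears in several
bins through successive harvests; an option collapses multiple same-bin
harvests of one study to their mean. Empty bins are reported with k = 0,
singleton bins flagged.

Structural caveat: because the binning covariate (the expected value) is
noisy and also forms the lnRR denominator, the edge bins acquire a
regression-to-the-mean bias under the null — pairs that fluctuate into the
bottom bin have inflated lnRR (measured mean z ≈ +0.7 in the 0–10 bin of
null simulations) and the top bin the reverse. Interior bins cancel by
symmetry. This is a property of the staging procedure itself, inherited by
any analysis that bins on a noisy expected value; stage-edge significance
should be read with this in mind.

## Trait divergence and moderator regressions

Within-mixture divergence of one trait is Rao's quadratic entropy, the
upper-triangle sum Σ_{i<j} d_ij·pᵢ·pⱼ with d_ij the mean absolute character
difference — one trait at a time (n = 1), so d_ij is |Xᵢ − Xⱼ| in the
trait's units; absolute values are used because d_ij is a distance. A
missing trait value in any component leaves that trait's divergence
undefined for the treatment (logged, excluded from that regression only).
Mixture effects for the divergence regressions are study means of lnRR
inside the 10–40% null-mass-loss window (the stage with the strongest
non-additive signal); studies with several in-window mixtures contribute the
mean divergence of those mixtures. Regressions are unweighted OLS (slope,
r², two-sided slope p); inverse-variance weighting is available behind a
flag, and a leverage filter (hat values above a threshold) re-runs any
regression without clusters of extreme moderator values as a sensitivity
check. Climate regressions (MAT, MAP) use one point per final-harvest paired
observation.

## Categorical groupings

Mesh classes are <1 mm, [1, 2] mm (closed, so the classes partition the
line), >2 mm. Evenness is equal iff all proportions agree within 1e-9.
Functional composition is deciduous-only / evergreen-only / mixed;
stand structure is canopy-only (all trees) vs any shrub/herb present;
components with unknown habit or life form drop the treatment from those
groupings only, with a log entry. Screening decisions of the source corpus
(one condition per species combination, ambient treatments) are represented
by a pre-curated `selected` flag on studies — flagged-out rows are retained
in the tables and excluded from analysis, never re-derived or dropped.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
any real dataset's values. Defaults describe the target corpus shape: 65
studies across five forest biomes (boreal 7%, temperate 42%, mediterranean
8%, subtropical 25%, tropical 18%), ≈4.4 mixture treatments per study
(≈280 final-harvest mixture observations), richness mix 2:3:4:6 species =
69:14.5:12:4.5%, 79% equal-proportion mixtures, mesh apertures
{0.5, 1, 2, 4} mm at 22/10/35/33%, harvest schedules of 1–4 occasions from
{91, 182, 365, 730} days (≈2.3 harvests per treatment), 4 replicate bags,
10% replicate-level CV. Species traits are drawn per leaf habit with
evergreens higher in lignin, lignin:N and C:N; decay constants decrease in
lignin:N scaled by a biome base rate; initial N ≈ 9–12 mg/g and
P ≈ 0.4–0.6 mg/g so that synthetic release magnitudes sit near the corpus's
reported averages.

Mechanics chosen for testability: reported means carry multiplicative
lognormal error (positivity preserved, as the log ratio requires; means
truncated at 99.5% loss); the observed mixture mass loss is the additive
null times e^θ whenever the true null mass loss lies inside the interaction
window, with θ = biome effect + N(0, τ²) + Σ β_trait·Rao_trait drawn **per
mixture treatment**, so the configured θ is the true lnRR by construction
and observations are independent (the pooling model's own assumption;
drawing θ per study and sharing it across that study's mixtures would
correlate observations and invalidate the independence-based variance).
Consequences: component species are not shared between treatments, so the
synthetic corpus has more distinct species than a real one; there is no
study-level clustering, spatial structure, or publication bias. Passing
recovery tests therefore validate the estimators under the model's stated
assumptions — they say nothing about robustness to violations of
independence in real corpora. Nutrient remaining fractions follow an
immobilization-then-release trajectory
R(t) = (1 + A·s·e^(1−s))·e^(−r·k·t), s = t/T (early hump above one, then
release proportional to the litter's own decay rate); mixture effects on
nutrients multiply the positive part of release only. Ground truth
(per-treatment θ, null trajectories from both true and observed component
means, per-interval mean applied effect, configured slopes) is stored next
to the tables.

Simulation scales used by the test suite — 200 null runs at 80 studies for
bootstrap calibration, 100 studies for biome recovery, 100 null runs for
stage rates, 60 single-mixture studies for slope recovery — keep the full
suite around one minute while leaving Monte-Carlo error well below the
tolerances tested. The slope-recovery oracle uses one mixture per study
because with several, study-averaging weights treatments by their in-window
harvest counts in the response but not in the moderator, and the regression
estimand is then no longer the configured slope.

## Numerical and degenerate-input choices

Proportions must sum to 1 within 1e-9; compositions need ≥2 components.
τ² is clipped at 0; k < 2 yields τ² = 0 with a logged warning and no
bootstrap ("cannot bootstrap a single observation"). Bootstrap replicate
counts below 999 are rejected (unstable 2.5% tails). Degenerate resampling
(all effects identical) returns a point interval. A flat regression response
returns slope 0, r² = 0; a constant moderator is an error. Pair-level
degeneracy (zero variance on both sides) is an error naming the pair. JSON
reports serialise with sorted keys; identical config + seed ⇒ byte-identical
output.

## Known limitations

No multi-level or robust-variance meta-analysis; no publication-bias
diagnostics; no refitting of decay curves from time series; no phylogenetic
correction or multivariate trait ordination; single-pool decay only. The
"final harvest" flag is taken as given in the input rather than re-derived.
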