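# Methods

This note records the statistical model, the defaults and the design
choices behind `decompmeta`, in the order data flow through the
pipeline.

## Data model

The unit of observation is a treatment-level summary: mean decay,
within-treatment SD across replicates, and replicate count for one
inoculum treatment at one study × litter type × time point cell.
Dispersion is stored canonically as SD; files may declare SE per row or
for the whole file, converted on read via sd = se·√n. Decay is either
mass loss (% of initial mass, constrained to [0, 100]) or cumulative
CO₂-C (mg g⁻¹ litter, non-negative); the two response families are
never mixed within a cell. A cell with a single treatment carries no
information about inoculum effects and is dropped with a warning.
Time is stored in days since decomposition began; no date handling.

## Effect sizes

Per cell with k ≥ 2 treatment means:

- CV = sample SD of the treatment means (n−1 denominator) divided by
  their mean. The sample SD is used rather than the population SD
  because k is typically 2–6; the choice is visible and consistent
  everywhere, including the synthetic generator, so it cancels in
  recovery checks.
- D = mean pairwise |difference| over the k(k−1)/2 unordered pairs.
  For scalar decay values the Euclidean distance degenerates to the
  absolute difference.

Degenerate cells: CV is undefined as the grand mean approaches zero;
cells with grand mean ≤ 1e−8 (response units) raise a
`DegenerateCellError` and are excluded and logged — never silently
zeroed. D has no such degeneracy and is still emitted.

Sampling variances use a parametric bootstrap (default `n_boot = 2000`,
minimum 100): each treatment mean is redrawn from N(mᵢ, sdᵢ²/nᵢ)
truncated at zero (decay responses cannot be negative; truncation also
keeps the bootstrap CV defined), the metric is recomputed per
replicate, and the sample variance of replicates is returned. A
bootstrap rather than a delta method because it is metric-agnostic and
correct for the non-smooth |·| in D near ties. Replicates whose grand
mean is degenerate are dropped; if all are, the cell errors out.
Per-cell random streams are derived from the root seed plus a CRC of
the cell key, so results are reproducible and *local*: removing one
study never changes another study's records.

Two auxiliary tables reuse the same machinery:

- litter-type CV: per study × time × response with ≥ 2 litter types,
  treatment means are averaged within each litter type and the CV is
  taken across litter-type means — the litter-chemistry analogue of the
  inoculum CV. Single-litter studies are skipped with a log notice.
- time-integrated effect sizes: one record per study × litter ×
  response. Default reading ("mean_trajectory"): each treatment's
  means are averaged over its time points (unweighted) and the metric
  is computed across those time-averaged values. The alternative
  reading — the mean of per-time CVs ("mean_of_cvs") — is available via
  `EffectConfig.time_integration`; the two coincide for single-time
  studies and for trajectories constant in time. The trajectory-first
  reading is the default because it treats the treatment, not the
  time point, as the unit being integrated.

## Multilevel pooling

Model: y_ij = x_ij′β + u_i + w_ij + e_ij with u_i ~ N(0, τ²_between)
per study, w_ij ~ N(0, τ²_within) per observation and e_ij ~ N(0, v_ij)
with v_ij the known (bootstrap) sampling variance. Both variance
components are on by default: studies contribute repeated, correlated
observations (time points, litter types), which is exactly what the
observation-level component absorbs. It can be disabled
(`tau2_within=0`, or `observation_level_component: false` in the
pipeline config) and the choice is echoed in the report metadata.

Estimation is REML. The marginal covariance is block-diagonal by study
with a rank-one (compound-symmetry) update per block, so the restricted
likelihood is accumulated per study via the Sherman–Morrison identity —
O(n) per evaluation, no dense factorisation. Free components are
optimised on the log-variance scale by L-BFGS-B from 5 dispersed starts
(objective tolerance 1e−12, bounds e^−27.6…e^13.8); after optimisation
the exact τ² = 0 boundary candidates are evaluated and kept if better,
since a log-scale search can only approach the boundary. Fixed effects
are the GLS solution at the optimum; Wald z tests with a normal
reference and 95% CI = ±1.96·SE (no Knapp–Hartung adjustment). With
both components fixed at zero the fit reduces exactly to the
inverse-variance weighted mean.

Numerical guards: sampling variances below 1e−10 are floored with a
warning (degenerate bootstrap variances would otherwise produce
infinite weights); rank-deficient designs raise an error naming the
aliased columns; constant moderators are rejected before fitting.

Subgroup analyses use a no-intercept (cell-means) design so each
observed level gets its own pooled estimate and CI; the omnibus Q_M
statistic is a Wald chi-square on successive level differences
(df = levels − 1). Levels with fewer than 2 effects are reported but
flagged `low_k`. Meta-regressions fit intercept + slope; moderators may
live at the study level (C:N, lignin, richness, treatment count) or at
the effect level (time_days); missing moderators drop rows listwise,
model by model.

Outlier screening: standardized residuals
(y − pooled)/√(v + τ²_w + τ²_b) from the intercept-only fit; |z| > 3
flags the record; flagged records are excluded and the model refit
once. One pass only — no iterative re-screening — and the flagged ids,
threshold and counts appear in every report. With few effects an
extreme point inflates τ² enough to partially mask itself; the
single-pass rule accepts this in exchange for transparency.

## Mantel tests

Within one study, treatments are compared in ordination space (NMDS or
PCA axes 1–2 — coordinates are meaningful only within a study, so no
cross-study comparison is attempted) and in decay. Euclidean distance
matrices are built for both; r is the Pearson correlation of the upper
triangles (Spearman behind a flag); p comes from randomly permuting one
matrix's labels, p = (1 + #{r_perm ≥ r_obs})/(n_perm + 1), default
n_perm = 9999. The default alternative is one-sided upper-tail — the
scientific hypothesis is that more dissimilar communities produce more
dissimilar function — so strongly negative r yields p near 1. Two-sided
is available. When a study reports several time points the final one is
used (configurable); with several litter types, treatment means are
averaged across litters first. Mantel needs ≥ 3 treatments; smaller
studies are skipped and logged, and mismatched treatment identifiers
raise an alignment error listing the offenders.

## Synthetic-data generator

The generator inverts the analysis model. Each cell's true effect is
θ_ij = μ + u_i + w_ij + moderator terms (u_i ~ N(0, τ²_between),
w_ij ~ N(0, τ²_within)); the cell's k treatment means are
grand_mean·(1 + θ_ij·c) with c a standardized contrast (zero mean, unit
sample SD), so the sample CV of the constructed means equals θ_ij
*exactly*. Reported means then get replicate noise N(0, σ²/n) and
reported SDs are drawn from the sampling distribution of a sample SD
(σ·√(χ²_{n−1}/(n−1))). With all noise at zero every computed CV equals
μ exactly, making the generator a direct oracle for the effect-size and
pooling stages.

Defaults describe a realistic compiled corpus of litter-inoculation
experiments: 36 studies; 2–6 inoculum treatments; one litter type for
most studies with a one-in-six minority crossing 2–3 litter types; 1–5
time points between day 14 and day 540; 3–10 replicates; ~70%
mass-loss studies (grand mean 25% of initial mass) and ~30% CO₂
studies (grand mean 18 mg CO₂-C g⁻¹); μ = 0.20, τ_between = 0.07,
τ_within = 0.05, replicate SD 2.0 response units. This yields ~135–140
effect-size cells per dataset. Two structural features of real
experiments are built in deliberately:

- litter chemistry shifts each litter type's overall decay level
  (relative SD `litter_effect_cv = 0.25`), so the across-litter CV is
  of the same order as the inoculum CV rather than an artefact of pure
  sampling noise;
- the treatment contrast pattern is drawn once per study × litter and
  reused across its time points (fast inocula stay fast), so
  time-integrated effect sizes are commensurate with per-time ones
  instead of cancelling.

Moderator effects are injected on the θ scale: `"column:level"` keys
add categorical offsets, bare column names act as slopes on the numeric
moderator. Truncation is by rejection-resampling (θ ≥ 1e−3, positive
treatment means, mass loss ≤ 100%), with a warning if clamping is ever
forced.

What the generator does **not** emulate: decay kinetics (no
exponential-decay trajectories — cell grand means are exchangeable over
time), litter × inoculum interactions (home-field advantage), non-normal
replicate error, correlated sampling errors between treatments sharing
a control, or publication bias. Passing recovery tests therefore shows
the estimator chain is correct under the assumed variance structure,
not that real compiled datasets satisfy that structure.

The companion generator for community–function pairs places a latent
function-relevant axis on ordination axis 1 and scales the variance of
axis 2 by (1 − coupling). At coupling 1 with zero noise the community
and decay distance matrices are exactly proportional and Mantel r = 1;
a free 2-D score cloud projected to 1-D could never achieve that, which
is why the off-axis variance is tied to the coupling rather than left
free.

## Pipeline and reproducibility

One root seed is expanded per stage (effects, litter CV,
time-integration, Mantel) through hashed seed sequences; reruns with
the same config are byte-identical in `report.json` (the config echo
omits the output directory; timestamps live only in `pipeline.log`).
Every exclusion — degenerate cells, single-treatment cells, flagged
outliers, skipped Mantel studies — is logged and the outlier exclusions
are tabulated in `exclusions.csv`.

The default report contains three intercept-only pools (CV across all
studies; D_ML and D_CO2 in separate models), four subgroup tables
(setting, environment, inoculum complexity, inoculum taxa), five
meta-regressions (maximum richness, decomposition length, litter C:N,
lignin, number of inoculum treatments), the litter-type CV fit, the
time-integrated sensitivity fit, and the Mantel section (marked
"skipped" when no ordination scores are supplied).

`scripts/acceptance.py` runs this pipeline on the default scenario at a
given seed; the simulation sizes there (36 studies, ~140 cells, 2000
bootstrap replicates, 9999 permutations) are the package defaults. The
test suite's recovery checks use 100–200 replicate datasets at the same
defaults — enough that the Monte-Carlo error on a coverage proportion
(±2% at 200 replicates) is well inside the asserted bands.

## Known limitations

- The bootstrap sampling variance treats reported SDs as known; very
  small replicate counts make v_ij noisy, and the variance floor
  (1e−10) only guards against exact zeros.
- The REML engine supports two nested variance components (study,
  observation); no crossed random effects, no robust (sandwich) SEs,
  no Knapp–Hartung small-sample adjustment.
- The outlier rule (|z| > 3, one pass) is a convention; results should
  be read alongside the reported exclusion list.
- Mantel tests use whatever ordination scores are supplied; two axes
  rarely capture full community dissimilarity, so weak r values are not
  evidence of functional redundancy by themselves.
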