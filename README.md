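# decompmeta

Multilevel meta-analysis of microbial **inoculum effects** on plant-litter
decomposition.

Litter-inoculation experiments sterilize a standard litter substrate,
re-inoculate it with two or more distinct microbial assemblages (single
strains, defined consortia, or whole-soil communities) and track decay —
mass loss as % of initial mass, or cumulative CO₂-C evolution. The question
such experiments answer is whether the *composition* of the decomposer
community matters for the *rate* of a core ecosystem function. `decompmeta`
provides the statistical machinery to synthesize many such experiments:
effect sizes that quantify cross-treatment variability in decay, multilevel
random-effects pooling of those effect sizes, moderator and subgroup
analyses, and within-study Mantel tests linking community dissimilarity to
functional dissimilarity. A built-in synthetic-data generator with known
ground truth makes every stage testable end to end.

It is aimed at soil ecologists and meta-analysts working with
treatment-level summary data (means, SDs or SEs, replicate counts) extracted
from published decomposition experiments.

## The statistics

**Effect sizes.** For each study × litter type × time point cell with
treatment means m₁…m_k (k ≥ 2):

- *CV* = s(m) / m̄, the sample SD (n−1 denominator) of the treatment means
  over their mean. Unitless, hence comparable across studies regardless of
  how decay was measured.
- *D* = 2/(k(k−1)) · Σ_{i<j} |mᵢ − mⱼ|, the mean pairwise Euclidean distance
  among treatment means, in response units. Mass-loss studies (D_ML, % of
  initial mass) and CO₂ studies (D_CO2, mg CO₂-C g⁻¹ litter) are pooled in
  separate models because their units differ.

Sampling variances come from a parametric bootstrap: each treatment mean is
redrawn from N(mᵢ, sdᵢ²/nᵢ) truncated at zero, the metric is recomputed, and
the variance over 2000 replicates is taken. The bootstrap is metric-agnostic
and handles the non-smooth |·| in D.

**Pooling.** Effect sizes y_ij (effect j in study i) with known sampling
variances v_ij are combined in the multilevel random-effects model

    y_ij = x_ij′β + u_i + w_ij + e_ij,
    u_i ~ N(0, τ²_between),  w_ij ~ N(0, τ²_within),  e_ij ~ N(0, v_ij),

with study identity as the grouping factor (experiments contribute several
correlated observations across time points and litter types). Variance
components are estimated by REML with multi-start optimisation; fixed
effects are the GLS solution; inference uses Wald z tests with 95% CI =
estimate ± 1.96·SE. Subgroup analyses use a cell-means parameterisation with
an omnibus Q_M test of level equality; meta-regressions fit intercept +
slope. Standardized-residual outliers (|z| > 3 against √(v + τ²_w + τ²_b))
are excluded in one pass before the final fit.

**Community–function correspondence.** Within a study, treatments are
compared in ordination space (NMDS/PCA axes 1–2) and in decay: a Mantel
permutation test correlates the two distance matrices, one-sided upper tail
by default (p = (1 + #{r_perm ≥ r_obs}) / (n_perm + 1)).

## Worked example

Simulate the default 36-study scenario (true mean CV 0.20, between-study SD
0.07) and run the full analysis:

```bash
decompmeta simulate --seed 11 --out demo
decompmeta all --summaries demo/summaries.csv \
               --moderators demo/moderators.csv \
               --seed 11 --out demo_report
# report written to demo_report/report.json
# pooled CV = 0.174 (SE 0.012, p = 8.58e-48)
```

`demo_report/report.json` holds every fit. For this seed the headline
numbers are:

| quantity | estimate | meaning |
|---|---|---|
| pooled CV | 0.174 ± 0.012 (k = 132) | decay varies by ~17% of its mean across inocula |
| pooled D_ML | 5.45 ± 0.54 (k = 92) | ≈ 5.5% of initial mass separates inoculum treatments |
| pooled D_CO2 | 3.74 ± 0.43 (k = 40) | ≈ 3.7 mg CO₂-C g⁻¹ between treatments |
| litter-type CV | 0.253 | litter chemistry effect, same scale as inoculum CV |
| time-integrated CV | 0.169 | sensitivity: one CV per study × litter, trajectories time-averaged |

The subgroup table for field vs laboratory studies (`subgroup_setting.csv`)
shows overlapping CIs (field 0.171 [0.138, 0.204], laboratory 0.177
[0.142, 0.211], Q_M p = 0.82), and the meta-regression of CV on
decomposition length finds no trend (β = 3.5e-05, p = 0.32) — as expected,
since the generator ties neither moderator to the true effects.

Each pipeline stage is also exposed on its own (`decompmeta effects`,
`fit`, `subgroups`, `metareg`, `mantel`) and as library functions
(`compute_effect_table`, `fit_random_effects`, `mantel_test`, …).

## Input format

Two CSV files. `summaries.csv`: one row per study × litter × time ×
inoculum treatment with columns `study_id, litter_id, time_days,
treatment_id, response_type {mass_loss_pct | co2_cum_mg_per_g}, mean,
dispersion, dispersion_type {sd|se}, n`. SE dispersions are converted to SD
(sd = se·√n) on read. `moderators.csv`: one row per study with setting
(field/laboratory), environment (terrestrial/freshwater), inoculum
complexity (reduced/whole_community), inoculum taxa (bacteria/fungi/both),
maximum inoculum richness (reduced-complexity designs only), litter C:N,
lignin %, and the number of inoculum treatments. Empty cells are missing
values; moderator analyses drop them listwise.

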