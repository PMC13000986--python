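# Methods

This note documents the statistical machinery, the choices made where the
design was genuinely open, and what the synthetic-data generator does and
does not emulate.

## Effect sizes

**Hedges' g.** For a record with per-arm means, SDs and sample sizes,
g = J (x̄_t − x̄_c)/s_p with the pooled SD s_p and the small-sample
correction J = 1 − 3/(4(n_t+n_c−2)−1). The sampling variance is the
standard large-sample form (n_t+n_c)/(n_t n_c) + g²/(2(n_t+n_c)). J is
recorded on every effect so the correction is auditable.

**Sign convention.** For development time and tissue damage, larger raw
values mean *worse* performance, so the sign of g is reversed for those two
outcomes — once, at computation time, with the reversal recorded and a
second application rejected. After reversal, negative g uniformly means
lower herbivore or plant performance following sequential attack (induced
resistance); for preference outcomes, negative g means preference for the
undamaged plant.

**Log odds ratio.** Records reporting individual survival or choice counts
use LOR = log[(a/b)/(c/d)] with cells a = events_t, b = n_t − a, c =
events_c, d = n_c − c, variance 1/a+1/b+1/c+1/d. Tables containing a zero
cell get 0.5 added to all four cells of that table only; tables with no
events (or no non-events) in both arms carry no direction information and
are rejected. Choice records are treated as two independent binomial arms;
paired-choice dependence within a single arena is not modelled — if choices
are negatively correlated within trials, the computed variances are
conservative for such records.

**Missing summaries.** Records lacking the summaries their metric needs are
excluded at effect-size computation time with a per-record logged warning,
not silently at read time.

## The three-level model

y_i = x_i'β + u_study(i) + u_trt(i) [+ u_taxon(i)] + e_i, with e_i ~
N(0, v_i) and v_i treated as known — the standard meta-analytic convention.
Study and treatment-within-study intercepts absorb the dependence of
multiple effect sizes per publication and of multiple treatments sharing a
control; the optional taxon term has level covariance σ²·R with R a
unit-diagonal Brownian-motion correlation from a tree.

**Estimation.** REML. Variance components are optimized on the log scale
(no boundary failures) by L-BFGS-B from three starts — a moment-based
guess, a small value (10⁻³), and half the sample variance of y — with
criterion tolerance 1e-12; components below 1e-8 are clamped to exactly
zero when that does not worsen the criterion. Fixed effects come from GLS
at the optimum. When no random term carries a correlation matrix, the
marginal covariance is block-diagonal over connected components of records
linked by shared factor levels; blocks of equal size are stacked and
factorized with batched Cholesky calls, which keeps one fit on ~1500
records around 0.1 s. Fits with a correlated taxon term use the dense path.

Optimizer reproducibility: the REML surface is smooth and the multi-start
rule deterministic, so repeated fits on identical input are identical;
estimates are invariant to record order and identifier relabeling to
optimizer precision (~10⁻⁵), which is the tolerance the order-invariance
tests assert.

**Inference.** Wald z intervals for coefficients and chi-square omnibus
(QM) tests on the non-intercept coefficients — the convention of standard
multilevel meta-analytic software; no small-sample t/F (Knapp–Hartung-type)
adjustment is applied. Categorical moderators use reference-level coding
(first sorted level), so a moderator with m levels gives QM on m−1 df.
Continuous moderators (feeding durations, in days) enter linearly,
untransformed. Heterogeneity is summarized as multilevel
I² = 100·Σσ²/(Σσ² + ṽ) with the typical sampling variance
ṽ = (k−1)Σw/((Σw)²−Σw²), w_i = 1/v_i. Prediction intervals for
intercept-only fits are β̂ ± z₀.₉₇₅·√(se² + Σσ²).

**Degenerate inputs.** A single record (or any saturated design) reduces to
the fixed-effects GLS solution with all components at zero — for one
record, β̂ = y₁ and se = √v₁. Rank-deficient designs raise an error naming
the aliased columns. Non-convergence is reported on the result object, not
raised.

## Phylogenetic correlation

Newick trees (dendropy) are pruned to the dataset's taxa — taxa absent from
the tree are returned as an exclusion list rather than raising, mirroring
the practice of dropping unplaced species from the phylogenetic sensitivity
analysis. The tip covariance is the shared root-to-MRCA path length;
correlation scales by √(depth_i·depth_j), which equals the common depth on
ultrametric trees and is the Brownian-motion correlation otherwise (raw
covariance available behind a flag). Name matching is case- and
underscore/space-insensitive; no fuzzy genus substitution is attempted.
Only one phylogeny is attached per model: crossed correlated terms over the
same records (plant and herbivore trees simultaneously) are poorly
identified, so plant, inducer and subsequent-herbivore trees are fitted in
three separate models.

## Publication-bias battery

*Cumulative meta-analysis*: records sorted by (publication year, study id,
record id); the full three-level model is refitted on every year-closing
prefix. On prefixes where a grouping factor has a single level that
component is not identifiable; it is pinned to zero and the step flagged,
rather than silently simplifying the model. The final step equals the
full-data fit.

*Funnel coordinates*: (value, SE) points plus pseudo-CI rails
pooled ± z·se over the observed SE range — plot-ready tables; no figure
rendering is built in.

*Asymmetry tests*: two variants, because both appear in practice and they
answer subtly different questions. `weighted_sei` is a random-effects
metaregression of the effect on its standard error (z statistic for the SE
coefficient) — the calibrated test under heterogeneity, used per response
category. `ols_inverse_variance` is an unweighted OLS regression of the
effect on 1/v (F with df (1, k−2)), used on all mean-based effects pooled.
Note one caveat the synthetic runs make visible: because var(g) contains
g²/(2n), sampling variance depends on the effect itself, so even unbiased
SMD data can show a mild inverse-variance–effect relationship; the
weighted-SE variant is less sensitive to this artifact.

## Sensitivity analyses

Leave-one-species-out refits remove every record involving one species in
one role (plant / inducing herbivore / subsequent herbivore), report the
share of records removed, the estimate shift, and whether the refit CI
excludes the full-data estimate — the criterion used to call a refit
"different from the main analysis". Species are ranked by representation
per role; the three most-studied per role are the standard exclusion set.
The binary-count subset is analysed on the LOR scale with the same
multilevel machinery, survival and choice outcomes separately, plus an
outcome-class moderator QM test.

## Synthetic-data generator

The generator emulates the *statistical* structure of sequential-herbivory
effect-size tables: ~161 studies each with 1–4 treatments sharing a control
and 1–6 measured outcomes per treatment; three response categories in
proportions 834:339:172; true effects θ = category mean + moderator shifts
+ u_study + u_trt (+ correlated u_taxon); raw per-arm summaries drawn so
the computed g is centred on θ (arm SDs from the chi distribution implied
by normal sampling, arm means from their normal sampling distributions);
and a binary-count subset (default 10% of survival/choice records,
emulating the ~30-study validation subset) drawn from binomial arms whose
logit difference is the true LOR. All draws are namespaced by (stream,
study, treatment, record) via SeedSequence spawn keys: datasets are
bit-reproducible and adding studies never perturbs existing ones.

Default parameters are the study conditions the package models:

- category means −0.326 / −0.142 / −0.013 (herbivore performance /
  preference / plant performance) and survival LOR −0.80 — the magnitudes
  characteristic of induced-resistance data;
- per-arm group sizes 5–30 (binary: 15–60), publication years 1985–2023
  skewed recent, 15% field studies, 80% inducer removal, ~8% conspecific
  sequences, ~1% mammal inducers;
- variance components per category (0.62/0.38, 1.66/1.01, 0.50/0.31 for
  study/treatment; binary 0.15/0.09) derived once from the target
  multilevel I² values (≈88 / 95 / 85%, LOR ≈50%) combined with the typical
  sampling variance implied by the configured group sizes;
- species tables whose weights put the three most-studied plants at
  13.5/11.8/10.8% of records and the most-studied herbivores at ~5–7%,
  with fixed guild / diet / feeding-location attributes per species;
- small moderator shifts (field +0.25, sap-feeder→chewer +0.15) so
  moderator machinery is exercised with realistic, modest signals.

`SimulationConfig.recovery()` is the clean single-category configuration
used for parameter-recovery studies: 150 studies, true mean −0.33,
σ²_study = 0.2, σ²_trt = 0.1, no moderator shifts, k ≈ 560.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: extraction error and digitization noise;
correlated effect sizes beyond the nested structure (shared-control
correlation enters only through the treatment random effect, not through
correlated sampling errors); non-normal true effects; selective reporting
(beyond the optional small-study-effect injection used by the bias tests);
real phylogenetic signal (taxon effects are generated from simulated trees);
and any relationship between moderators and heterogeneity magnitude.
Moderator shifts also displace the marginal category mean slightly
(≈ +0.04 for herbivore performance), and with 161 studies the realized
study-deviate mean wanders by ±0.1 between seeds, so single-dataset pooled
estimates scatter around the configured means with that spread — parameter
recovery is therefore validated on the recovery configuration over 200
replicates, not on one draw.

## Problem sizes

The validation studies use: 200 replicates at the recovery configuration
(k ≈ 560) for bias and coverage; 25 instances with k ≤ 12 against a
zoomed grid search of the REML criterion (independent dense
implementation); 200 null replicates (k = 60) for asymmetry-p uniformity
and 100 replicates (k = 200) for small-study-effect power; and one R
metafor `rma.mv` cross-check on a 12-study fixture. The acceptance script
runs the full pipeline on one paper-shaped dataset plus a 100-replicate
recovery study.

## Known limitations

- Wald-type inference only; no cluster-robust (sandwich) standard errors.
- The QM test is asymptotic; with very sparse moderator levels (a few
  records per level) its chi-square reference is optimistic.
- `cumul`-style stepwise refits can be slow on very long year ranges since
  each step is a full REML fit.
- The LOR arm model treats choice data as independent binomials (see
  above).
- Prediction intervals use the normal quantile, not a t quantile.
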