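# Methods

`parcelbrain` implements the statistical machinery used to ask whether a
binary clinical exposure — sleep-disordered breathing (SDB) in the
motivating application — is associated with regional gray-matter volume or
with advanced brain age across cognitive groups (healthy controls, mild
cognitive impairment, Alzheimer's disease). This note documents the models,
their assumptions, the tunable parameters and the design choices made where
the design was genuinely open.

## 1. Parcel representation

All statistics operate on a subjects × parcels matrix of gray-matter
volumes. A labelled 3-D atlas defines the compression from voxel-wise
modulated gray-matter maps: for each label, voxel values are summed and
scaled by the voxel volume (modulated segments represent actual tissue
volume, and summation preserves volume; a `mean` reduction is available for
sensitivity checks). The default atlas is a synthetic stand-in with the
same structure as the anatomical atlases used in practice: exactly 673
labels split 600 cortical / 36 subcortical / 37 cerebellar, built as a
nearest-seed (Voronoi) tessellation of an ellipsoidal mask so that every
region is connected and non-empty. Any NIfTI label image with a
label/parcel/compartment table can be substituted. Overlapping
(probabilistic) atlases are rejected by construction.

## 2. Synthetic cohort model

The generator is the package's definition of the study conditions; all
calibration tests run against it. Parcel volume for subject *i*, parcel
*p*:

    v_ip = b_p + s_p (a_i + Δ_i − a_min) − δ_dx(i) 1[p ∈ A]
           + β_SDB 1[SDB+] + u_site(i),p + ε_ip

* `b_p ~ N(1500, 250²)` volume units: baseline parcel volume.
* `s_p ~ N(−3, 1²)` units/year: linear age-related decline.
* `Δ_i ~ N(Δ_dx(i), σ_dx(i)²)` (years): *advanced brain aging*, applied
  along the age-slope direction in every parcel. Group means default to
  0 / +4.0 / +9.2 y for HC / MCI / AD (2.3 AD:MCI ratio); the per-subject
  SDs default to 3 / 10 / 10 y — the between-subject heterogeneity implied
  by the confidence intervals comparable studies report for group-mean
  brain-age gaps (a CI of ±1.4 y at n = 222 implies a within-group SD near
  10 y), and, clinically, the wide spectrum from stable to progressive
  impairment. Each subject's realized `Δ_i` is recorded in the cohort
  table as `true_brainage_offset`, the ground truth for recovery tests.
* `δ_dx` (volume units): *focal atrophy* on the affected subset `A` — the
  first 15% of parcels, an index set with no anatomical semantics.
  Defaults 0 / 300 / 690 units, chosen to be clearly detectable per parcel
  (≈1.4 σ / 3.3 σ of the per-parcel noise) as the positive control of the
  parcel-wise ANOVA. Focal atrophy also advances apparent brain age; the
  helper `expected_brainage_offsets` returns the combined offset an optimal
  linear readout would see.
* `β_SDB` (volume units): SDB effect, **default 0**. When zero, the volume
  code path never reads SDB status, so the two arms are exchangeable by
  construction — the null scenario of the motivating study.
* `u_site,p ~ N(0, 60²)`: site offsets, drawn independently per site ×
  parcel (the form of multi-site heterogeneity is otherwise unspecified).
* `ε_ip ~ N(0, 200²)`: parcel noise. Volumes are floored at 1.0 to keep
  them strictly positive; under the defaults fewer than 1 in 10⁴ entries
  touch the floor.

The reference cohort (default n = 2089, ages 55–85) has deliberately
unequal site sizes (geometric), site-dependent sex ratios and an
older-skewed age distribution, to exercise the stratified subsampling of
the brain-age stage. The study cohort fills six diagnosis × SDB cells
(default 30/111/24 per arm, ages 56.1–91.9, 57 acquisition sites — the
consortium the cohort emulates pools roughly that many scanners, and with
few simulated sites the per-site offsets act as cluster-common shifts
that i.i.d. group-mean confidence intervals cannot account for). Both cohorts share the same
parcel-level parameters (`b_p`, `s_p`, `A`), derived deterministically from
the configuration seed, so a reference-trained model is correctly specified
for the study cohort. Missing BMI / education values are
missing-completely-at-random at a configurable rate (default 1.5%, ~5 of
330 subjects); no informative missingness mechanism is simulated. Parcels
are independent given the covariates — no between-parcel covariance
structure is simulated, which mainly matters for the max-statistic null
(positively correlated parcels would make it less extreme, not more).

What the generator does **not** emulate: raw image formation and
preprocessing, non-linear age trajectories, spatially structured atrophy,
diagnosis-dependent covariate distributions, informative missingness, or
biomarkers. Passing calibration tests therefore demonstrates statistical
correctness of the machinery under the stated model, not robustness to
real-data violations of it.

## 3. Cohort assembly

* **Multiple imputation**: chained-equation regression imputation with
  posterior sampling (scikit-learn's iterative imputer) over the variable
  set {sex, age, cognitive status, BMI, education years}; *m* completed
  tables (default 5) plus a pooled table (per-cell mean of the numeric
  imputations) that feeds the single matching run. Observed cells are
  never modified.
* **Propensity model**: logistic regression of SDB-positive status on age,
  sex, education, BMI, cognitive status, APOE4 *presence* (count > 0),
  imaging protocol and field strength. Treatment history is excluded: it
  is structurally constant in the SDB-negative arm and would separate the
  classes perfectly. Perfect separation raises an explicit error advising
  penalization or covariate removal.
* **Matching**: greedy 1:1 nearest-neighbour on the propensity logit,
  without replacement, exact on cognitive status, caliper 0.2 × SD of the
  logit scores (a widely used convention; the method name fixes neither
  algorithm nor caliper), processing order randomized by seed. Exact
  matching on diagnosis guarantees identical per-diagnosis counts in both
  arms. A diagnosis stratum with an empty arm yields a warning, not an
  error. One record per subject is matched.
* **Balance diagnostics**: standardized mean difference (positive = higher
  in the SDB-positive arm) with a pooled-variance t test for numeric
  covariates; for categorical covariates, the mean absolute level-wise
  standardized proportion difference and a chi-square test without
  continuity correction. Constant covariates are reported with SMD 0 and a
  skipped test. Balance p-values are descriptive; nothing gates on them.

## 4. Parcel-wise permutation ANOVA

One linear model per parcel: age (continuous, centered), diagnosis
(3 levels), SDB (2 levels), and the single SDB × diagnosis interaction.
Per factor, the partial F uses Type-II sums of squares — each term tested
against the model containing every other term that does not contain it,
with the full-model residual in the denominator — vectorized across
parcels via QR projections. "Tested separately as factors" admits two
readings (separate one-factor models vs one joint model); the joint model
with partial tests is the standard reading of an n-way ANOVA and avoids
confounded main effects, and any factor subset can be requested for the
other reading.

The permutation null for a factor shuffles that factor's labels uniformly
across subjects, holding all other columns fixed, and refits; the
interaction permutes the SDB label *within diagnosis strata* (the
exchangeable units under the interaction null) while the SDB main-effect
column keeps the original labels. Simple label shuffling is used rather
than residual-based schemes (Freedman–Lane and relatives); it is known to
be mildly anticonservative when strong nuisance effects are present, which
is accepted as part of the emulated procedure and monitored by the FWE
calibration test.

Per replication the set-wise maximum F across parcels is recorded.
Uncorrected p-values use the add-one estimator against the parcel's own
null; family-wise-corrected p-values use it against the max-F null, so all
p lie in [1/(n_perm+1), 1] and FWE p dominates uncorrected p. The FWE
threshold is the empirical 95th percentile (linear interpolation) of the
max-F sample, and "significant" means reference F above that threshold.
Zero-variance parcels are flagged, carry no F, and are excluded from the
maximum with a warning. The reference procedure uses 10,000 permutations;
the desk-scale default is 1,000 (the threshold estimate's Monte-Carlo error
scales as n_perm^(−1/2); calibration tests use 500–1,000).

## 5. Brain-age ensemble (BrainAGE)

Before training, the reference and test cohorts are **jointly
harmonized** (`harmonize_cohorts`): additive per-site effects are
estimated by covariate-protected least squares on the pooled sample
(protecting age and diagnosis so biological signal stays out of the site
estimates) and removed, centering both cohorts on a common per-parcel
basis. Harmonizing each cohort separately would preserve each cohort's
own grand level, and the reference-vs-test difference of site means would
transfer into every prediction as a cohort-wide brain-age shift — the
multi-site transfer bias that batch-harmonization methods exist to
remove. Per-cohort harmonization (`harmonize_sites`) is also available.

Each of `n_replicates` replicates draws a stratified subsample of the
reference cohort: within every age-bracket × sex × site cell (5-year
brackets tiling 55–85), at most 30 subjects drawn uniformly without
replacement; sex counts are then equalized within each bracket by
down-sampling the larger sex ("similar numbers across brackets, equal
sexes" is operationalized as this equalize-within-bracket rule); finally
one third of the balanced pool is drawn per replicate
(`per_replicate_fraction = 1/3`). The sub-unity fraction is what makes
this a real ensemble: with the full pool reused every replicate the weak
learners are nearly identical and bagging cannot average away estimation
noise, whereas genuinely distinct subsamples decorrelate the learners, in
the manner of subsample bagging. Each subsample standardizes the 673
features with its own statistics and fits a linear ε-insensitive
support-vector regression of age on the features (C = 1, ε = 0.1 years;
conventional defaults — linear SVR is the standard weak learner on parcel
features and keeps training O(n·p); the test error is flat across two
orders of magnitude of C under the default noise model). Per-replicate
seeds derive from the master seed by counter-based spawning, so the
ensemble is bit-reproducible and parallelizable. The reference procedure
uses 10,000 replicates; the default is 200.

Predictions are averaged across learners (bagging). Because regression of
age on noisy features shrinks predictions toward the training-age mean
(regression dilution — under the default noise model, whose biological
heterogeneity also acts as label noise, the raw prediction-on-age slope
is ≈0.7–0.9), the ensemble applies the standard linear **age-bias
correction**: 15% of the reference cohort is held out of all training
subsamples, the bagged predictions on that split are regressed on age,
and every prediction is corrected as `(raw − intercept) / slope`. Without
this step the group-mean BrainAGE of a cohort with a true advanced-aging
offset Δ is biased toward (slope × Δ); with it the implant is recovered
unbiasedly. BrainAGE is the corrected bagged prediction minus
chronological age (positive = older-appearing brain).

Group evaluation reports per-diagnosis MAE, mean BrainAGE with a t-based
95% CI (omitted with a notice below 2 subjects; a zero-variance group gets
a degenerate-CI notice), and a permutation ANOVA of the scores on
diagnosis, SDB and their interaction, reusing the parcel-wise engine on
the single BrainAGE "parcel". A degenerate design (e.g. a one-subject
group aliasing the interaction) skips the ANOVA with a warning instead of
failing the evaluation.

The analytic accuracy floor used in tests combines the two irreducible
error sources for a healthy subject: the optimal-linear-readout noise
`sqrt(noise_sd² + site_offset_sd²) / ||s||₂` (≈2.6 y under the defaults)
and the biological heterogeneity of healthy brain aging (HC offset SD,
3 y) — chronological age cannot be read more precisely than the brain's
own deviation from it. The floor MAE is `sqrt(2/π)` times the combined
SD, ≈3.2 y; the achieved held-out HC MAE of ≈4 y sits between this floor
and the ≈3.6 y that comparable ensembles report on real data (where the
generating noise model is of course unknown).

## 6. Pipeline, determinism and problem sizes

The pipeline (simulate → impute + match → parcel-wise inference → brain
age → report) is driven by a single YAML-serializable configuration; the
master seed is split into per-stage seeds, every stage communicates through
TSV files in the run directory, and a JSON manifest records configuration,
derived seeds and package version, making every random draw reproducible
from the manifest alone. Report tables are pure pass-throughs of stage
outputs.

Calibration and recovery tests run at reduced problem sizes chosen so that
each property is still sharply testable: FWE calibration on 200 null
datasets of 60 subjects × 50 parcels with 500 permutations; p-uniformity
on 100 such datasets; power and null-SDB control at the full default study
scale (330 subjects × 673 parcels, 1,000 permutations, 100 runs);
brain-age recovery with a 1,500-subject reference and 200 replicates;
pipeline determinism on a ~300-subject configuration. The reference
procedure's 10,000 permutations / 10,000 replicates are scale parameters,
available through the same configuration fields.

## 7. Known limitations

* The simple-shuffle permutation scheme is anticonservative under very
  strong nuisance structure; a residual-based scheme is not implemented.
* Greedy matching is order-dependent (mitigated by seed-randomized order);
  optimal matching and weighting estimators are out of scope.
* The generator's independence across parcels understates the spatial
  correlation of real morphometry; max-statistic thresholds on real data
  would be somewhat less extreme.
* One record per subject is matched; designs with repeated images per
  subject are not modelled.
* The age-bias correction assumes a linear prediction-vs-age relation;
  strongly non-linear aging would need a flexible calibration curve.
* Site harmonization estimates plain additive site effects by least
  squares; very small sites get noisy estimates (no empirical-Bayes
  shrinkage), and multiplicative (scale) site effects are not modelled.
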