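# parcelbrain

Parcel-based gray-matter morphometry statistics, propensity-matched cohort
assembly and bagged brain-age estimation — the statistical machinery needed
to ask whether a binary clinical exposure (such as sleep-disordered
breathing, SDB) is associated with regional gray-matter volume or with
advanced brain age across cognitive groups (healthy controls, mild
cognitive impairment, Alzheimer's disease).

The package is aimed at neuroimaging statisticians and methodologists who
want a tested, reproducible implementation of this analysis stack that runs
end-to-end on synthetic cohorts — no imaging data required — while
accepting real parcel tables and NIfTI label images through the same
interfaces.

## What it implements

1. **Parcellation** — compression of voxel-wise modulated gray-matter maps
   to 673 parcel volumes (600 cortical / 36 subcortical / 37 cerebellar):
   per-label sum scaled by voxel volume. A synthetic 673-label atlas
   builder stands in for anatomical label images.
2. **Cohort assembly** — chained-equation multiple imputation of missing
   BMI/education, a logistic propensity model of exposure status, greedy
   1:1 nearest-neighbour matching on the propensity logit (without
   replacement, exact on cognitive status, 0.2 SD caliper), and balance
   diagnostics (standardized mean differences, t and chi-square tests).
3. **Parcel-wise inference** — per-parcel n-way ANOVA (age + diagnosis +
   SDB + SDB×diagnosis) with Type-II partial F statistics, factor-wise
   label-permutation null distributions, and set-wise **max-statistic
   family-wise error correction**: per permutation the maximum F across all
   parcels is recorded, and the FWE threshold is the 95th percentile of
   that max-F null,

       p_FWE(parcel) = (1 + #{max-F null >= F_parcel}) / (n_perm + 1).

4. **Brain age (BrainAGE)** — an ensemble of linear ε-insensitive
   support-vector regressions of age on the 673 parcels, each trained on a
   stratified subsample of a heterogeneous reference cohort (≤30 subjects
   per age-bracket × sex × site cell, sexes equalized per bracket, a third
   of the pool drawn per replicate), bagged by averaging, with joint
   covariate-protected site harmonization of reference and test cohorts
   and a linear age-bias correction calibrated on a held-out reference
   split. A subject's BrainAGE score is

       BrainAGE = (bias-corrected) bagged predicted age − chronological age,

   positive = older-appearing brain; groups are compared by MAE, mean
   BrainAGE with 95% CI, and a permutation ANOVA of the scores.
5. **Synthetic cohorts** — a generator producing reference and study
   cohorts with linear age-related decline, diagnosis-graded focal atrophy,
   configurable global advanced-aging offsets, a configurable (default
   zero) SDB effect, site heterogeneity and missing covariates; it defines
   the conditions under which every statistical property of the pipeline is
   tested. See `docs/methods.md` for the model and all defaults.

## Worked example

```python
import parcelbrain as pb

cfg = pb.SimulationConfig(
    n_reference=800, n_parcels=200, seed=3,
    n_study_per_cell={"HC": 30, "MCI": 80, "AD": 24},
    diagnosis_effects={"HC": 0.0, "MCI": 0.0, "AD": 0.0},   # no focal atrophy
    brainage_offset_years={"HC": 0.0, "MCI": 4.0, "AD": 9.0},  # implanted aging
)
ref_cohort, ref_parcels = pb.generate_reference_cohort(cfg)
study_cohort, study_parcels = pb.generate_study_cohort(cfg)

results = pb.run_parcelwise_analysis(study_parcels, study_cohort, n_perm=1000, seed=1)
for factor, r in results.items():
    print(f"{factor:15s} significant parcels: {r.n_significant:4d}   "
          f"FWE threshold F = {r.threshold:.2f}")

ref_parcels, study_parcels = pb.harmonize_cohorts(
    ref_parcels, ref_cohort, study_parcels, study_cohort)
ensemble = pb.train_ensemble(ref_cohort, ref_parcels,
                             pb.StratificationConfig(n_replicates=60, seed=2))
predicted = pb.predict_ensemble(ensemble, study_parcels)
report = pb.evaluate_groups(predicted, study_cohort, n_perm=1000, seed=3)
print(report.group_summary[["diagnosis", "n", "mae", "mean_brainage",
                            "ci_low", "ci_high"]].round(2).to_string(index=False))
print(report.anova.round(3).to_string(index=False))
```

Output:

```
age             significant parcels:    2   FWE threshold F = 13.72
diagnosis       significant parcels:    0   FWE threshold F = 8.47
sdb             significant parcels:    0   FWE threshold F = 13.17
sdb:diagnosis   significant parcels:    0   FWE threshold F = 8.68
diagnosis   n   mae  mean_brainage  ci_low  ci_high
       AD  48 12.22          10.97    8.04    13.90
       HC  60  6.06          -0.34   -2.24     1.56
      MCI 160  9.08           4.04    2.42     5.66
       factor      f     p
    diagnosis 18.241 0.001
          sdb  3.944 0.056
sdb:diagnosis  0.019 0.984
```

Reading the numbers: the study cohort carries no SDB effect and no focal
atrophy — only implanted advanced-aging offsets with means +4 y (MCI) and
+9 y (AD) and paper-scale between-subject heterogeneity (SD ≈ 10 y).
Accordingly no parcel is FWE-significant for SDB, the interaction or
diagnosis (advanced aging is a distributed signal, not a focal one; only
the age covariate reaches the parcel-wise threshold), while the BrainAGE
analysis separates the groups sharply: the diagnosis factor dominates the
score ANOVA (permutation p = .001), SDB does not (p = .056), and each
group's mean-BrainAGE confidence interval covers its implanted offset
(the AD point estimate sits above +9 because that cohort's realized
implant draw does).  Healthy-control MAE is ≈6 y here because the example
uses only 200 parcels; at the default 673-parcel resolution it is ≈4 y
against an analytic noise-model floor of ≈3.2 y.

A full pipeline run (simulate → impute + match → parcel-wise inference →
brain age → report), driven by a YAML config and writing TSV tables plus a
JSON manifest:

```bash
parcelbrain pipeline run --out my_run --seed 7
parcelbrain pipeline report --run my_run
```

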