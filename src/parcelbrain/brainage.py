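"""Bagged support-vector brain-age estimation (BrainAGE).

A heterogeneous multi-site reference cohort is repeatedly subsampled with
stratification — at most ``max_per_stratum`` subjects per age-bracket x sex
x site cell, with sex counts equalized within each age bracket — and each
subsample trains one linear epsilon-insensitive support-vector regression
of age on the parcel volumes (features standardized with that subsample's
own statistics).  Predictions of all weak learners on the study cohort are
averaged ("bagging"); a subject's BrainAGE score is the bagged predicted
age minus the chronological age, so positive scores mean an
older-appearing brain.  Group-level evaluation reports per-group MAE, mean
BrainAGE with t-based 95% confidence intervals, and a permutation ANOVA of
the BrainAGE scores on diagnosis, SDB and their interaction (reusing the
parcel-wise inference core on the single BrainAGE "parcel").
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import LinearSVR

from .containers import ParcelMatrix, validate_cohort
from . import inference

__all__ = [
    "StratificationConfig",
    "SVRHyper",
    "WeakLearner",
    "AgePredictionEnsemble",
    "BrainAgeResult",
    "harmonize_sites",
    "harmonize_cohorts",
    "stratified_subsample",
    "fit_weak_learner",
    "train_ensemble",
    "predict_ensemble",
    "brainage_scores",
    "evaluate_groups",
    "save_ensemble",
    "load_ensemble",
]


def harmonize_sites(
    parcels: ParcelMatrix,
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = ("age",),
) -> ParcelMatrix:
    """Remove additive per-site effects from parcel volumes.

    Per parcel, an OLS model with the protected covariates plus site
    indicators estimates each site's additive offset; the offsets (centered
    on their subject-weighted mean, so the cohort's grand level is
    preserved) are subtracted.  Protected covariates — age, and diagnosis /
    SDB status where present with >1 level — keep biological signal out of
    the site estimates.  Standard practice for multi-site morphometry:
    without it, models trained across sites partially encode site
    signatures and transfer with a site-dependent bias to new cohorts.
    """
    if parcels.subject_ids != list(cohort["subject_id"].astype(str)):
        raise ValueError("parcel matrix rows must align with the cohort table")
    sites = cohort["site"].astype(str).to_numpy()
    site_levels = sorted(pd.unique(sites))
    if len(site_levels) < 2:
        return ParcelMatrix(parcels.values.copy(), parcels.parcel_ids, parcels.subject_ids)

    cols = [np.ones((len(cohort), 1))]
    for cov in covariates:
        col = {"sdb": "sdb_status"}.get(cov, cov)
        if col not in cohort.columns or cohort[col].isna().any():
            continue
        if pd.api.types.is_numeric_dtype(cohort[col]):
            a = pd.to_numeric(cohort[col]).to_numpy(dtype=float)
            cols.append((a - a.mean())[:, None])
        else:
            levels = sorted(cohort[col].astype(str).unique())
            if len(levels) > 1:
                cols.append(
                    np.column_stack(
                        [(cohort[col].astype(str) == lev).astype(float) for lev in levels[1:]]
                    )
                )
    site_dummies = np.column_stack([(sites == s).astype(float) for s in site_levels[1:]])
    X = np.hstack(cols + [site_dummies])
    beta, *_ = np.linalg.lstsq(X, parcels.values, rcond=None)
    site_coefs = np.vstack([np.zeros((1, parcels.n_parcels)), beta[-len(site_levels) + 1 :]])
    site_index = np.searchsorted(site_levels, sites)
    per_subject = site_coefs[site_index]
    values = parcels.values - (per_subject - per_subject.mean(axis=0, keepdims=True))
    return ParcelMatrix(values, parcels.parcel_ids, parcels.subject_ids)


def harmonize_cohorts(
    reference_parcels: ParcelMatrix,
    reference: pd.DataFrame,
    test_parcels: ParcelMatrix,
    test_cohort: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "diagnosis"),
) -> tuple[ParcelMatrix, ParcelMatrix]:
    """Jointly harmonize a reference and a test cohort onto a common basis.

    Site effects are estimated on the pooled sample (treating every
    reference and test site as a batch, with covariate protection) and
    removed, so the two cohorts end up on the same per-parcel level —
    harmonizing each cohort separately would leave their site-mean
    difference in place and transfer it into every prediction as a
    cohort-wide brain-age shift.
    """
    if set(reference["subject_id"].astype(str)) & set(test_cohort["subject_id"].astype(str)):
        raise ValueError("reference and test cohorts must not share subject ids")
    ref_n = reference_parcels.n_subjects
    pooled_cohort = pd.concat(
        [reference.assign(site="ref::" + reference["site"].astype(str)),
         test_cohort.assign(site="test::" + test_cohort["site"].astype(str))],
        ignore_index=True,
    )
    pooled = ParcelMatrix(
        np.vstack([reference_parcels.values, test_parcels.values]),
        reference_parcels.parcel_ids,
        list(pooled_cohort["subject_id"].astype(str)),
    )
    harmonized = harmonize_sites(pooled, pooled_cohort, covariates=covariates)
    return (
        ParcelMatrix(harmonized.values[:ref_n], pooled.parcel_ids, reference_parcels.subject_ids),
        ParcelMatrix(harmonized.values[ref_n:], pooled.parcel_ids, test_parcels.subject_ids),
    )


@dataclass
class StratificationConfig:
    """Stratified-subsampling and ensemble-size parameters.

    ``n_replicates`` is a scale parameter: the reference procedure uses
    10,000 replicates; the default 200 keeps desk-scale runs fast while the
    bagging variance (which scales as 1/n_replicates) stays small.
    """

    age_bracket_width: float = 5.0  # years; brackets tile bracket_range
    bracket_range: tuple[float, float] = (55.0, 85.0)
    max_per_stratum: int = 30  # per age-bracket x sex x site cell
    n_replicates: int = 200
    #: fraction of the stratified pool drawn per replicate; sub-unity
    #: fractions give the ensemble genuinely distinct subsamples, which is
    #: what lets bagging average away estimation noise
    per_replicate_fraction: float = 1.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.age_bracket_width <= 0:
            raise ValueError("age_bracket_width must be positive")
        if self.max_per_stratum < 1:
            raise ValueError("max_per_stratum must be at least 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")
        if not 0 < self.per_replicate_fraction <= 1:
            raise ValueError("per_replicate_fraction must lie in (0, 1]")

    def bracket_of(self, age: np.ndarray) -> np.ndarray:
        lo, hi = self.bracket_range
        edges = np.arange(lo, hi, self.age_bracket_width)
        return np.clip(np.digitize(age, edges) - 1, 0, len(edges) - 1)


@dataclass
class SVRHyper:
    """Weak-learner hyperparameters: linear epsilon-insensitive SVR."""

    C: float = 1.0
    epsilon: float = 0.1  # years
    tol: float = 1e-3
    max_iter: int = 5000


def stratified_subsample(
    reference: pd.DataFrame,
    config: StratificationConfig,
    rng: np.random.Generator | int | None = None,
) -> list[str]:
    """Draw one balanced training subsample from the reference cohort.

    Within each age-bracket x sex x site cell, ``min(available,
    max_per_stratum)`` subjects are drawn uniformly without replacement;
    sex counts within each age bracket are then equalized by down-sampling
    the larger sex.  No subject is repeated within a replicate.
    """
    if len(reference) == 0:
        raise ValueError("reference cohort is empty")
    validate_cohort(reference)
    if reference["sex"].nunique() < 2:
        raise ValueError("stratified subsampling requires both sexes in the reference cohort")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    age = pd.to_numeric(reference["age"]).to_numpy(dtype=float)
    bracket = config.bracket_of(age)
    if len(np.unique(bracket)) < 2:
        raise ValueError("stratified subsampling requires at least 2 occupied age brackets")
    ids = reference["subject_id"].to_numpy(dtype=object)
    sex = reference["sex"].to_numpy(dtype=object)
    site = reference["site"].to_numpy(dtype=object)

    drawn: dict[tuple[int, str], list[str]] = {}
    for b in np.unique(bracket):
        for s in np.unique(sex):
            chosen: list[str] = []
            for st in np.unique(site):
                cell = np.flatnonzero((bracket == b) & (sex == s) & (site == st))
                if len(cell) == 0:
                    continue
                take = min(len(cell), config.max_per_stratum)
                chosen.extend(ids[rng.choice(cell, size=take, replace=False)])
            drawn[(int(b), str(s))] = chosen

    selected: list[str] = []
    for b in np.unique(bracket):
        by_sex = {s: drawn.get((int(b), str(s)), []) for s in np.unique(sex)}
        n_min = min(len(v) for v in by_sex.values())
        for s, members in by_sex.items():
            members = list(members)
            if len(members) > n_min:
                members = list(rng.choice(np.array(members, dtype=object), size=n_min, replace=False))
            selected.extend(members)

    if config.per_replicate_fraction < 1.0:
        k = max(1, int(round(config.per_replicate_fraction * len(selected))))
        selected = list(rng.choice(np.array(selected, dtype=object), size=k, replace=False))
    return sorted(str(s) for s in selected)


@dataclass
class WeakLearner:
    """One standardization + linear SVR pair; standardization statistics
    come from this learner's own training subsample only."""

    center: np.ndarray
    scale: np.ndarray
    coef: np.ndarray
    intercept: float
    train_ids: list[str] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.center):
            raise ValueError(
                f"feature count {X.shape[1]} does not match training ({len(self.center)})"
            )
        return ((X - self.center) / self.scale) @ self.coef + self.intercept


def fit_weak_learner(
    X: np.ndarray,
    ages: np.ndarray,
    hyper: SVRHyper | None = None,
    random_state: int = 0,
    train_ids: list[str] | None = None,
) -> WeakLearner:
    """Standardize features on the training subsample and fit a linear SVR."""
    hyper = hyper or SVRHyper()
    X = np.asarray(X, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if X.shape[0] < 20:
        raise ValueError(f"need at least 20 training subjects, got {X.shape[0]}")
    if X.shape[0] != len(ages):
        raise ValueError("feature rows and ages must align")
    if np.isnan(X).any():
        raise ValueError("training features contain missing values")

    center = X.mean(axis=0)
    scale = X.std(axis=0)
    constant = scale == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s); variance floor applied",
            stacklevel=2,
        )
        scale = np.where(constant, 1.0, scale)

    model = LinearSVR(
        C=hyper.C,
        epsilon=hyper.epsilon,
        loss="epsilon_insensitive",
        tol=hyper.tol,
        max_iter=hyper.max_iter,
        random_state=random_state,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit((X - center) / scale, ages)
    return WeakLearner(
        center=center,
        scale=scale,
        coef=model.coef_.ravel().copy(),
        intercept=float(np.atleast_1d(model.intercept_)[0]),
        train_ids=list(train_ids or []),
    )


@dataclass
class AgePredictionEnsemble:
    """Bag of weak learners plus the configuration that produced them.

    ``bias_slope`` / ``bias_intercept`` hold the age-bias calibration fitted
    on a held-out reference split (``None`` when correction is disabled):
    regression of age on parcel features shrinks predictions toward the
    training-age mean (regression dilution), so the raw bagged prediction is
    corrected as ``(raw - intercept) / slope`` — the standard age-bias
    correction of the brain-age literature.
    """

    learners: list[WeakLearner]
    parcel_ids: list[str]
    config: StratificationConfig
    hyper: SVRHyper
    bias_slope: float | None = None
    bias_intercept: float | None = None
    calibration_ids: list[str] = field(default_factory=list)

    @property
    def n_replicates(self) -> int:
        return len(self.learners)


def train_ensemble(
    reference: pd.DataFrame,
    parcels: ParcelMatrix,
    config: StratificationConfig | None = None,
    hyper: SVRHyper | None = None,
    bias_correction: bool = True,
    calibration_fraction: float = 0.15,
) -> AgePredictionEnsemble:
    """Fit the full ensemble: one weak learner per stratified subsample.

    Per-replicate seeds derive from the master seed through a counter-based
    spawning scheme, so replicates are independent and the whole ensemble
    is reproducible bit-for-bit.  With ``bias_correction`` (default) a
    ``calibration_fraction`` of the reference cohort is held out of every
    training subsample; the bagged predictions on that split calibrate the
    linear age-bias correction applied by :func:`predict_ensemble`.
    For multi-site data, harmonize the reference and test cohorts jointly
    with :func:`harmonize_cohorts` before training and prediction.
    """
    config = config or StratificationConfig()
    hyper = hyper or SVRHyper()
    validate_cohort(reference)
    if parcels.subject_ids != list(reference["subject_id"].astype(str)):
        raise ValueError("parcel matrix rows must align with the reference cohort")
    if not 0 < calibration_fraction < 0.5:
        raise ValueError("calibration_fraction must lie in (0, 0.5)")

    base = np.random.SeedSequence(config.seed)
    cal_child, *children = base.spawn(config.n_replicates + 1)
    train_ref, train_parcels = reference, parcels
    calibration_ids: list[str] = []
    cal_parcels = None
    if bias_correction:
        rng = np.random.default_rng(cal_child)
        n_cal = int(round(calibration_fraction * len(reference)))
        if n_cal < 20:
            raise ValueError(
                "bias correction needs a calibration split of at least 20 subjects; "
                "enlarge the reference cohort or disable bias_correction"
            )
        all_ids = reference["subject_id"].astype(str).to_numpy()
        calibration_ids = sorted(rng.choice(all_ids, size=n_cal, replace=False))
        keep = ~reference["subject_id"].astype(str).isin(calibration_ids)
        train_ref = reference[keep].reset_index(drop=True)
        train_parcels = parcels.subset(list(train_ref["subject_id"].astype(str)))
        cal_parcels = parcels.subset(calibration_ids)

    age_by_id = dict(zip(reference["subject_id"].astype(str), pd.to_numeric(reference["age"])))
    learners: list[WeakLearner] = []
    for child in children:
        rng = np.random.default_rng(child)
        ids = stratified_subsample(train_ref, config, rng)
        sub = train_parcels.subset(ids)
        ages = np.array([age_by_id[s] for s in ids])
        learner_seed = int(child.generate_state(1)[0] % (2**31))
        learners.append(
            fit_weak_learner(sub.values, ages, hyper, random_state=learner_seed, train_ids=ids)
        )
    ensemble = AgePredictionEnsemble(
        learners=learners,
        parcel_ids=list(parcels.parcel_ids),
        config=config,
        hyper=hyper,
        calibration_ids=list(calibration_ids),
    )
    if bias_correction:
        cal_age = np.array([age_by_id[s] for s in calibration_ids])
        raw = np.stack([w.predict(cal_parcels.values) for w in ensemble.learners]).mean(axis=0)
        slope, intercept = np.polyfit(cal_age, raw, 1)
        if slope <= 0.05:
            raise RuntimeError(
                f"age-bias calibration slope {slope:.3f} is degenerate; the ensemble "
                "carries no usable age signal"
            )
        ensemble.bias_slope = float(slope)
        ensemble.bias_intercept = float(intercept)
    return ensemble


def predict_ensemble(ensemble: AgePredictionEnsemble, parcels: ParcelMatrix) -> np.ndarray:
    """Bagged predicted age: mean over weak learners, bias-corrected if fitted."""
    if parcels.parcel_ids != ensemble.parcel_ids:
        raise ValueError("test parcel features must match the training feature order")
    preds = np.stack([w.predict(parcels.values) for w in ensemble.learners]).mean(axis=0)
    if ensemble.bias_slope is not None:
        preds = (preds - ensemble.bias_intercept) / ensemble.bias_slope
    return preds


def brainage_scores(predicted: np.ndarray, chronological: np.ndarray) -> np.ndarray:
    """BrainAGE = bagged predicted age - chronological age (years, signed)."""
    predicted = np.asarray(predicted, dtype=float)
    chronological = np.asarray(chronological, dtype=float)
    if predicted.shape != chronological.shape:
        raise ValueError("predicted and chronological ages must align")
    return predicted - chronological


@dataclass
class BrainAgeResult:
    """Per-subject brain-age output plus group summaries and inference."""

    per_subject: pd.DataFrame  # subject_id, diagnosis, sdb_status, age, predicted_age, brainage
    group_summary: pd.DataFrame  # per diagnosis: n, mae, mean_brainage, ci_low, ci_high
    anova: pd.DataFrame  # factor, f, p


def evaluate_groups(
    predicted: np.ndarray,
    cohort: pd.DataFrame,
    n_perm: int = 2000,
    seed: int = 0,
) -> BrainAgeResult:
    """Group-level evaluation of bagged age predictions on a study cohort.

    Per diagnosis group: MAE, mean BrainAGE and its t-based 95% CI (omitted
    with a notice for groups of fewer than 2 subjects).  BrainAGE is then
    tested for association with diagnosis, SDB status and their interaction
    with the same permutation machinery used parcel-wise, treating the
    score vector as a single parcel.
    """
    validate_cohort(cohort, require_sdb=True)
    predicted = np.asarray(predicted, dtype=float)
    age = pd.to_numeric(cohort["age"]).to_numpy(dtype=float)
    scores = brainage_scores(predicted, age)

    per_subject = pd.DataFrame(
        {
            "subject_id": cohort["subject_id"].astype(str),
            "diagnosis": cohort["diagnosis"],
            "sdb_status": cohort["sdb_status"],
            "age": age,
            "predicted_age": predicted,
            "brainage": scores,
        }
    )

    rows = []
    for dx, grp in per_subject.groupby("diagnosis", sort=True, observed=True):
        n = len(grp)
        mae = float(np.mean(np.abs(grp["predicted_age"] - grp["age"])))
        mean_ba = float(grp["brainage"].mean())
        if n >= 2:
            sd = float(grp["brainage"].std(ddof=1))
            half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
            ci_low, ci_high, note = mean_ba - half, mean_ba + half, ""
            if sd == 0:
                note = "degenerate variance: CI width 0"
        else:
            ci_low = ci_high = np.nan
            note = "CI omitted: fewer than 2 subjects"
        rows.append(
            {"diagnosis": dx, "n": n, "mae": mae, "mean_brainage": mean_ba,
             "ci_low": ci_low, "ci_high": ci_high, "note": note}
        )
    group_summary = pd.DataFrame(rows)

    score_matrix = ParcelMatrix(
        scores[:, None], ["brainage"], list(cohort["subject_id"].astype(str))
    )
    factors = ("diagnosis", "sdb", "sdb:diagnosis")
    try:
        results = inference.run_parcelwise_analysis(
            score_matrix, cohort, factors=factors, n_perm=n_perm, seed=seed, warn_unmatched=False
        )
        anova = pd.DataFrame(
            {
                "factor": list(factors),
                "f": [float(results[f].f[0]) for f in factors],
                "p": [float(results[f].p_unc[0]) for f in factors],
            }
        )
    except ValueError as e:
        # degenerate design (e.g. a one-subject group aliasing the
        # interaction): report the groups, skip the inference
        warnings.warn(f"BrainAGE group ANOVA skipped: {e}", stacklevel=2)
        anova = pd.DataFrame(
            {"factor": list(factors), "f": [np.nan] * 3, "p": [np.nan] * 3}
        )
    return BrainAgeResult(per_subject=per_subject, group_summary=group_summary, anova=anova)


# ---------------------------------------------------------------------------
# Model-directory serialization (manifest JSON + one npz of learner arrays)


def save_ensemble(ensemble: AgePredictionEnsemble, model_dir) -> None:
    model_dir = Path(model_dir)
    model_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "parcel_ids": ensemble.parcel_ids,
        "config": asdict(ensemble.config),
        "hyper": asdict(ensemble.hyper),
        "n_replicates": ensemble.n_replicates,
        "train_ids": [w.train_ids for w in ensemble.learners],
        "bias_slope": ensemble.bias_slope,
        "bias_intercept": ensemble.bias_intercept,
        "calibration_ids": ensemble.calibration_ids,
    }
    (model_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    np.savez_compressed(
        model_dir / "learners.npz",
        center=np.stack([w.center for w in ensemble.learners]),
        scale=np.stack([w.scale for w in ensemble.learners]),
        coef=np.stack([w.coef for w in ensemble.learners]),
        intercept=np.array([w.intercept for w in ensemble.learners]),
    )


def load_ensemble(model_dir) -> AgePredictionEnsemble:
    model_dir = Path(model_dir)
    manifest = json.loads((model_dir / "manifest.json").read_text())
    arrays = np.load(model_dir / "learners.npz")
    cfg = manifest["config"]
    cfg["bracket_range"] = tuple(cfg["bracket_range"])
    config = StratificationConfig(**cfg)
    hyper = SVRHyper(**manifest["hyper"])
    learners = [
        WeakLearner(
            center=arrays["center"][i],
            scale=arrays["scale"][i],
            coef=arrays["coef"][i],
            intercept=float(arrays["intercept"][i]),
            train_ids=list(manifest["train_ids"][i]),
        )
        for i in range(manifest["n_replicates"])
    ]
    return AgePredictionEnsemble(
        learners=learners,
        parcel_ids=list(manifest["parcel_ids"]),
        config=config,
        hyper=hyper,
        bias_slope=manifest.get("bias_slope"),
        bias_intercept=manifest.get("bias_intercept"),
        calibration_ids=list(manifest.get("calibration_ids", [])),
    )
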