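"""Cohort assembly: multiple imputation, propensity scores, 1:1 matching.

Reproduces the cohort-assembly statistics of the study design:

* chained-equation multiple imputation of missing BMI / education values
  using sex, age, cognitive status, BMI and education as the imputation
  variable set,
* a logistic propensity model of SDB-positive status on the matching
  covariates (age, sex, education, BMI, cognitive status, APOE4 presence,
  imaging protocol, field strength),
* greedy 1:1 nearest-neighbour matching on the propensity logit, without
  replacement, exact on cognitive status, with a caliper (default 0.2 SD of
  the logit scores) and seed-randomized processing order,
* a balance report with standardized mean differences, t tests for numeric
  covariates and chi-square tests for categorical ones.

SDB treatment history is deliberately not a propensity covariate: it is
structurally constant (False) in the SDB-negative arm and would force
perfect separation of the logistic model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .containers import DIAGNOSES, validate_cohort

__all__ = [
    "IMPUTATION_VARIABLES",
    "DEFAULT_MATCH_COVARIATES",
    "PropensityModel",
    "MatchedCohort",
    "impute_missing",
    "estimate_propensity",
    "match_pairs",
    "balance_table",
    "mean_absolute_smd",
]

#: Variables of the chained-equation imputation model.
IMPUTATION_VARIABLES = ["sex", "age", "diagnosis", "bmi", "education_years"]

#: Default covariates of the propensity model.
DEFAULT_MATCH_COVARIATES = [
    "age",
    "sex",
    "education_years",
    "bmi",
    "diagnosis",
    "apoe4_positive",
    "protocol",
    "field_strength",
]

_IMPUTABLE = ("bmi", "education_years")


class PerfectSeparationError(ValueError):
    """The propensity model separates the SDB classes perfectly."""


# ---------------------------------------------------------------------------
# Multiple imputation


def _imputation_design(cohort: pd.DataFrame) -> pd.DataFrame:
    """Numeric design over the imputation variable set."""
    design = pd.DataFrame(index=cohort.index)
    design["age"] = pd.to_numeric(cohort["age"])
    design["sex_male"] = (cohort["sex"] == "male").astype(float)
    for dx in DIAGNOSES[1:]:  # HC is the reference level
        design[f"dx_{dx}"] = (cohort["diagnosis"] == dx).astype(float)
    design["bmi"] = pd.to_numeric(cohort["bmi"], errors="coerce")
    design["education_years"] = pd.to_numeric(cohort["education_years"], errors="coerce")
    return design


def impute_missing(
    cohort: pd.DataFrame, m: int = 5, seed: int = 0
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Multiply impute missing BMI / education values.

    Returns ``m`` completed cohort tables (chained regression imputation
    with posterior sampling, so imputed cells vary across tables) and a
    pooled table whose imputed numeric cells are the per-cell mean of the
    ``m`` imputations — the single completed table used for matching.
    Observed entries are never modified.
    """
    validate_cohort(cohort)
    if m < 1:
        raise ValueError("m must be at least 1")
    other = [c for c in cohort.columns if c not in _IMPUTABLE]
    if cohort[other].isna().drop(columns=["sdb_status"], errors="ignore").to_numpy().any():
        raise ValueError("missingness must be confined to bmi and education_years")

    design = _imputation_design(cohort)
    predictors = design.drop(columns=["bmi", "education_years"])
    if predictors.isna().all(axis=1).any():
        bad = cohort.loc[predictors.isna().all(axis=1), "subject_id"].iloc[0]
        raise ValueError(f"subject {bad!r} is missing every imputation predictor")

    missing_mask = design[list(_IMPUTABLE)].isna()
    if not missing_mask.to_numpy().any():
        pooled = cohort.copy()
        return [cohort.copy() for _ in range(m)], pooled

    seeds = np.random.SeedSequence(seed).generate_state(m) % (2**31)
    completed: list[pd.DataFrame] = []
    stacks = {col: [] for col in _IMPUTABLE}
    for k in range(m):
        imputer = IterativeImputer(
            sample_posterior=True, max_iter=25, random_state=int(seeds[k])
        )
        filled = pd.DataFrame(
            imputer.fit_transform(design), columns=design.columns, index=design.index
        )
        table = cohort.copy()
        for col in _IMPUTABLE:
            values = pd.to_numeric(table[col], errors="coerce")
            values[missing_mask[col]] = filled.loc[missing_mask[col], col]
            table[col] = values
            stacks[col].append(values.to_numpy(dtype=float))
        completed.append(table)

    pooled = cohort.copy()
    for col in _IMPUTABLE:
        pooled[col] = np.mean(np.column_stack(stacks[col]), axis=1)
    return completed, pooled


# ---------------------------------------------------------------------------
# Propensity model


@dataclass
class PropensityModel:
    """Fitted logistic model of SDB-positive status on matching covariates."""

    coefficients: pd.Series
    covariates: list[str]
    design_columns: list[str]
    fitted: bool = True

    def predict(self, cohort: pd.DataFrame) -> np.ndarray:
        X = _propensity_design(cohort, self.covariates)
        X = X.reindex(columns=self.design_columns, fill_value=0.0)
        eta = X.to_numpy() @ self.coefficients.to_numpy()
        p = 1.0 / (1.0 + np.exp(-eta))
        return np.clip(p, 1e-12, 1 - 1e-12)


def _propensity_design(cohort: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    work = cohort.copy()
    if "apoe4_positive" in covariates and "apoe4_positive" not in work.columns:
        work["apoe4_positive"] = (pd.to_numeric(work["apoe4_count"]) > 0).astype(float)
    X = pd.DataFrame(index=work.index)
    X["const"] = 1.0
    for cov in covariates:
        col = work[cov]
        if pd.api.types.is_numeric_dtype(col) or pd.api.types.is_bool_dtype(col):
            X[cov] = pd.to_numeric(col).astype(float)
        else:
            levels = sorted(col.astype(str).unique())
            for level in levels[1:]:  # first level is the reference
                X[f"{cov}[{level}]"] = (col.astype(str) == level).astype(float)
    return X


def estimate_propensity(
    cohort: pd.DataFrame, covariates: list[str] | None = None
) -> PropensityModel:
    """Fit the logistic propensity model; scores lie strictly in (0, 1).

    Raises :class:`PerfectSeparationError` when a covariate combination
    determines the SDB label (advice: penalize or drop the covariate), and
    ``ValueError`` when only one SDB class is present.
    """
    validate_cohort(cohort, require_sdb=True)
    covariates = list(covariates or DEFAULT_MATCH_COVARIATES)
    y = (cohort["sdb_status"] == "positive").to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both SDB classes must be present to fit a propensity model")
    X = _propensity_design(cohort, covariates)
    if X.isna().to_numpy().any():
        raise ValueError("propensity covariates contain missing values; impute first")

    from statsmodels.tools.sm_exceptions import PerfectSeparationError as SMSepError

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = sm.Logit(y, X.to_numpy()).fit(disp=0, maxiter=200)
        except (SMSepError, np.linalg.LinAlgError) as e:
            raise PerfectSeparationError(
                "perfect separation in the propensity model; penalize the fit or "
                "remove the offending covariate"
            ) from e
    params = np.asarray(result.params)
    fitted = 1.0 / (1.0 + np.exp(-(X.to_numpy() @ params)))
    if np.max(np.abs(params)) > 30 or np.any(fitted < 1e-10) or np.any(fitted > 1 - 1e-10):
        raise PerfectSeparationError(
            "perfect separation in the propensity model; penalize the fit or "
            "remove the offending covariate"
        )
    return PropensityModel(
        coefficients=pd.Series(params, index=list(X.columns)),
        covariates=covariates,
        design_columns=list(X.columns),
    )


# ---------------------------------------------------------------------------
# Greedy 1:1 matching


@dataclass
class MatchedCohort:
    """Result of 1:1 matching: (SDB-positive, SDB-negative) subject-id pairs."""

    pairs: list[tuple[str, str]]
    discarded: list[str]
    caliper: float  # propensity-logit units

    def __post_init__(self) -> None:
        used = [s for pair in self.pairs for s in pair]
        if len(used) != len(set(used)):
            raise ValueError("a subject appears in more than one matched pair")

    @property
    def matched_ids(self) -> list[str]:
        return [s for pair in self.pairs for s in pair]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["sdb_positive_id", "sdb_negative_id"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, caliper: float = float("nan")) -> "MatchedCohort":
        df = pd.read_csv(path, sep="\t")
        pairs = list(zip(df["sdb_positive_id"].astype(str), df["sdb_negative_id"].astype(str)))
        return cls(pairs=pairs, discarded=[], caliper=caliper)


def match_pairs(
    cohort: pd.DataFrame,
    scores: np.ndarray,
    caliper: float | None = None,
    seed: int = 0,
) -> MatchedCohort:
    """Greedy nearest-neighbour 1:1 matching on the propensity logit.

    Matching is without replacement and exact on diagnosis; SDB-positive
    subjects are processed in seed-randomized order and each takes the
    nearest remaining SDB-negative subject within the caliper.  A diagnosis
    stratum with no eligible subjects on either side yields a warning and
    an empty stratum, not an error.  The matched cohort therefore has
    identical per-diagnosis counts in both arms.
    """
    validate_cohort(cohort, require_sdb=True)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (len(cohort),):
        raise ValueError("scores must align with cohort rows")
    if np.any((scores <= 0) | (scores >= 1)):
        raise ValueError("propensity scores must lie strictly in (0, 1)")
    logit = np.log(scores / (1 - scores))
    if caliper is None:
        sd = float(np.std(logit, ddof=1)) if len(logit) > 1 else 0.0
        caliper = 0.2 * sd if sd > 0 else np.inf

    rng = np.random.default_rng(seed)
    ids = cohort["subject_id"].to_numpy(dtype=object)
    diagnosis = cohort["diagnosis"].to_numpy(dtype=object)
    positive = (cohort["sdb_status"] == "positive").to_numpy()

    pairs: list[tuple[str, str]] = []
    matched = np.zeros(len(cohort), dtype=bool)
    for dx in pd.unique(diagnosis):
        treat_idx = np.flatnonzero(positive & (diagnosis == dx))
        control_idx = np.flatnonzero(~positive & (diagnosis == dx))
        if len(treat_idx) == 0 or len(control_idx) == 0:
            warnings.warn(
                f"diagnosis stratum {dx!r} has an empty SDB arm; no pairs formed",
                stacklevel=2,
            )
            continue
        available = np.ones(len(control_idx), dtype=bool)
        for t in rng.permutation(treat_idx):
            dists = np.abs(logit[control_idx] - logit[t])
            dists[~available] = np.inf
            j = int(np.argmin(dists))
            if dists[j] <= caliper:
                c = control_idx[j]
                available[j] = False
                matched[t] = matched[c] = True
                pairs.append((str(ids[t]), str(ids[c])))
    discarded = [str(s) for s in ids[~matched]]
    return MatchedCohort(pairs=pairs, discarded=discarded, caliper=float(caliper))


# ---------------------------------------------------------------------------
# Balance diagnostics


DEFAULT_BALANCE_COVARIATES = [
    "age",
    "sex",
    "diagnosis",
    "bmi",
    "education_years",
    "apoe4_count",
    "protocol",
    "field_strength",
]


def _numeric_smd(x_pos: np.ndarray, x_neg: np.ndarray) -> float:
    """Standardized mean difference; positive = higher in the SDB+ arm."""
    pooled = np.sqrt((np.var(x_pos, ddof=1) + np.var(x_neg, ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return float((np.mean(x_pos) - np.mean(x_neg)) / pooled)


def _categorical_smd(x_pos: pd.Series, x_neg: pd.Series) -> float:
    """Mean absolute level-wise standardized proportion difference."""
    levels = sorted(set(x_pos.astype(str)) | set(x_neg.astype(str)))
    ds = []
    for level in levels:
        p1 = float(np.mean(x_pos.astype(str) == level))
        p2 = float(np.mean(x_neg.astype(str) == level))
        denom = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2.0)
        ds.append(0.0 if denom == 0 else (p1 - p2) / denom)
    return float(np.mean(np.abs(ds)))


def balance_table(
    matched: MatchedCohort | None,
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Two-arm balance diagnostics (descriptive-table analogue).

    For numeric covariates: SMD and Welch-free two-sample pooled-variance t
    test; for categorical covariates: level-wise SMD summary and chi-square
    test.  With ``matched=None`` the full cohort's arms are compared
    (pre-matching balance).  Covariates constant in both arms get SMD 0 and
    a skipped test.
    """
    validate_cohort(cohort, require_sdb=True)
    if matched is not None:
        if matched.n_pairs < 2:
            raise ValueError("balance diagnostics need at least 2 matched pairs")
        cohort = cohort.set_index("subject_id").loc[matched.matched_ids].reset_index()
    covariates = list(covariates or DEFAULT_BALANCE_COVARIATES)
    pos = cohort[cohort["sdb_status"] == "positive"]
    neg = cohort[cohort["sdb_status"] == "negative"]

    rows = []
    for cov in covariates:
        numeric = pd.api.types.is_numeric_dtype(cohort[cov]) and cohort[cov].nunique() > 2
        x_pos, x_neg = pos[cov], neg[cov]
        if cohort[cov].nunique(dropna=True) <= 1:
            rows.append(
                {"covariate": cov, "type": "constant", "smd": 0.0, "statistic": np.nan,
                 "p_value": np.nan, "test": "skipped (constant covariate)"}
            )
            continue
        if numeric:
            a = pd.to_numeric(x_pos).to_numpy(dtype=float)
            b = pd.to_numeric(x_neg).to_numpy(dtype=float)
            smd = _numeric_smd(a, b)
            if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
                stat, p = np.nan, 1.0 if np.mean(a) == np.mean(b) else 0.0
            else:
                stat, p = stats.ttest_ind(a, b, equal_var=True)
            rows.append(
                {"covariate": cov, "type": "numeric", "smd": smd, "statistic": float(stat),
                 "p_value": float(p), "test": "two-sample t"}
            )
        else:
            smd = _categorical_smd(x_pos, x_neg)
            contingency = pd.crosstab(cohort["sdb_status"], cohort[cov].astype(str))
            if (contingency.to_numpy() == 0).all(axis=0).any() or contingency.shape[1] < 2:
                stat, p = np.nan, 1.0
            else:
                stat, p, _, _ = stats.chi2_contingency(contingency, correction=False)
            rows.append(
                {"covariate": cov, "type": "categorical", "smd": smd, "statistic": float(stat),
                 "p_value": float(p), "test": "chi-square"}
            )
    return pd.DataFrame(rows)


def mean_absolute_smd(balance: pd.DataFrame) -> float:
    """Mean |SMD| over non-constant covariates of a balance table."""
    usable = balance[balance["type"] != "constant"]
    return float(np.mean(np.abs(usable["smd"].to_numpy()))) if len(usable) else 0.0
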