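"""Parcel-wise n-way ANOVA with max-statistic permutation FWE correction.

The engine behind both the positive age / cognitive-status findings and the
null SDB findings.  Three consecutive parts:

1. *Reference statistics* — one linear model per parcel (age as a
   continuous covariate, diagnosis and SDB as unordered factors, plus the
   single SDB-by-diagnosis interaction); per-factor partial F via Type-II
   sums of squares (each term tested against the model containing every
   other term that does not contain it, with the full-model residual in the
   denominator), vectorized across parcels.
2. *Permutation statistics* — per factor, the tested factor's labels are
   shuffled uniformly at random across subjects (other columns fixed), the
   models are refitted, and per-parcel F values recorded; the interaction
   is permuted as the SDB label within diagnosis strata to respect
   exchangeability.  Per replication the set-wise maximum F across parcels
   is also recorded.
3. *FWE correction* — a parcel's family-wise-corrected p-value compares its
   reference F to the null distribution of the set-wise maximum; the FWE
   threshold is the empirical 95th percentile of that max-F sample.
   Add-one estimators are used throughout, so p-values lie in
   [1/(n_perm+1), 1].

The simple label-shuffle scheme (rather than residual-based schemes) is a
deliberate choice; it is mildly anticonservative when strong nuisance
effects are present, which is documented in the methods note.
Zero-variance parcels are flagged, excluded from the maximum statistic, and
carry no F.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ParcelMatrix

__all__ = [
    "FACTORS",
    "DesignSpec",
    "PermutationTestResult",
    "fit_reference_anova",
    "permutation_null",
    "fwe_correct",
    "run_parcelwise_analysis",
]

#: Canonical factor set: main effects plus the single interaction.
FACTORS = ("age", "diagnosis", "sdb", "sdb:diagnosis")

_FACTOR_COLUMNS = {"age": "age", "diagnosis": "diagnosis", "sdb": "sdb_status"}


def _components(term: str) -> tuple[str, ...]:
    return tuple(term.split(":"))


def _contains(term: str, factor: str) -> bool:
    """True when ``term`` is a higher-order term containing ``factor``."""
    return term != factor and set(_components(factor)) < set(_components(term))


class DesignSpec:
    """Model design over a cohort table for a chosen factor subset.

    Factor columns are taken from the cohort (``age``, ``diagnosis``,
    ``sdb_status``); categorical levels are fixed from the observed data in
    sorted order, with the first level as reference.
    """

    def __init__(self, cohort: pd.DataFrame, factors=FACTORS):
        factors = tuple(factors)
        unknown = [f for f in factors if f not in FACTORS]
        if unknown:
            raise ValueError(f"unknown factors {unknown}; choose from {FACTORS}")
        if not factors:
            raise ValueError("at least one factor is required")
        self.factors = factors
        self.n = len(cohort)

        needed = set()
        for f in factors:
            needed.update(_components(f))
        self.labels: dict[str, np.ndarray] = {}
        self.levels: dict[str, list[str]] = {}
        for base in needed:
            col = _FACTOR_COLUMNS[base]
            if col not in cohort.columns:
                raise ValueError(f"cohort table lacks column {col!r} required by factor {base!r}")
            if cohort[col].isna().any():
                raise ValueError(f"factor column {col!r} contains missing values")
            if base == "age":
                self.labels["age"] = pd.to_numeric(cohort[col]).to_numpy(dtype=float)
                if np.ptp(self.labels["age"]) == 0:
                    raise ValueError("age is constant; its effect is not testable")
            else:
                lab = cohort[col].astype(str).to_numpy()
                lev = sorted(pd.unique(lab))
                if len(lev) < 2:
                    raise ValueError(f"factor {base!r} needs at least 2 observed levels")
                self.labels[base] = lab
                self.levels[base] = lev

        self._check_rank()

    # -- design blocks -----------------------------------------------------

    def block(self, term: str, override: dict[str, np.ndarray] | None = None) -> np.ndarray:
        """Design columns of a single term, optionally with overridden labels."""
        override = override or {}

        def lab(base):
            return override.get(base, self.labels[base])

        if term == "age":
            a = lab("age")
            return (a - a.mean())[:, None]
        if term in ("diagnosis", "sdb"):
            return self._dummies(term, lab(term))
        if term == "sdb:diagnosis":
            sdb_ind = self._dummies("sdb", lab("sdb"))
            dx = self._dummies("diagnosis", lab("diagnosis"))
            return sdb_ind * dx if dx.shape[1] == 1 else np.hstack(
                [sdb_ind * dx[:, [j]] for j in range(dx.shape[1])]
            )
        raise ValueError(f"unknown term {term!r}")

    def _dummies(self, base: str, lab: np.ndarray) -> np.ndarray:
        levels = self.levels[base]
        return np.column_stack([(lab == lev).astype(float) for lev in levels[1:]])

    def matrix(self, terms, override=None) -> np.ndarray:
        cols = [np.ones((self.n, 1))]
        cols.extend(self.block(t, override) for t in terms)
        return np.hstack(cols)

    def _check_rank(self) -> None:
        ranks = {}
        X = np.ones((self.n, 1))
        for t in self.factors:
            Xt = np.hstack([X, self.block(t)])
            gained = np.linalg.matrix_rank(Xt) - np.linalg.matrix_rank(X)
            ranks[t] = gained
            if gained < self.block(t).shape[1]:
                raise ValueError(
                    f"rank-deficient design: term {t!r} is aliased with earlier terms "
                    f"({self.factors[: self.factors.index(t)]})"
                )
            X = Xt
        self.rank_full = int(np.linalg.matrix_rank(X))
        if self.n <= self.rank_full:
            raise ValueError(
                f"need more subjects ({self.n}) than model rank ({self.rank_full})"
            )
        self.df_den = self.n - self.rank_full
        self.df_num = {t: self.block(t).shape[1] for t in self.factors}


def _proj_rss(X: np.ndarray, Y: np.ndarray, sumsq: np.ndarray) -> np.ndarray:
    """Residual sum of squares of Y columns after projection on col(X)."""
    Q, R = np.linalg.qr(X)
    d = np.abs(np.diag(R))
    if d.size and d.min() < 1e-10 * max(d.max(), 1.0):
        U, s, _ = np.linalg.svd(X, full_matrices=False)
        Q = U[:, s > (s[0] if s.size else 1.0) * 1e-12]
    QtY = Q.T @ Y
    return np.maximum(sumsq - np.einsum("ij,ij->j", QtY, QtY), 0.0)


class _FactorEngine:
    """Precomputed pieces for testing one factor over one response matrix."""

    def __init__(self, design: DesignSpec, Y: np.ndarray, factor: str):
        if factor not in design.factors:
            raise ValueError(f"factor {factor!r} not present in design {design.factors}")
        self.design = design
        self.factor = factor
        self.Y = Y
        Yc = Y - Y.mean(axis=0)
        self.sumsq = np.einsum("ij,ij->j", Yc, Yc)
        self.Yc = Yc

        others = [t for t in design.factors if t != factor and not _contains(t, factor)]
        self.containing = [t for t in design.factors if _contains(t, factor)]
        self.X1 = design.matrix(others)
        self.rss1 = _proj_rss(self.X1, Yc, self.sumsq)
        self.q = design.df_num[factor]
        self.df_den = design.df_den

    def f_stats(self, override: dict[str, np.ndarray] | None = None) -> np.ndarray:
        d = self.design
        block_f = d.block(self.factor, override)
        X2 = np.hstack([self.X1, block_f])
        rss2 = _proj_rss(X2, self.Yc, self.sumsq)
        if self.containing:
            Xf = np.hstack([X2] + [d.block(t, override) for t in self.containing])
            rss_full = _proj_rss(Xf, self.Yc, self.sumsq)
        else:
            rss_full = rss2
        denom = rss_full / self.df_den
        with np.errstate(divide="ignore", invalid="ignore"):
            return ((self.rss1 - rss2) / self.q) / denom

    def permuted_override(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        d = self.design
        if self.factor == "age":
            return {"age": rng.permutation(d.labels["age"])}
        if self.factor in ("diagnosis", "sdb"):
            return {self.factor: rng.permutation(d.labels[self.factor])}
        # interaction: SDB labels permuted within diagnosis strata; the SDB
        # main-effect column keeps the original labels (other columns fixed).
        sdb = d.labels["sdb"].copy()
        dx = d.labels["diagnosis"]
        for level in np.unique(dx):
            idx = np.flatnonzero(dx == level)
            sdb[idx] = sdb[idx[rng.permutation(len(idx))]]
        return {"sdb": sdb}


@dataclass
class AnovaFit:
    """Reference per-parcel, per-factor partial F statistics."""

    f: pd.DataFrame  # parcels x factors
    df_num: dict[str, int]
    df_den: int
    zero_variance: pd.Series  # flagged parcels (no F)


def _zero_variance_mask(Y: np.ndarray) -> np.ndarray:
    return np.ptp(Y, axis=0) == 0


def fit_reference_anova(
    parcels: ParcelMatrix, cohort: pd.DataFrame, factors=FACTORS
) -> AnovaFit:
    """Per-parcel Type-II partial F for every factor (reference statistics)."""
    design = DesignSpec(cohort, factors)
    if parcels.n_subjects != design.n:
        raise ValueError("parcel matrix rows must align with the cohort table")
    Y = parcels.values
    flagged = _zero_variance_mask(Y)
    Yok = Y[:, ~flagged]

    F = np.full((parcels.n_parcels, len(design.factors)), np.nan)
    for j, factor in enumerate(design.factors):
        engine = _FactorEngine(design, Yok, factor)
        F[~flagged, j] = engine.f_stats()
    return AnovaFit(
        f=pd.DataFrame(F, index=parcels.parcel_ids, columns=list(design.factors)),
        df_num=dict(design.df_num),
        df_den=design.df_den,
        zero_variance=pd.Series(flagged, index=parcels.parcel_ids),
    )


def permutation_null(
    parcels: ParcelMatrix,
    cohort: pd.DataFrame,
    factor: str,
    n_perm: int,
    seed: int = 0,
    factors=FACTORS,
) -> tuple[np.ndarray, np.ndarray]:
    """Null F distribution for one factor by label permutation.

    Returns ``(null_f, null_max)``: the per-parcel null F matrix of shape
    (n_perm, n_parcels) (NaN for zero-variance parcels) and the per-
    replication set-wise maximum F across parcels.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100 for a usable null distribution")
    design = DesignSpec(cohort, factors)
    if parcels.n_subjects != design.n:
        raise ValueError("parcel matrix rows must align with the cohort table")
    Y = parcels.values
    flagged = _zero_variance_mask(Y)
    if flagged.any():
        warnings.warn(
            f"{int(flagged.sum())} zero-variance parcel(s) excluded from the max statistic",
            stacklevel=2,
        )
    Yok = Y[:, ~flagged]
    engine = _FactorEngine(design, Yok, factor)

    rng = np.random.default_rng(seed)
    null_f = np.full((n_perm, parcels.n_parcels), np.nan)
    null_max = np.empty(n_perm)
    for b in range(n_perm):
        fb = engine.f_stats(engine.permuted_override(rng))
        null_f[b, ~flagged] = fb
        null_max[b] = fb.max() if fb.size else np.nan
    return null_f, null_max


@dataclass
class PermutationTestResult:
    """Per-parcel permutation inference for one factor."""

    factor: str
    parcel_ids: list[str]
    f: np.ndarray  # reference F per parcel (NaN where flagged)
    p_unc: np.ndarray
    p_fwe: np.ndarray
    threshold: float  # empirical 95th percentile of the null max-F sample
    null_max: np.ndarray
    n_perm: int
    seed: int | None
    significant: np.ndarray  # reference F above the FWE threshold
    zero_variance: np.ndarray

    def __post_init__(self) -> None:
        ok = ~self.zero_variance
        if np.any(self.p_fwe[ok] + 1e-12 < self.p_unc[ok]):
            raise AssertionError("FWE p-values must dominate uncorrected p-values")

    @property
    def n_significant(self) -> int:
        return int(np.sum(self.significant))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parcel_id": self.parcel_ids,
                "f": self.f,
                "p_unc": self.p_unc,
                "p_fwe": self.p_fwe,
                "significant": self.significant.astype(int),
            }
        )


def fwe_correct(
    f_ref: np.ndarray,
    null_max: np.ndarray,
    null_f: np.ndarray | None = None,
    factor: str = "",
    parcel_ids: list[str] | None = None,
    seed: int | None = None,
) -> PermutationTestResult:
    """Set-wise maximum FWE correction of reference F statistics.

    ``p_fwe = (1 + #{null max-F >= F}) / (n_perm + 1)`` per parcel;
    uncorrected p analogously from the parcel's own null F column when
    ``null_f`` is given.  The FWE threshold is the empirical 95th
    percentile (linear interpolation) of the null max-F sample, and parcels
    whose reference F exceeds it are flagged significant.
    """
    f_ref = np.asarray(f_ref, dtype=float)
    null_max = np.asarray(null_max, dtype=float)
    n_perm = len(null_max)
    if null_f is not None and null_f.shape != (n_perm, len(f_ref)):
        raise ValueError(
            f"null F matrix shape {null_f.shape} does not match "
            f"({n_perm} permutations, {len(f_ref)} parcels)"
        )
    flagged = ~np.isfinite(f_ref)

    exceed = np.sum(null_max[:, None] >= f_ref[None, :], axis=0)
    p_fwe = (1.0 + exceed) / (n_perm + 1.0)
    if null_f is not None:
        with np.errstate(invalid="ignore"):
            p_unc = (1.0 + np.nansum(null_f >= f_ref[None, :], axis=0)) / (n_perm + 1.0)
    else:
        p_unc = np.full_like(p_fwe, np.nan)
    threshold = float(np.quantile(null_max, 0.95))
    significant = np.where(flagged, False, f_ref > threshold)
    p_fwe[flagged] = np.nan
    p_unc[flagged] = np.nan
    return PermutationTestResult(
        factor=factor,
        parcel_ids=list(parcel_ids) if parcel_ids is not None else [str(i) for i in range(len(f_ref))],
        f=f_ref,
        p_unc=p_unc,
        p_fwe=p_fwe,
        threshold=threshold,
        null_max=null_max,
        n_perm=n_perm,
        seed=seed,
        significant=significant,
        zero_variance=flagged,
    )


def run_parcelwise_analysis(
    parcels: ParcelMatrix,
    cohort: pd.DataFrame,
    factors=FACTORS,
    n_perm: int = 1000,
    seed: int = 0,
    warn_unmatched: bool = True,
) -> dict[str, PermutationTestResult]:
    """Reference fit, permutation null and FWE correction for each factor."""
    factors = tuple(factors)
    if warn_unmatched and "sdb" in {c for f in factors for c in _components(f)}:
        counts = cohort.groupby(["diagnosis", "sdb_status"], observed=True).size().unstack(fill_value=0)
        if counts.shape[1] == 2 and not (counts.iloc[:, 0] == counts.iloc[:, 1]).all():
            warnings.warn(
                "SDB arms have unequal per-diagnosis counts; a matched cohort is "
                "recommended for SDB inference",
                stacklevel=2,
            )
    fit = fit_reference_anova(parcels, cohort, factors)
    children = np.random.SeedSequence(seed).spawn(len(factors))
    results: dict[str, PermutationTestResult] = {}
    for child, factor in zip(children, factors):
        factor_seed = int(child.generate_state(1)[0] % (2**31))
        null_f, null_max = permutation_null(
            parcels, cohort, factor, n_perm=n_perm, seed=factor_seed, factors=factors
        )
        results[factor] = fwe_correct(
            fit.f[factor].to_numpy(),
            null_max,
            null_f=null_f,
            factor=factor,
            parcel_ids=parcels.parcel_ids,
            seed=factor_seed,
        )
    return results
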