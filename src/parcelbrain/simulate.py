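"""Synthetic cohort and parcel-volume generator.

Emulates the statistical structure the downstream analysis assumes, so that
matching, parcel-wise permutation inference and the brain-age ensemble are
all testable without any imaging download:

* a large heterogeneous *reference* cohort (default n = 2089, ages 55-85,
  several sites with deliberately unequal site / sex / age-bracket
  frequencies) whose parcel volumes decline linearly with age,
* a *study* cohort laid out as six diagnosis x SDB cells (default
  30 HC / 111 MCI / 24 AD per SDB arm, ages 56.1-91.9) with

  - focal, diagnosis-graded volume loss on an "affected" parcel subset
    (the regional-atrophy positive control for the parcel-wise ANOVA),
  - a global advanced-aging shift applied along the age-slope direction
    (the implanted brain-age offset, in years),
  - a configurable SDB effect that defaults to zero — the null scenario:
    when ``sdb_effect == 0`` the volume model never reads SDB status, so
    both SDB arms are exchangeable by construction,
  - site offsets, Gaussian parcel noise, and missing-completely-at-random
    BMI / education entries.

The parcel-level parameters (baseline volumes, age slopes, affected subset)
are derived deterministically from the configuration seed and are shared
between the reference and study cohorts of the same configuration, so a
model trained on the reference cohort is correctly specified for the study
cohort.

Volume model for subject i, parcel p::

    v_ip = b_p + s_p * (age_i + offset_years[dx_i] + sd_dx(i) * z_i - age_min)
           - diagnosis_effects[dx_i] * 1[p affected]
           + sdb_effect * 1[SDB+]            (term absent when sdb_effect == 0)
           + u_{site(i), p} + eps_ip

with b_p ~ N(baseline_mean, baseline_sd), s_p ~ N(slope_mean, slope_sd)
(negative mean), u ~ N(0, site_offset_sd) per site x parcel and
eps ~ N(0, noise_sd).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DIAGNOSES, ParcelMatrix
from .parcellation import AtlasLabelMap

__all__ = [
    "SimulationConfig",
    "ParcelParams",
    "parcel_parameters",
    "generate_reference_cohort",
    "generate_study_cohort",
    "paint_voxel_image",
    "analytic_age_sd",
    "analytic_mae_floor",
    "expected_brainage_offsets",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohorts.  Units noted per field.

    Defaults emulate the study conditions: reference n = 2089 across 7
    heterogeneous sites, study cells of 30/111/24 (HC/MCI/AD) per SDB arm,
    673 parcels, zero SDB effect, 2.3 AD:MCI ratio for both the focal
    atrophy magnitudes and the implanted advanced-aging offsets.
    """

    n_reference: int = 2089
    #: subjects per diagnosis cell, per SDB arm; values may be an int
    #: (both arms equal) or a (negative, positive) pair.
    n_study_per_cell: dict = field(default_factory=lambda: {"HC": 30, "MCI": 111, "AD": 24})
    n_parcels: int = 673
    reference_age_range: tuple[float, float] = (55.0, 85.0)
    study_age_range: tuple[float, float] = (56.1, 91.9)
    n_sites: int = 7
    n_study_sites: int = 57  # the emulated study cohort is a ~57-site consortium
    baseline_volume_mean: float = 1500.0  # volume units per parcel
    baseline_volume_sd: float = 250.0
    age_slope_mean: float = -3.0  # volume units per year
    age_slope_sd: float = 1.0
    #: focal volume loss (volume units) on the affected parcel subset
    diagnosis_effects: dict = field(default_factory=lambda: {"HC": 0.0, "MCI": 300.0, "AD": 690.0})
    #: global advanced aging (years) applied along the age-slope direction
    brainage_offset_years: dict = field(default_factory=lambda: {"HC": 0.0, "MCI": 4.0, "AD": 9.2})
    #: per-subject SD (years) of the advanced-aging offset: biological
    #: heterogeneity of brain aging within each diagnosis group
    brainage_offset_sd_years: dict = field(
        default_factory=lambda: {"HC": 3.0, "MCI": 10.0, "AD": 10.0}
    )
    affected_parcel_fraction: float = 0.15
    sdb_effect: float = 0.0  # volume units added to every parcel of SDB+ subjects
    site_offset_sd: float = 60.0
    noise_sd: float = 200.0
    missing_rate: float = 0.015  # fraction of subjects with a masked BMI/education entry
    #: covariate imbalance knobs; zero keeps the SDB arms exchangeable
    sdb_age_shift: float = 0.0  # years added to SDB+ ages
    sdb_bmi_shift: float = 0.0  # kg/m^2 added to SDB+ BMI
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reference <= 0 or self.n_parcels <= 0:
            raise ValueError("n_reference and n_parcels must be positive")
        if self.n_sites <= 0 or self.n_study_sites <= 0:
            raise ValueError("site counts must be positive")
        for name in ("baseline_volume_sd", "age_slope_sd", "site_offset_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for lo, hi in (self.reference_age_range, self.study_age_range):
            if not lo < hi:
                raise ValueError("age range minimum must be below maximum")
        if not 0.0 < self.affected_parcel_fraction <= 1.0:
            raise ValueError("affected_parcel_fraction must lie in (0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        for knob in (self.diagnosis_effects, self.brainage_offset_years, self.brainage_offset_sd_years):
            missing = set(DIAGNOSES) - set(knob)
            if missing:
                raise ValueError(f"diagnosis-keyed parameters missing groups: {sorted(missing)}")
        if any(v < 0 for v in self.brainage_offset_sd_years.values()):
            raise ValueError("brainage_offset_sd_years must be non-negative")
        if self.diagnosis_effects["HC"] != 0.0:
            raise ValueError("diagnosis_effects['HC'] must be exactly 0 (HC is the anchor group)")
        if self.brainage_offset_years["HC"] != 0.0:
            raise ValueError("brainage_offset_years['HC'] must be exactly 0")
        normalized = {}
        for dx, n in self.n_study_per_cell.items():
            pair = (int(n), int(n)) if np.isscalar(n) else (int(n[0]), int(n[1]))
            if any(k <= 0 for k in pair):
                raise ValueError(f"study cell size for {dx} must be positive")
            normalized[dx] = int(n) if np.isscalar(n) else pair
        self.n_study_per_cell = normalized


def _cell_sizes(config: SimulationConfig) -> dict[str, tuple[int, int]]:
    """Per-diagnosis (SDB-negative, SDB-positive) cell sizes."""
    out = {}
    for dx in DIAGNOSES:
        n = config.n_study_per_cell.get(dx, 0)
        out[dx] = (int(n), int(n)) if np.isscalar(n) else (int(n[0]), int(n[1]))
    return out


def _seed_streams(config: SimulationConfig) -> dict[str, np.random.SeedSequence]:
    base = np.random.SeedSequence(config.seed)
    children = base.spawn(4)
    return dict(zip(("parcels", "reference", "study", "paint"), children))


@dataclass
class ParcelParams:
    """Parcel-level generating parameters, deterministic given the config seed."""

    baseline: np.ndarray  # (P,) volume units
    slope: np.ndarray  # (P,) volume units per year
    affected: np.ndarray  # (P,) bool — carries the diagnosis effect


def parcel_parameters(config: SimulationConfig) -> ParcelParams:
    rng = np.random.default_rng(_seed_streams(config)["parcels"])
    P = config.n_parcels
    baseline = config.baseline_volume_mean + config.baseline_volume_sd * rng.standard_normal(P)
    baseline = np.maximum(baseline, 50.0)  # parcels are strictly positive structures
    slope = config.age_slope_mean + config.age_slope_sd * rng.standard_normal(P)
    n_affected = max(1, int(round(config.affected_parcel_fraction * P)))
    affected = np.zeros(P, dtype=bool)
    # "temporal" subset: a fixed index set at the start of the (cortical-first)
    # parcel ordering; no anatomical semantics are simulated.
    affected[:n_affected] = True
    return ParcelParams(baseline=baseline, slope=slope, affected=affected)


def _site_offsets(rng: np.random.Generator, n_sites: int, n_parcels: int, sd: float) -> np.ndarray:
    return sd * rng.standard_normal((n_sites, n_parcels)) if sd > 0 else np.zeros((n_sites, n_parcels))


def _volumes(
    config: SimulationConfig,
    params: ParcelParams,
    rng: np.random.Generator,
    age: np.ndarray,
    diagnosis: np.ndarray,
    sdb_positive: np.ndarray | None,
    site_index: np.ndarray,
    site_offsets: np.ndarray,
    out_offset: np.ndarray,
) -> np.ndarray:
    age_min = config.reference_age_range[0]
    offset = np.array([config.brainage_offset_years[d] for d in diagnosis])
    offset_sd = np.array([config.brainage_offset_sd_years[d] for d in diagnosis])
    # per-subject biological heterogeneity of brain aging
    offset = offset + offset_sd * rng.standard_normal(len(age))
    effective_age = age + offset
    out_offset[:] = offset
    v = params.baseline[None, :] + params.slope[None, :] * (effective_age - age_min)[:, None]
    focal = np.array([config.diagnosis_effects[d] for d in diagnosis])
    v = v - focal[:, None] * params.affected[None, :]
    if config.sdb_effect != 0.0:
        # Only a non-zero SDB effect reads SDB status: under the default null
        # the generator is blind to the SDB labels by construction.
        if sdb_positive is None:
            raise ValueError("sdb_effect != 0 requires SDB labels")
        v = v + config.sdb_effect * sdb_positive.astype(float)[:, None]
    v = v + site_offsets[site_index]
    if config.noise_sd > 0:
        v = v + config.noise_sd * rng.standard_normal(v.shape)
    return np.maximum(v, 1.0)


def generate_reference_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, ParcelMatrix]:
    """Generate the heterogeneous multi-site reference (training) cohort.

    Ages, sites and sexes are drawn with deliberately unequal frequencies
    (older-skewed ages, geometric site sizes, site-dependent sex ratios) to
    exercise the stratified subsampling of the brain-age stage.  No
    diagnosis or SDB terms enter the volume model.
    """
    if config.n_reference < 8:
        raise ValueError(
            "n_reference is too small: stratified subsampling requires subjects in "
            "at least two age-bracket x sex strata (need n_reference >= 8)"
        )
    params = parcel_parameters(config)
    rng = np.random.default_rng(_seed_streams(config)["reference"])
    n = config.n_reference
    lo, hi = config.reference_age_range

    site_probs = 0.72 ** np.arange(config.n_sites)
    site_probs /= site_probs.sum()
    site_index = rng.choice(config.n_sites, size=n, p=site_probs)
    sites = np.array([f"REF{k + 1:02d}" for k in range(config.n_sites)])

    female_fracs = np.array([0.30, 0.62, 0.45, 0.38, 0.55, 0.33, 0.60])
    female_fracs = female_fracs[np.arange(config.n_sites) % len(female_fracs)]
    sex = np.where(rng.random(n) < female_fracs[site_index], "female", "male")

    # older-skewed ages (beta(2, 1.4) over the range) -> unequal bracket sizes
    age = lo + (hi - lo) * rng.beta(2.0, 1.4, size=n)

    bmi = np.clip(27.0 + 4.5 * rng.standard_normal(n), 15.0, 55.0)
    education = np.clip(np.round(14.0 + 3.0 * rng.standard_normal(n)), 6.0, 22.0)
    apoe4 = rng.choice([0, 1, 2], size=n, p=[0.72, 0.24, 0.04])

    diagnosis = np.full(n, "HC")
    offsets = _site_offsets(rng, config.n_sites, config.n_parcels, config.site_offset_sd)
    true_offset = np.empty(n)
    values = _volumes(config, params, rng, age, diagnosis, None, site_index, offsets, true_offset)

    cohort = pd.DataFrame(
        {
            "subject_id": [f"REF{i:05d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "diagnosis": diagnosis,
            "sdb_status": pd.Series([pd.NA] * n, dtype="object"),
            "bmi": bmi,
            "education_years": education,
            "apoe4_count": apoe4,
            "site": sites[site_index],
            "protocol": ["site-native"] * n,
            "field_strength": ["3T"] * n,
            "treatment_flag": [False] * n,
            "true_brainage_offset": true_offset,  # simulation ground truth
        }
    )
    parcel_ids = [f"parcel_{p + 1:03d}" for p in range(config.n_parcels)]
    return cohort, ParcelMatrix(values, parcel_ids, list(cohort["subject_id"]))


def generate_study_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, ParcelMatrix]:
    """Generate the six diagnosis x SDB study cells with matched covariates.

    Covariates are drawn identically for both SDB arms unless the
    ``sdb_age_shift`` / ``sdb_bmi_shift`` imbalance knobs are set, so the
    arms are exchangeable under the default configuration.  A
    ``missing_rate`` fraction of subjects has BMI (60%) or education (40%)
    masked as missing, completely at random.
    """
    params = parcel_parameters(config)
    rng = np.random.default_rng(_seed_streams(config)["study"])
    cells = _cell_sizes(config)
    lo, hi = config.study_age_range

    rows = []
    for dx in DIAGNOSES:
        for arm, n_arm in zip(("negative", "positive"), cells[dx]):
            for _ in range(n_arm):
                rows.append((dx, arm))
    n = len(rows)
    diagnosis = np.array([r[0] for r in rows])
    sdb = np.array([r[1] for r in rows])
    sdb_positive = sdb == "positive"

    mu, sd = 74.5, 7.4
    a, b = (lo - mu) / sd, (hi - mu) / sd
    age = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)
    age = np.clip(age + config.sdb_age_shift * sdb_positive, lo, hi)

    sex = np.where(rng.random(n) < 0.33, "female", "male")
    bmi = np.clip(29.0 + 5.7 * rng.standard_normal(n) + config.sdb_bmi_shift * sdb_positive, 15.0, 60.0)
    education = np.clip(np.round(16.0 + 2.7 * rng.standard_normal(n)), 6.0, 22.0)
    apoe4 = rng.choice([0, 1, 2], size=n, p=[0.52, 0.37, 0.11])
    site_index = rng.choice(config.n_study_sites, size=n)
    sites = np.array([f"ADNI{k + 1:02d}" for k in range(config.n_study_sites)])
    protocol = np.where(rng.random(n) < 0.73, "MP-RAGE", "IR-SPGR")
    field_strength = np.where(rng.random(n) < 0.4, "1.5T", "3T")
    treatment = sdb_positive & (rng.random(n) < 0.34)

    offsets = _site_offsets(rng, config.n_study_sites, config.n_parcels, config.site_offset_sd)
    true_offset = np.empty(n)
    values = _volumes(
        config, params, rng, age, diagnosis, sdb_positive, site_index, offsets, true_offset
    )

    bmi = bmi.astype(object)
    education = education.astype(object)
    if config.missing_rate > 0:
        miss = rng.random(n) < config.missing_rate
        which_bmi = rng.random(n) < 0.6
        bmi[miss & which_bmi] = pd.NA
        education[miss & ~which_bmi] = pd.NA

    cohort = pd.DataFrame(
        {
            "subject_id": [f"STU{i:05d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "diagnosis": diagnosis,
            "sdb_status": sdb,
            "bmi": bmi,
            "education_years": education,
            "apoe4_count": apoe4,
            "site": sites[site_index],
            "protocol": protocol,
            "field_strength": field_strength,
            "treatment_flag": treatment,
            "true_brainage_offset": true_offset,  # simulation ground truth
        }
    )
    parcel_ids = [f"parcel_{p + 1:03d}" for p in range(config.n_parcels)]
    return cohort, ParcelMatrix(values, parcel_ids, list(cohort["subject_id"]))


def paint_voxel_image(
    parcel_values: np.ndarray,
    atlas: AtlasLabelMap,
    voxel_noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Paint parcel values back into a voxel grid (fixture generator).

    Each voxel of label ``l`` receives ``parcel_values[l] / (count_l *
    voxel_volume)`` plus Gaussian noise, so sum-aggregation (which scales by
    the voxel volume) returns ``parcel_values`` exactly in the noise-free
    case.  Background voxels are zero.
    """
    parcel_values = np.asarray(parcel_values, dtype=float)
    if parcel_values.shape != (atlas.n_parcels,):
        raise ValueError(
            f"expected {atlas.n_parcels} parcel values, got shape {parcel_values.shape}"
        )
    counts = atlas.voxel_counts()
    if (counts == 0).any():
        bad = atlas.label_table.loc[counts == 0, "parcel_id"].iloc[0]
        raise ValueError(f"label for parcel {bad!r} has zero voxels in the atlas grid")

    per_voxel = np.zeros(int(atlas.labels.max()) + 1)
    order = atlas.label_table["label"].to_numpy()
    per_voxel[order] = parcel_values / (counts * atlas.voxel_volume)
    image = per_voxel[atlas.labels]
    if voxel_noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = image + voxel_noise_sd * rng.standard_normal(image.shape) * (atlas.labels > 0)
    return image


# ---------------------------------------------------------------------------
# Analytic summaries of the generating model (used as test oracles)


def analytic_age_sd(config: SimulationConfig) -> float:
    """Standard deviation (years) of the optimal chronological-age readout
    for a healthy subject.

    Two irreducible components: per-parcel noise (parcel noise plus site
    offsets, both invisible to a model trained across sites) propagated
    through the generalized least-squares combination of all parcels,
    sigma_eff / ||s||_2, and the biological brain-aging heterogeneity of
    healthy subjects (brain age differs from chronological age by the HC
    offset SD even with a perfect brain readout).
    """
    params = parcel_parameters(config)
    sigma_eff = math.hypot(config.noise_sd, config.site_offset_sd)
    readout = sigma_eff / float(np.linalg.norm(params.slope))
    return math.hypot(readout, config.brainage_offset_sd_years["HC"])


def analytic_mae_floor(config: SimulationConfig) -> float:
    """Noise-model floor for the mean absolute age-prediction error (years)."""
    return math.sqrt(2.0 / math.pi) * analytic_age_sd(config)


def expected_brainage_offsets(config: SimulationConfig) -> dict[str, float]:
    """Per-diagnosis brain-age offset (years) seen by the optimal readout.

    The global advanced-aging implant contributes its value exactly; the
    focal atrophy contributes ``delta * sum_affected(-s_p) / ||s||^2``.
    """
    params = parcel_parameters(config)
    denom = float(np.sum(params.slope**2))
    focal_gain = float(np.sum(-params.slope[params.affected])) / denom
    return {
        dx: config.brainage_offset_years[dx] + config.diagnosis_effects[dx] * focal_gain
        for dx in DIAGNOSES
    }


def null_sdb_config(config: SimulationConfig | None = None, **overrides) -> SimulationConfig:
    """Convenience: a copy of ``config`` with a guaranteed-zero SDB effect."""
    config = config or SimulationConfig()
    return replace(config, sdb_effect=0.0, **overrides)
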