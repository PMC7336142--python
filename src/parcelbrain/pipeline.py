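"""End-to-end pipeline: simulate -> impute + match -> parcel-wise inference
-> brain age, with a run manifest and publication-style report tables.

A run is fully determined by its :class:`PipelineConfig` (serializable to
YAML): the master seed is split into per-stage seeds through a
counter-based scheme, every stage writes its outputs as TSV into the run
directory, and a JSON manifest records the configuration, derived seeds
and package version.  Stages communicate only through their declared file
interfaces, and a stage failure halts the run naming the stage while
preserving partial outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ParcelMatrix, read_cohort, write_cohort
from .simulate import SimulationConfig, generate_reference_cohort, generate_study_cohort
from .matching import balance_table, estimate_propensity, impute_missing, match_pairs
from .inference import FACTORS, run_parcelwise_analysis
from .brainage import (
    StratificationConfig,
    SVRHyper,
    evaluate_groups,
    harmonize_cohorts,
    predict_ensemble,
    train_ensemble,
)

__all__ = ["PipelineConfig", "run_pipeline", "render_report"]

logger = logging.getLogger("parcelbrain.pipeline")

_STAGES = ("simulate", "match", "inference", "brainage", "report")


@dataclass
class PipelineConfig:
    """Whole-run configuration; a serialized config fully determines a run."""

    out_dir: str = "parcelbrain_run"
    seed: int = 0
    stages: tuple[str, ...] = _STAGES
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    m_imputations: int = 5
    caliper: float | None = None  # propensity-logit units; None = 0.2 SD
    factors: tuple[str, ...] = FACTORS
    n_perm: int = 1000
    stratification: StratificationConfig = field(default_factory=StratificationConfig)
    svr: SVRHyper = field(default_factory=SVRHyper)
    brainage_n_perm: int = 2000

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in _STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; choose from {_STAGES}")
        if self.n_perm < 100 or self.brainage_n_perm < 100:
            raise ValueError("permutation counts must be at least 100")
        if self.m_imputations < 1:
            raise ValueError("m_imputations must be at least 1")

    # -- YAML round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["factors"] = list(self.factors)
        d["simulation"]["reference_age_range"] = list(self.simulation.reference_age_range)
        d["simulation"]["study_age_range"] = list(self.simulation.study_age_range)
        d["simulation"]["n_study_per_cell"] = {
            dx: (n if np.isscalar(n) else list(n))
            for dx, n in self.simulation.n_study_per_cell.items()
        }
        d["stratification"]["bracket_range"] = list(self.stratification.bracket_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = dict(d.pop("simulation", {}))
        for key in ("reference_age_range", "study_age_range"):
            if key in sim:
                sim[key] = tuple(sim[key])
        strat = dict(d.pop("stratification", {}))
        if "bracket_range" in strat:
            strat["bracket_range"] = tuple(strat["bracket_range"])
        svr = dict(d.pop("svr", {}))
        for key in ("stages", "factors"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(
            simulation=SimulationConfig(**sim),
            stratification=StratificationConfig(**strat),
            svr=SVRHyper(**svr),
            **d,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("pipeline config YAML must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _stage_seeds(master: int) -> dict[str, int]:
    state = np.random.SeedSequence(master).generate_state(4) % (2**31)
    return dict(zip(("simulate", "match", "inference", "brainage"), (int(s) for s in state)))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = {
        "package": "parcelbrain",
        "version": __version__,
        "config": config.to_dict(),
        "stage_seeds": seeds,
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    for stage in [s for s in _STAGES if s in config.stages]:
        t0 = time.perf_counter()
        logger.info("stage %s: starting (seed %s)", stage, seeds.get(stage, "-"))
        try:
            _STAGE_FUNCS[stage](config, run_dir, seeds)
        except Exception as e:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
        logger.info("stage %s: done in %.1fs", stage, time.perf_counter() - t0)
    return run_dir


# -- stages -----------------------------------------------------------------


def _stage_simulate(config: PipelineConfig, run_dir: Path, seeds: dict) -> None:
    out = run_dir / "cohorts"
    out.mkdir(exist_ok=True)
    sim = dataclasses.replace(config.simulation, seed=seeds["simulate"])
    ref_cohort, ref_parcels = generate_reference_cohort(sim)
    study_cohort, study_parcels = generate_study_cohort(sim)
    write_cohort(ref_cohort, out / "reference_cohort.tsv")
    ref_parcels.to_tsv(out / "reference_parcels.tsv")
    write_cohort(study_cohort, out / "study_cohort.tsv")
    study_parcels.to_tsv(out / "study_parcels.tsv")


def _stage_match(config: PipelineConfig, run_dir: Path, seeds: dict) -> None:
    out = run_dir / "matching"
    out.mkdir(exist_ok=True)
    cohort = read_cohort(run_dir / "cohorts" / "study_cohort.tsv")
    _, pooled = impute_missing(cohort, m=config.m_imputations, seed=seeds["match"])
    write_cohort(pooled, out / "imputed_pooled.tsv")
    balance_table(None, pooled).to_csv(out / "balance_before.tsv", sep="\t", index=False)
    model = estimate_propensity(pooled)
    scores = model.predict(pooled)
    matched = match_pairs(pooled, scores, caliper=config.caliper, seed=seeds["match"])
    matched.to_tsv(out / "matched_pairs.tsv")
    balance_table(matched, pooled).to_csv(out / "balance_after.tsv", sep="\t", index=False)
    matched_cohort = pooled.set_index("subject_id").loc[matched.matched_ids].reset_index()
    write_cohort(matched_cohort, out / "matched_cohort.tsv")


def _matched_inputs(config: PipelineConfig, run_dir: Path):
    parcels = ParcelMatrix.from_tsv(run_dir / "cohorts" / "study_parcels.tsv")
    matched_path = run_dir / "matching" / "matched_cohort.tsv"
    if "match" in config.stages and matched_path.exists():
        cohort = read_cohort(matched_path)
        parcels = parcels.subset(list(cohort["subject_id"].astype(str)))
    else:
        cohort = read_cohort(run_dir / "cohorts" / "study_cohort.tsv")
    return cohort, parcels


def _stage_inference(config: PipelineConfig, run_dir: Path, seeds: dict) -> None:
    out = run_dir / "inference"
    out.mkdir(exist_ok=True)
    cohort, parcels = _matched_inputs(config, run_dir)
    results = run_parcelwise_analysis(
        parcels, cohort, factors=config.factors, n_perm=config.n_perm, seed=seeds["inference"]
    )
    counts = []
    for factor, res in results.items():
        safe = factor.replace(":", "_x_")
        res.to_frame().to_csv(out / f"{safe}.tsv", sep="\t", index=False)
        pd.DataFrame({"max_f": res.null_max}).to_csv(
            out / f"null_max_{safe}.tsv", sep="\t", index=False
        )
        counts.append(
            {"factor": factor, "n_significant": res.n_significant,
             "fwe_threshold": res.threshold}
        )
    pd.DataFrame(counts).to_csv(out / "significant_counts.tsv", sep="\t", index=False)


def _stage_brainage(config: PipelineConfig, run_dir: Path, seeds: dict) -> None:
    out = run_dir / "brainage"
    out.mkdir(exist_ok=True)
    ref_cohort = read_cohort(run_dir / "cohorts" / "reference_cohort.tsv")
    ref_parcels = ParcelMatrix.from_tsv(run_dir / "cohorts" / "reference_parcels.tsv")
    cohort, parcels = _matched_inputs(config, run_dir)
    strat = dataclasses.replace(config.stratification, seed=seeds["brainage"])
    ref_parcels, parcels = harmonize_cohorts(ref_parcels, ref_cohort, parcels, cohort)
    ensemble = train_ensemble(ref_cohort, ref_parcels, strat, config.svr)
    predicted = predict_ensemble(ensemble, parcels)
    result = evaluate_groups(
        predicted, cohort, n_perm=config.brainage_n_perm, seed=seeds["brainage"]
    )
    result.per_subject.to_csv(out / "brainage.tsv", sep="\t", index=False)
    result.group_summary.to_csv(out / "group_summary.tsv", sep="\t", index=False)
    result.anova.to_csv(out / "anova.tsv", sep="\t", index=False)


def _stage_report(config: PipelineConfig, run_dir: Path, seeds: dict) -> None:
    render_report(run_dir)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "match": _stage_match,
    "inference": _stage_inference,
    "brainage": _stage_brainage,
    "report": _stage_report,
}


def render_report(run_dir) -> dict[str, pd.DataFrame]:
    """Assemble publication-style summary tables from completed stage outputs.

    Pure pass-through: report values equal those in the underlying stage
    TSVs.  A missing stage output raises a named error.
    """
    run_dir = Path(run_dir)
    out = run_dir / "report"
    out.mkdir(exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}

    sources = {
        "balance": run_dir / "matching" / "balance_after.tsv",
        "significant_counts": run_dir / "inference" / "significant_counts.tsv",
        "brainage_groups": run_dir / "brainage" / "group_summary.tsv",
        "brainage_anova": run_dir / "brainage" / "anova.tsv",
    }
    for name, src in sources.items():
        if not src.exists():
            raise FileNotFoundError(
                f"report input {src.name!r} missing: stage {src.parent.name!r} has not run"
            )
        df = pd.read_csv(src, sep="\t")
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        tables[name] = df
    return tables
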