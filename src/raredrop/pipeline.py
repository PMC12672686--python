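"""End-to-end orchestration: simulate -> detect -> curate -> phenotype ->
enumerate -> stats -> predict, with a reproducible run report.

The run is configured by a schema-validated :class:`RunConfig` (unknown
keys rejected), seeded from a single integer, and writes every tabular
artifact as CSV plus Parquet under the output directory together with a
JSON report carrying the stage funnel (events detected -> curated ->
phenotyped), artifact checksums and the full configuration echo.  Rerunning
a completed run with an unchanged config reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import artifactfilter, enumstats, phenotype, predict as predict_mod, raredetect, synthgen

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "demo_config"]

#: Config defaults that are this package's choices rather than assay facts.
REPO_DEFAULT_FIELDS = (
    "cohort.n_background_cells",
    "cohort.artifact_rate",
    "cohort.covariate_correlation",
    "detection.distance_quantile",
    "detection.max_rare_cluster_size",
    "detection.variance_retained",
    "curation.n_training_events",
    "curation.artifact_fraction",
    "curation.cv_folds",
)


class CohortSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    state_counts: dict[str, int] = Field(
        default_factory=lambda: dict(synthgen.COHORT_LAYOUT_TEXT)
    )
    n_background_cells: int = 1500
    artifact_rate: float = 0.02
    covariate_correlation: float = 0.5


class DetectionSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    variance_retained: float = 0.95
    linkage: str = "complete"
    # desk-scale cohorts carry a far larger rare fraction than real slides,
    # so the screen threshold sits lower and clusters may be larger
    distance_quantile: float = 90.0
    singleton_quantile: float = 99.5
    max_rare_cluster_size: float = 0.2
    min_cluster_support: int = 3

    def to_params(self) -> raredetect.DetectionParams:
        return raredetect.DetectionParams(
            variance_retained=self.variance_retained,
            linkage=self.linkage,
            distance_quantile=self.distance_quantile,
            singleton_quantile=self.singleton_quantile,
            max_rare_cluster_size=self.max_rare_cluster_size,
            min_cluster_support=self.min_cluster_support,
        )


class CurationSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_training_events: int = 2000
    artifact_fraction: float = 0.3
    confidence_threshold: float = 0.90
    cv_folds: int = 5


class StageToggles(BaseModel):
    model_config = ConfigDict(extra="forbid")
    detect: bool = True
    curate: bool = True
    phenotype: bool = True
    stats: bool = True
    umap: bool = True
    predict: bool = True


class RunConfig(BaseModel):
    """Validated pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    out_dir: str = "raredrop_run"
    stages: StageToggles = Field(default_factory=StageToggles)
    cohort: CohortSettings = Field(default_factory=CohortSettings)
    detection: DetectionSettings = Field(default_factory=DetectionSettings)
    curation: CurationSettings = Field(default_factory=CurationSettings)
    prediction_tasks: list[str] = Field(default_factory=lambda: ["precursor_vs_overt"])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)


def demo_config(out_dir: str, seed: int = 0, n_per_state: int = 2) -> RunConfig:
    """Small bundled demo: a few samples per state, minutes on one CPU."""
    return RunConfig(
        seed=seed,
        out_dir=str(out_dir),
        cohort=CohortSettings(
            state_counts={s: n_per_state for s in synthgen.DISEASE_STATES},
            n_background_cells=800,
        ),
        stages=StageToggles(predict=False, umap=True),
    )


def analyze_cohort_enumerations(
    state_counts: dict[str, int],
    seed: int,
    n_background_cells: int = 600,
    detection: DetectionSettings | None = None,
) -> pd.DataFrame:
    """Simulate a cohort and run detect -> phenotype -> enumerate in memory.

    A file-free version of the pipeline's analysis chain, returning the
    wide per-sample cells/mL table; used for repeated-cohort experiments
    where writing artifacts per run would dominate the cost.
    """
    det_params = (detection or DetectionSettings()).to_params()
    root = np.random.SeedSequence(seed)
    enum_list = []
    for state in synthgen.DISEASE_STATES:
        for j in range(state_counts.get(state, 0)):
            spec = synthgen.SampleSpec.from_preset(
                state, sample_id=f"{state}-{j:02d}", n_background_cells=n_background_cells
            )
            events, _ = synthgen.generate_event_table(spec, root.spawn(1)[0])
            res = raredetect.detect_rare_events(events, det_params)
            kept = events.loc[res.flags == "rare"]
            thresholds = phenotype.estimate_thresholds(events)
            phenotyped = phenotype.phenotype_events(kept, thresholds)
            enum_list.append(
                enumstats.enumerate_sample(
                    phenotyped,
                    sample_id=spec.sample_id,
                    disease_state=state,
                    n_analyzed_cells=spec.n_analyzed_cells,
                    cbc_total_nucleated=spec.cbc_nucleated_per_ml * spec.blood_volume_ml,
                    blood_volume_ml=spec.blood_volume_ml,
                )
            )
    return enumstats.enumeration_table(enum_list)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_table(df: pd.DataFrame, out: Path, name: str, checksums: dict) -> None:
    csv_path = out / f"{name}.csv"
    df.to_csv(csv_path, index=False)
    checksums[csv_path.name] = _sha256(csv_path)
    try:
        pq_path = out / f"{name}.parquet"
        df.to_parquet(pq_path, index=False)
        checksums[pq_path.name] = _sha256(pq_path)
    except Exception as exc:  # parquet is a convenience copy
        logger.warning("parquet write failed for %s: %s", name, exc)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log.jsonl"
    log_fh = open(log_path, "w")

    def log_event(stage: str, **kw) -> None:
        log_fh.write(json.dumps({"stage": stage, **kw}, sort_keys=True) + "\n")

    checksums: dict[str, str] = {}
    funnel: dict[str, int] = {}

    # --- simulate -----------------------------------------------------
    cohort_cfg = synthgen.CohortConfig(
        state_counts=config.cohort.state_counts,
        n_background_cells=config.cohort.n_background_cells,
        artifact_rate=config.cohort.artifact_rate,
        covariate_correlation=config.cohort.covariate_correlation,
        seed=config.seed,
    )
    samples, clinical = synthgen.generate_cohort(cohort_cfg)
    events = pd.concat([ev for ev, _ in samples.values()], ignore_index=True)
    truth = pd.concat([tr for _, tr in samples.values()], ignore_index=True)
    _write_table(events, out, "events", checksums)
    _write_table(truth, out, "truth", checksums)
    _write_table(clinical, out, "clinical", checksums)
    funnel["simulated"] = len(events)
    log_event("simulate", n_samples=len(samples), n_events=len(events))

    # --- detect -------------------------------------------------------
    if config.stages.detect:
        det_params = config.detection.to_params()
        flagged = []
        det_rows = []
        for sid, (ev, _) in samples.items():
            res = raredetect.detect_rare_events(ev, det_params)
            det = res.to_frame()
            det.insert(0, "cell_id", ev["cell_id"].to_numpy())
            det_rows.append(det)
            flagged.append(ev.loc[(res.flags == "rare")])
        detection = pd.concat(det_rows, ignore_index=True)
        detected = pd.concat(flagged, ignore_index=True)
        _write_table(detection, out, "detection", checksums)
    else:
        detected = events
    funnel["detected"] = len(detected)
    log_event("detect", enabled=config.stages.detect, n_detected=len(detected))

    # --- curate -------------------------------------------------------
    if config.stages.curate:
        training = synthgen.generate_curation_set(
            n_events=config.curation.n_training_events,
            artifact_fraction=config.curation.artifact_fraction,
            seed=config.seed + 1,
        )
        model = artifactfilter.train_curation_model(
            training,
            cv_folds=config.curation.cv_folds,
            confidence_threshold=config.curation.confidence_threshold,
            seed=config.seed,
        )
        kept, rejected, conf = artifactfilter.apply_confidence_filter(model, detected)
        curated = kept
        _write_table(
            detected.assign(cell_confidence=conf, kept=conf >= model.confidence_threshold),
            out,
            "curation",
            checksums,
        )
        log_event(
            "curate",
            cv_accuracy=model.mean_cv_accuracy,
            n_kept=len(kept),
            n_rejected=len(rejected),
        )
    else:
        curated = detected
    funnel["curated"] = len(curated)

    # --- phenotype ----------------------------------------------------
    if config.stages.phenotype:
        # thresholds from the full (background-dominated) event population
        thresholds = phenotype.estimate_thresholds(events)
        phenotyped = phenotype.phenotype_events(
            curated, thresholds, drop_dapi_negative=False
        )
        _write_table(phenotyped, out, "phenotyped", checksums)
    else:
        phenotyped = curated.assign(**{"class": ""})
    funnel["phenotyped"] = len(phenotyped)
    log_event("phenotype", n_phenotyped=len(phenotyped))

    # --- enumerate ----------------------------------------------------
    enum_list = []
    for sid, (ev, _) in samples.items():
        sub = phenotyped.loc[phenotyped["sample_id"] == sid]
        spec = synthgen.SampleSpec.from_preset(
            clinical.loc[clinical["sample_id"] == sid, "disease_state"].iloc[0],
            sample_id=sid,
        )
        enum_list.append(
            enumstats.enumerate_sample(
                sub,
                sample_id=sid,
                disease_state=spec.disease_state,
                n_analyzed_cells=spec.n_analyzed_cells,
                cbc_total_nucleated=spec.cbc_nucleated_per_ml * spec.blood_volume_ml,
                blood_volume_ml=spec.blood_volume_ml,
            )
        )
    enum_df = enumstats.enumeration_table(enum_list)
    _write_table(enum_df, out, "enumeration", checksums)
    log_event("enumerate", n_samples=len(enum_df))

    # --- stats --------------------------------------------------------
    if config.stages.stats:
        state_sizes = enum_df["disease_state"].value_counts()
        if (state_sizes >= 2).sum() >= 2:
            usable = [s for s in synthgen.DISEASE_STATES if state_sizes.get(s, 0) >= 2]
            table2 = enumstats.pairwise_state_tests(
                enum_df.loc[enum_df["disease_state"].isin(usable)], states=usable
            )
            _write_table(table2, out, "table2_style", checksums)
        else:
            logger.warning("pairwise tests skipped: fewer than 2 samples per state")
            log_event("stats", skipped="pairwise")
        table3 = enumstats.clinical_correlations(
            enum_df,
            clinical,
            {"age": "continuous", "m_spike": "continuous", "del13": "binary", "gain_1q": "binary"},
        )
        _write_table(table3, out, "table3_style", checksums)
        log_event("stats", n_correlations=len(table3))

    if config.stages.umap and len(phenotyped) >= 20:
        emb = enumstats.morphometric_umap(phenotyped, seed=config.seed)
        _write_table(
            emb[["cell_id", "sample_id", "class", "umap_x", "umap_y"]],
            out,
            "umap",
            checksums,
        )
        log_event("umap", n_events=len(emb))

    # --- predict ------------------------------------------------------
    predictions = {}
    if config.stages.predict:
        for task_name in config.prediction_tasks:
            task = predict_mod.TASKS[task_name]
            try:
                res = predict_mod.multivariate_accuracy(enum_df, task)
            except ValueError as exc:
                logger.warning("prediction task %s skipped: %s", task_name, exc)
                log_event("predict", task=task_name, skipped=str(exc))
                continue
            predictions[task_name] = {
                "accuracy": res.accuracy,
                "n_samples": res.n_samples,
                "top_feature": res.importance_ranking[0],
            }
            log_event("predict", task=task_name, accuracy=res.accuracy)

    report = {
        "seed": config.seed,
        "funnel": funnel,
        "predictions": predictions,
        "checksums": checksums,
        "config": config.model_dump(),
        "repo_default_fields": list(REPO_DEFAULT_FIELDS),
    }
    log_fh.close()
    checksums[log_path.name] = _sha256(log_path)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
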