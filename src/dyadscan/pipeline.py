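"""End-to-end orchestration: config validation, seed cascade, run directory.

A single YAML config (sections: timeline, generator, similarity, rqa,
classify) plus one global seed drives the whole pipeline.  Stage seeds are
derived deterministically from the global seed via a spawned seed sequence
with a fixed stage index (generator=0, annotations=1, classify=2), so any
stage can be re-run in isolation and identical configs give byte-identical
summaries.  All artifacts are written into a run directory together with a
manifest listing every file and the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, ValidationError

from . import classify as clf
from . import io as dio
from . import rqa as rqa_mod
from . import similarity as sim
from . import synthgen as gen

logger = logging.getLogger("dyadscan")

STAGE_INDEX = {"generator": 0, "annotations": 1, "classify": 2}


class TimelineSection(BaseModel):
    n_localizers: int = 10
    clip_duration: float = 12.0
    silence_duration: float = 10.0
    drama_duration: float = 1620.0
    sample_rate: float = 30.0


class GeneratorSection(BaseModel):
    alpha: float = Field(1.0, ge=0)
    beta: float = Field(1.0, ge=0)
    noise_sd: float = Field(0.5, ge=0)
    coupling_weight: float = Field(0.6, ge=0)
    coupling_lag: float = Field(1.0, ge=0)
    coupling_window: Optional[tuple[float, float]] = None
    n_single: int = Field(18, ge=0)
    n_dyads: int = Field(9, ge=0)
    burst_rate: float = Field(6.0, ge=0)
    burst_floor: float = Field(0.35, ge=0, lt=1)
    gaze_smoothness: float = Field(0.5, gt=0)


class SimilaritySection(BaseModel):
    window: float = Field(20.0, gt=0)
    step: float = Field(1.0, gt=0)
    alpha: float = Field(0.05, gt=0, lt=1)
    min_run: int = Field(2, ge=1)
    model_kind: Literal["strong", "weak"] = "weak"
    modalities: list[str] = ["eyebrow", "smile", "gaze"]


class RQASection(BaseModel):
    target_rr: float = Field(3.0, gt=0, le=100)
    window: float = Field(20.0, gt=0)
    l_min: int = Field(2, ge=2)
    v_min: int = Field(2, ge=2)
    exclude_loi: bool = True


class ClassifySection(BaseModel):
    split: Literal["random", "subject_wise", "both"] = "both"
    iters: int = Field(200, ge=1)
    train_frac: float = Field(0.8, gt=0, lt=1)
    search_budget: int = Field(20, ge=1)


class PipelineConfig(BaseModel):
    seed: int  # mandatory
    timeline: TimelineSection = TimelineSection()
    generator: GeneratorSection = GeneratorSection()
    similarity: SimilaritySection = SimilaritySection()
    rqa: RQASection = RQASection()
    classify: ClassifySection = ClassifySection()

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        state = np.random.SeedSequence(self.seed).generate_state(len(STAGE_INDEX))
        return int(state[STAGE_INDEX[stage]] % (2**31))


class ConfigError(ValueError):
    """Aggregated, human-readable config validation errors."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors))


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML config file; raise ConfigError listing problems."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(["config file must contain a mapping of sections"])
    return validate_config_dict(raw)


def validate_config_dict(raw: dict) -> PipelineConfig:
    if "seed" not in raw:
        raise ConfigError(["seed: a global seed is mandatory"])
    try:
        return PipelineConfig(**raw)
    except ValidationError as exc:
        msgs = [
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        ]
        raise ConfigError(msgs) from exc


def _build(config: PipelineConfig) -> tuple[gen.StimulusTimeline, gen.GeneratorConfig]:
    tl = gen.build_timeline(**config.timeline.model_dump())
    gc = gen.GeneratorConfig(
        **config.generator.model_dump(), seed=config.stage_seed("generator")
    )
    return tl, gc


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run synthgen -> localizer RSA -> drama scan -> RQA -> classification.

    Writes every artifact under ``outdir`` plus ``summary.json`` and
    ``manifest.json``; returns the summary dict.  Output is a pure function
    of the config (including its seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    def log(stage: str, msg: str) -> None:
        logger.info("stage=%s seed=%s config=%s %s", stage, config.seed, chash, msg)

    written: list[str] = []

    def track(path: Path) -> Path:
        written.append(str(path.relative_to(outdir)))
        return path

    summary: dict = {"config": config.model_dump(), "config_hash": chash}

    # --- simulate -----------------------------------------------------
    timeline, gen_config = _build(config)
    cohort = gen.generate_cohort(gen_config, timeline)
    annotations = gen.generate_annotations(timeline, config.stage_seed("annotations"))
    dio.write_cohort_csv(cohort, track(outdir / "cohort.csv"))
    dio.write_labels_csv(cohort.labels, track(outdir / "labels.csv"))
    dio.write_annotations_csv(annotations, track(outdir / "annotations.csv"))
    summary["cohort"] = {
        "n_subjects": gen_config.n_subjects,
        "n_signals": len(cohort.signals),
        "duration_s": timeline.total_duration,
    }
    log("simulate", f"generated {len(cohort.signals)} signals")

    # --- localizer RSA -------------------------------------------------
    rdm_dir = outdir / "rdms"
    rdm_dir.mkdir(exist_ok=True)
    sim_cfg = config.similarity
    models = {k: sim.model_rdm(cohort.labels, k) for k in ("strong", "weak")}
    for kind, m in models.items():
        dio.write_rdm_csv(m, track(rdm_dir / f"model_{kind}.csv"))
    localizer_summary = {}
    if timeline.n_localizers >= 1:
        for modality in sim_cfg.modalities:
            rdms = sim.localizer_rdms(cohort, modality, window_len=sim_cfg.window)
            for name, r in rdms:
                dio.write_rdm_csv(r, track(rdm_dir / f"{modality}_{name}.csv"))
            entries = [(n, r) for n, r in rdms] + [
                (f"model-{k}", m) for k, m in models.items()
            ]
            if len(entries) >= 2:
                tau, p, masked = sim.compare_all_rdms(entries, alpha=sim_cfg.alpha)
                tau.to_csv(track(rdm_dir / f"{modality}_rdm_tau.csv"))
                p.to_csv(track(rdm_dir / f"{modality}_rdm_p.csv"))
                masked.to_csv(track(rdm_dir / f"{modality}_rdm_tau_masked.csv"))
                localizer_summary[modality] = {
                    "n_rdms": len(entries),
                    "n_comparisons": len(entries) * (len(entries) - 1) // 2,
                }
    summary["localizer_rsa"] = localizer_summary
    log("localizer-rsa", f"{len(localizer_summary)} modalities")

    # --- drama scan -----------------------------------------------------
    scan_summary = {}
    for modality in sim_cfg.modalities:
        res = sim.rsa_scan(
            cohort,
            modality,
            model=sim_cfg.model_kind,
            window_len=sim_cfg.window,
            step=sim_cfg.step,
            alpha=sim_cfg.alpha,
            min_run=sim_cfg.min_run,
        )
        dio.write_scan_outputs(
            res,
            track(outdir / f"scan_windows_{modality}.csv"),
            track(outdir / f"scan_intervals_{modality}.tsv"),
        )
        scan_summary[modality] = {
            "n_windows": int(res.window_starts.size),
            "n_intervals": len(res.intervals),
            "intervals": [list(iv) for iv in res.intervals],
        }
    summary["scan"] = scan_summary
    log("scan", f"{sum(s['n_intervals'] for s in scan_summary.values())} intervals")

    # --- RQA -------------------------------------------------------------
    params = rqa_mod.RQAParams(
        target_rr=config.rqa.target_rr,
        l_min=config.rqa.l_min,
        v_min=config.rqa.v_min,
        exclude_loi=config.rqa.exclude_loi,
    )
    features: list[rqa_mod.RQAFeatures] = []
    for sig in cohort.signals:
        features.extend(
            rqa_mod.windowed_rqa(
                sig,
                window_len=config.rqa.window,
                params=params,
                start=timeline.drama_start,
                duration=timeline.drama_duration,
            )
        )
    dio.write_features_csv(features, cohort.labels, track(outdir / "rqa_features.csv"))
    summary["rqa"] = {
        "n_windows": len(features),
        "segments_per_signal": len(features) // max(1, len(cohort.signals)),
    }
    log("rqa", f"{len(features)} windows quantified")

    # --- classification --------------------------------------------------
    table = clf.assemble_features(features, cohort.labels)
    cls_cfg = config.classify
    kinds = (
        ["random", "subject_wise"] if cls_cfg.split == "both" else [cls_cfg.split]
    )
    cls_summary = {"n_rows": len(table), "n_dropped": table.n_dropped, "results": {}}
    cls_seed = config.stage_seed("classify")
    for kind in kinds:
        res = clf.repeated_eval(
            table,
            split_kind=kind,
            n_iter=cls_cfg.iters,
            seed=cls_seed,
            train_frac=cls_cfg.train_frac,
            search_budget=cls_cfg.search_budget,
        )
        cls_summary["results"][kind] = res.summary()
    summary["classify"] = cls_summary
    dio.write_json(cls_summary, track(outdir / "classify_results.json"))
    log("classify", f"{len(kinds)} split kinds x {cls_cfg.iters} iterations")

    dio.write_json(summary, track(outdir / "summary.json"))
    manifest = {"config_hash": chash, "files": sorted(written) + ["manifest.json"]}
    dio.write_json(manifest, outdir / "manifest.json")
    return summary
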