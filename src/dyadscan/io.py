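"""Plain-text readers/writers for all pipeline artifacts.

Everything is CSV/TSV/JSON so runs can be inspected, diffed and consumed by
standard plotting tools: long-format cohort signals, label tables,
annotation traces, square RDM matrices with a label header row/column,
per-window scan tables, BED-like significant-interval tables and the
windowed RQA feature table.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .rqa import RQAFeatures
from .similarity import RDM, ModelRDM, RSAScanResult
from .synthgen import AnnotationTrace, Cohort, ResponseSignal, StimulusTimeline


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    """Long-format signal table: subject_id, group, dyad_id, modality, t, value."""
    frames = []
    for sig in cohort.signals:
        t = sig.t0 + np.arange(sig.values.size) / sig.sample_rate
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": sig.subject_id,
                    "group": sig.group,
                    "dyad_id": sig.dyad_id if sig.dyad_id is not None else "",
                    "modality": sig.modality,
                    "t": t,
                    "value": sig.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_cohort_csv(
    path: str | Path, timeline: StimulusTimeline, config=None
) -> Cohort:
    """Rebuild a cohort from the long-format CSV (timeline supplied separately)."""
    df = pd.read_csv(path, keep_default_na=False)
    signals: list[ResponseSignal] = []
    labels_rows = {}
    for (sid, modality), g in df.groupby(["subject_id", "modality"], sort=False):
        g = g.sort_values("t")
        dyad = g["dyad_id"].iloc[0] or None
        group = g["group"].iloc[0]
        signals.append(
            ResponseSignal(
                subject_id=sid,
                group=group,
                modality=modality,
                sample_rate=timeline.sample_rate,
                values=g["value"].to_numpy(),
                dyad_id=dyad,
                role_in_dyad=None if dyad is None else int(sid[-1]),
                t0=float(g["t"].iloc[0]),
            )
        )
        labels_rows[sid] = {"subject_id": sid, "group": group, "dyad_id": dyad}
    labels = pd.DataFrame(labels_rows.values(), columns=["subject_id", "group", "dyad_id"])
    return Cohort(signals=signals, labels=labels, timeline=timeline, config=config)


def write_labels_csv(labels: pd.DataFrame, path: str | Path) -> None:
    labels.to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["dyad_id"] = df["dyad_id"].where(pd.notna(df["dyad_id"]), None)
    return df


def write_annotations_csv(
    traces: Iterable[AnnotationTrace], path: str | Path
) -> None:
    frames = []
    for tr in traces:
        t = tr.t0 + np.arange(tr.values.size) / tr.sample_rate
        frames.append(pd.DataFrame({"kind": tr.kind, "t": t, "value": tr.values}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_rdm_csv(rdm: RDM | ModelRDM, path: str | Path) -> None:
    """Square matrix with the subject labels as header row and index column."""
    pd.DataFrame(rdm.matrix, index=rdm.labels, columns=rdm.labels).to_csv(path)


def read_rdm_csv(path: str | Path) -> RDM:
    df = pd.read_csv(path, index_col=0)
    return RDM(labels=list(df.columns), matrix=df.to_numpy(dtype=float))


def write_scan_outputs(
    result: RSAScanResult, windows_path: str | Path, intervals_path: str | Path
) -> None:
    """Per-window CSV plus the BED-like TSV of significant intervals."""
    result.windows_frame().to_csv(windows_path, index=False)
    result.intervals_frame().to_csv(intervals_path, sep="\t", index=False)


def write_features_csv(
    features: Iterable[RQAFeatures],
    labels: pd.DataFrame,
    path: str | Path,
) -> None:
    from .classify import rqa_features_frame

    df = rqa_features_frame(features)
    df = df.merge(labels[["subject_id", "group"]], on="subject_id", how="left")
    cols = [
        "subject_id",
        "group",
        "modality",
        "segment_index",
        "window_start_s",
        "RR",
        "DET",
        "ENTR",
        "LAM",
        "E",
    ]
    df[cols].to_csv(path, index=False)


def read_features_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
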