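"""Plain-text serialisation.

Recordings are delimited matrices (rows = channels, columns = samples) with
a JSON sidecar ``{rate_hz, modality, channel_labels, montage_xy}``.  Event
tables and feature matrices are TSV; feature matrices carry a JSON column
manifest.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Tuple

import numpy as np
import pandas as pd

from .datatypes import (
    CVReport,
    FeatureDescriptor,
    FeatureMatrix,
    Recording,
    SweepCurve,
    validate_events,
)

__all__ = [
    "write_recording", "read_recording", "write_events", "read_events",
    "write_feature_matrix", "read_feature_matrix", "write_cv_report",
    "write_sweep_curve",
]


def write_recording(rec: Recording, prefix) -> None:
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".tsv"), rec.data, delimiter="\t")
    sidecar = {
        "rate_hz": rec.rate,
        "modality": rec.modality,
        "channel_labels": list(rec.channels),
        "montage_xy": None if rec.montage_xy is None else rec.montage_xy.tolist(),
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(prefix) -> Recording:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    data = np.atleast_2d(np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t"))
    xy = meta["montage_xy"]
    return Recording(data, meta["rate_hz"], meta["modality"],
                     meta["channel_labels"], None if xy is None else np.array(xy))


def write_events(events: pd.DataFrame, path) -> None:
    validate_events(events).to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    return validate_events(pd.read_csv(path, sep="\t"))


def write_feature_matrix(fm: FeatureMatrix, prefix) -> None:
    prefix = Path(prefix)
    table = pd.concat(
        [fm.provenance.reset_index(drop=True),
         pd.Series(fm.labels, name="label"),
         pd.DataFrame(fm.values, columns=[f"f{i}" for i in range(fm.n_features)])],
        axis=1,
    )
    table.to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
    manifest = [dataclasses.asdict(d) | {"channel": list(d.channel)}
                for d in fm.descriptors]
    prefix.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def read_feature_matrix(prefix) -> FeatureMatrix:
    prefix = Path(prefix)
    table = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
    manifest = json.loads(prefix.with_suffix(".json").read_text())
    descs = [FeatureDescriptor(m["modality"], m["band"], tuple(m["channel"]),
                               m["window"], m["estimator"]) for m in manifest]
    feat_cols = [c for c in table.columns if c.startswith("f") and c[1:].isdigit()]
    return FeatureMatrix(
        table[feat_cols].to_numpy(float), descs, table["label"].to_numpy(),
        table[["participant", "session", "series"]],
    )


def write_cv_report(report: CVReport, path) -> None:
    payload = {
        "classifier": report.classifier,
        "seed": report.seed,
        "positive_label": report.positive_label,
        "fold_accuracies": report.fold_accuracies.tolist(),
        "accuracy_pct": report.accuracy,
        "sensitivity_pct": report.sensitivity,
        "specificity_pct": report.specificity,
        "auc": report.auc,
        "confusion": dataclasses.asdict(report.confusion),
        "roc_points": report.roc_points.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_sweep_curve(curve: SweepCurve, prefix) -> None:
    prefix = Path(prefix)
    pd.DataFrame({
        "abscissa_s": curve.abscissa,
        "accuracy_pct": curve.accuracy,
        "fold_sd_pct": curve.spread,
    }).to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
    prefix.with_suffix(".json").write_text(json.dumps({
        "mode": curve.mode, "modality": curve.modality,
        "task_pair": list(curve.task_pair),
    }, indent=1))
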