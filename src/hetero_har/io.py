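"""Plain-text serialization of sessions, features and reports.

Recordings are CSV (``t,ax,ay,az``) with a JSON sidecar header
(sensor_id, unit, nominal_rate_hz); annotations are JSON lists of
{label, start_s, end_s}; feature tables are CSV with ``axis_band_stat``
column names.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import EvaluationReport
from .features import DomainDataset, feature_names
from .synth import AnnotationTrack, SensorRecording


def write_recording(rec: SensorRecording, csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    df = pd.DataFrame(
        {"t": rec.timestamps, "ax": rec.acc[:, 0], "ay": rec.acc[:, 1], "az": rec.acc[:, 2]}
    )
    df.to_csv(csv_path, index=False)
    header = {
        "sensor_id": rec.sensor_id,
        "unit": rec.unit,
        "nominal_rate_hz": rec.nominal_rate_hz,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(header, indent=2))


def read_recording(csv_path: str | Path) -> SensorRecording:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    header = json.loads(csv_path.with_suffix(".json").read_text())
    return SensorRecording(
        sensor_id=header["sensor_id"],
        unit=header["unit"],
        timestamps=df["t"].to_numpy(),
        acc=df[["ax", "ay", "az"]].to_numpy(),
        nominal_rate_hz=header.get("nominal_rate_hz", 32.0),
    )


def write_annotations(track: AnnotationTrack, path: str | Path) -> None:
    payload = [
        {"label": label, "start_s": start, "end_s": end}
        for label, start, end in track.intervals
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_annotations(path: str | Path) -> AnnotationTrack:
    payload = json.loads(Path(path).read_text())
    return AnnotationTrack(
        [(iv["label"], float(iv["start_s"]), float(iv["end_s"])) for iv in payload]
    )


def write_features(ds: DomainDataset, path: str | Path) -> None:
    df = pd.DataFrame(ds.X, columns=feature_names())
    if ds.y is not None:
        df.insert(0, "label", ds.y)
    for col, val in (("subject", ds.subject), ("sensor", ds.sensor), ("scenario", ds.scenario)):
        if val:
            df[col] = val
    df.to_csv(path, index=False)


def read_features(path: str | Path) -> DomainDataset:
    df = pd.read_csv(path)
    names = feature_names()
    y = df["label"].to_numpy() if "label" in df else None
    return DomainDataset(
        X=df[names].to_numpy(),
        y=y,
        subject=str(df["subject"].iloc[0]) if "subject" in df else "",
        sensor=str(df["sensor"].iloc[0]) if "sensor" in df else "",
        scenario=str(df["scenario"].iloc[0]) if "scenario" in df else "",
    )


def reports_to_frame(
    rows: Sequence[tuple[str, EvaluationReport]]
) -> pd.DataFrame:
    """Table mirroring the comparative report layout (task columns, F1, acc)."""
    records = []
    for name, report in rows:
        rec = {"name": name}
        rec.update(report.to_row())
        records.append(rec)
    return pd.DataFrame(records)
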