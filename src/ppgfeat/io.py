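"""Plain-text serialization of records, hypnograms and ground truth.

One synthetic subject-night is stored as four files in a directory:
``<id>.csv`` (``time_s,ppg``), ``<id>.json`` (subject metadata sidecar),
``<id>_hypnogram.csv`` (``epoch_index,stage``), and ``<id>_truth.json``
(beat times, artifact windows, age).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .records import GroundTruth, PPGRecord, SubjectMeta

__all__ = ["write_record", "read_record", "write_ground_truth", "read_ground_truth"]


def write_record(record: PPGRecord, out_dir, gt: GroundTruth | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = record.meta.subject_id

    t = np.arange(len(record.samples)) / record.fs
    pd.DataFrame({"time_s": t, "ppg": record.samples}).to_csv(
        out_dir / f"{sid}.csv", index=False, float_format="%.6f"
    )
    sidecar = {
        "subject_id": sid,
        "group": record.meta.group,
        "age": record.meta.age,
        "night": record.meta.night,
        "fs": record.fs,
    }
    (out_dir / f"{sid}.json").write_text(json.dumps(sidecar, indent=1))
    pd.DataFrame(
        {"epoch_index": range(len(record.hypnogram)), "stage": record.hypnogram}
    ).to_csv(out_dir / f"{sid}_hypnogram.csv", index=False)
    if gt is not None:
        write_ground_truth(gt, out_dir / f"{sid}_truth.json")
    return out_dir / f"{sid}.csv"


def read_record(csv_path) -> PPGRecord:
    csv_path = Path(csv_path)
    sid = csv_path.stem
    df = pd.read_csv(csv_path)
    sidecar = json.loads((csv_path.parent / f"{sid}.json").read_text())
    hyp_path = csv_path.parent / f"{sid}_hypnogram.csv"
    hypnogram = pd.read_csv(hyp_path)["stage"].tolist() if hyp_path.exists() else []
    meta = SubjectMeta(
        subject_id=sidecar["subject_id"],
        group=sidecar.get("group", "A"),
        age=float(sidecar.get("age", float("nan"))),
        night=int(sidecar.get("night", 1)),
    )
    return PPGRecord(
        samples=df["ppg"].to_numpy(dtype=float),
        fs=float(sidecar["fs"]),
        meta=meta,
        hypnogram=hypnogram,
    )


def write_ground_truth(gt: GroundTruth, path) -> None:
    payload = {
        "ibi_times": [float(v) for v in gt.ibi_times],
        "ibi_durations": [float(v) for v in gt.ibi_durations],
        "artifact_windows": [[float(a), float(b)] for a, b in gt.artifact_windows],
        "hypnogram_epochs": list(gt.hypnogram_epochs),
        "age": gt.age,
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        ibi_times=np.asarray(payload["ibi_times"], dtype=float),
        ibi_durations=np.asarray(payload["ibi_durations"], dtype=float),
        artifact_windows=[tuple(w) for w in payload["artifact_windows"]],
        hypnogram_epochs=payload["hypnogram_epochs"],
        age=float(payload.get("age", float("nan"))),
    )
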