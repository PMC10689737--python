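"""Segmenting recordings into 5-min windows and assembling the feature matrix.

A recording is processed once (filter, artifact mask, pulse segmentation,
interbeat intervals); features are then computed on non-overlapping 300-s
segments, either tiled over the whole night or over maximal runs of one
sleep stage (runs shorter than ten 30-s epochs yield no segment; Wake is
never used in stage mode).  A segment is accepted only if strictly less than
20% of its samples are artifact-masked and strictly less than 20% of its
interbeat intervals are invalid.  Each accepted segment yields one row of
the 67-feature catalogue (30 HRV + 37 morphology) plus provenance metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fiducials import pulses_to_ibi_series, segment_pulses
from .hrv import HRV_FEATURE_NAMES, filter_ibis, hrv_features
from .morphology import (
    MIN_PULSES_PER_SEGMENT,
    MORPH_FEATURE_NAMES,
    aggregate_segment_morphology,
    pulse_morphology,
)
from .preprocess import SIIConfig, preprocess_record
from .records import EPOCH_S, IBISeries, PPGRecord

__all__ = [
    "FEATURE_NAMES",
    "SEGMENT_S",
    "Segment",
    "FeatureVector",
    "RecordAnalysis",
    "process_record",
    "window_segments",
    "quality_gate",
    "extract_feature_vector",
    "extract_features",
    "features_dataframe",
]

#: The full 67-feature catalogue, HRV first then morphology.
FEATURE_NAMES = HRV_FEATURE_NAMES + MORPH_FEATURE_NAMES

SEGMENT_S = 300.0
QUALITY_MAX_FRACTION = 0.2
MIN_STAGE_RUN_EPOCHS = 10


@dataclass
class Segment:
    """One candidate 300-s analysis window."""

    subject_id: str
    start_s: float
    stage: str = "full-night"
    night: int = 1
    fraction_masked: float = 0.0
    fraction_invalid_ibis: float = 0.0
    accepted: bool = False


@dataclass
class FeatureVector:
    """The 67 catalogued features for one accepted segment, plus metadata."""

    segment: Segment
    features: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.features)
        if missing:
            raise ValueError(f"feature vector incomplete: {sorted(missing)[:3]}...")


@dataclass
class RecordAnalysis:
    """Preprocessed state of one recording, shared by all its segments."""

    record: PPGRecord
    filtered: np.ndarray
    mask: object
    sii: np.ndarray
    pulses: list
    ibis: IBISeries  # whole-record trough-to-trough series with validity flags

    @property
    def fs(self) -> float:
        return 32.0


def process_record(record: PPGRecord, cfg: SIIConfig = SIIConfig()) -> RecordAnalysis:
    """Filter, mask, segment into pulses and derive the record's IBI series."""
    filtered, mask, sii = preprocess_record(record.samples, record.fs, cfg)
    pulses = segment_pulses(filtered, 32.0, mask=mask)
    raw = pulses_to_ibi_series(pulses)
    ibis = filter_ibis(raw) if len(raw) >= 2 else raw
    return RecordAnalysis(record, filtered, mask, sii, pulses, ibis)


def window_segments(
    duration_s: float,
    hypnogram: list,
    stage_mode: str = "full",
) -> list:
    """Candidate segment start times.

    ``stage_mode='full'`` tiles consecutive 300-s windows from the start of
    the recording.  A stage name ('N1/N2', 'N3', 'REM') tiles windows over
    maximal runs of at least :data:`MIN_STAGE_RUN_EPOCHS` consecutive epochs
    of that stage, so every stage segment is stage-pure.  Wake is not a
    valid stage mode.
    """
    if stage_mode == "full":
        n = int(duration_s // SEGMENT_S)
        return [i * SEGMENT_S for i in range(n)]
    if stage_mode == "Wake":
        raise ValueError("Wake data are discarded in stage mode")
    if stage_mode not in ("N1/N2", "N3", "REM"):
        raise ValueError(f"unknown stage mode: {stage_mode!r}")

    starts = []
    i = 0
    n_ep = len(hypnogram)
    while i < n_ep:
        if hypnogram[i] != stage_mode:
            i += 1
            continue
        j = i
        while j + 1 < n_ep and hypnogram[j + 1] == stage_mode:
            j += 1
        run_epochs = j - i + 1
        if run_epochs >= MIN_STAGE_RUN_EPOCHS:
            run_start = i * EPOCH_S
            run_len = run_epochs * EPOCH_S
            for k in range(int(run_len // SEGMENT_S)):
                start = run_start + k * SEGMENT_S
                if start + SEGMENT_S <= duration_s:
                    starts.append(start)
        i = j + 1
    return starts


def _segment_ibis(analysis: RecordAnalysis, start_s: float) -> IBISeries:
    """Slice the whole-record IBI series to intervals inside the window."""
    bt = analysis.ibis.beat_times
    if len(bt) < 2:
        return IBISeries(np.empty(0), np.empty(0), np.empty(0, dtype=bool))
    inside = (bt[:-1] >= start_s) & (bt[1:] <= start_s + SEGMENT_S)
    idx = np.flatnonzero(inside)
    if len(idx) == 0:
        return IBISeries(np.empty(0), np.empty(0), np.empty(0, dtype=bool))
    lo, hi = idx[0], idx[-1]
    return IBISeries(
        bt[lo : hi + 2].copy(),
        analysis.ibis.ibis[lo : hi + 1].copy(),
        analysis.ibis.valid[lo : hi + 1].copy(),
    )


def quality_gate(analysis: RecordAnalysis, segment: Segment) -> Segment:
    """Fill the segment's quality fractions and its accepted flag.

    Accepted iff masked-sample fraction < 20% and invalid-IBI fraction < 20%
    (both strict).
    """
    fs = analysis.fs
    lo = int(segment.start_s * fs)
    hi = min(int((segment.start_s + SEGMENT_S) * fs), len(analysis.filtered))
    segment.fraction_masked = float(analysis.mask.mask[lo:hi].mean()) if hi > lo else 1.0

    seg_ibis = _segment_ibis(analysis, segment.start_s)
    if len(seg_ibis) == 0:
        segment.fraction_invalid_ibis = 1.0
    else:
        segment.fraction_invalid_ibis = float(1.0 - seg_ibis.valid.mean())
    segment.accepted = (
        segment.fraction_masked < QUALITY_MAX_FRACTION
        and segment.fraction_invalid_ibis < QUALITY_MAX_FRACTION
    )
    return segment


def extract_feature_vector(analysis: RecordAnalysis, segment: Segment) -> FeatureVector:
    """Compute all 67 features on one accepted segment.

    Families that cannot be computed (too few beats/pulses) come back as
    missing values; the vector is emitted regardless.
    """
    seg_ibis = _segment_ibis(analysis, segment.start_s)
    if len(seg_ibis) >= 2:
        hrv = hrv_features(seg_ibis)
    else:
        hrv = {k: math.nan for k in HRV_FEATURE_NAMES}

    fs = analysis.fs
    lo = int(segment.start_s * fs)
    hi = int((segment.start_s + SEGMENT_S) * fs)
    pulse_feats = [
        pulse_morphology(p)
        for p in analysis.pulses
        if p.valid and p.start >= lo and p.start + len(p.samples) <= hi
    ]
    morph, _ = aggregate_segment_morphology(pulse_feats)

    features = {**hrv, **morph}
    return FeatureVector(segment=segment, features=features)


def extract_features(
    record: PPGRecord,
    stage_mode: str = "full",
    cfg: SIIConfig = SIIConfig(),
    analysis: RecordAnalysis | None = None,
) -> list:
    """All accepted-segment feature vectors of one recording."""
    if analysis is None:
        analysis = process_record(record, cfg)
    duration = len(analysis.filtered) / analysis.fs
    out = []
    for start in window_segments(duration, record.hypnogram, stage_mode):
        seg = Segment(
            subject_id=record.meta.subject_id,
            start_s=start,
            stage="full-night" if stage_mode == "full" else stage_mode,
            night=record.meta.night,
        )
        quality_gate(analysis, seg)
        if seg.accepted:
            out.append(extract_feature_vector(analysis, seg))
    return out


def features_dataframe(records: list, stage_mode: str = "full", cfg: SIIConfig = SIIConfig()) -> pd.DataFrame:
    """Tidy feature matrix: one row per accepted segment across recordings.

    ``records`` is an iterable of :class:`PPGRecord` (group and age are read
    from each record's metadata).  Missing feature values are NaN.
    """
    rows = []
    for record in records:
        analysis = process_record(record, cfg)
        for fv in extract_features(record, stage_mode, cfg, analysis=analysis):
            row = {
                "subject": record.meta.subject_id,
                "group": record.meta.group,
                "night": record.meta.night,
                "age": record.meta.age,
                "stage": fv.segment.stage,
                "start_s": fv.segment.start_s,
            }
            row.update(fv.features)
            rows.append(row)
    cols = ["subject", "group", "night", "age", "stage", "start_s", *FEATURE_NAMES]
    return pd.DataFrame(rows, columns=cols)
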