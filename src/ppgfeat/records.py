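"""Core in-memory containers shared across the pipeline.

A :class:`PPGRecord` is one subject-night of raw (or filtered) wristband PPG
together with its 30-s-epoch hypnogram and subject metadata.  An
:class:`IBISeries` holds trough-to-trough beat times and the derived
interbeat intervals with per-interval validity flags.  Ground truth emitted
by the synthetic generator travels in :class:`GroundTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sleep-stage labels used on 30-s hypnogram epochs.
STAGES = ("Wake", "N1/N2", "N3", "REM")

#: Hypnogram epoch length in seconds.
EPOCH_S = 30.0


@dataclass
class SubjectMeta:
    """Identity and covariates for one subject-night."""

    subject_id: str
    group: str = "A"
    age: float = float("nan")
    night: int = 1


@dataclass
class PPGRecord:
    """One subject-night of single-channel PPG.

    Parameters
    ----------
    samples : ndarray
        Raw or filtered PPG amplitude, one value per sample.
    fs : float
        Sampling rate in Hz (the pipeline operates at 32 Hz).
    meta : SubjectMeta
        Subject identity, group label, age and night index.
    hypnogram : list of str
        One stage label per 30-s epoch, drawn from :data:`STAGES`.
    """

    samples: np.ndarray
    fs: float
    meta: SubjectMeta
    hypnogram: list = field(default_factory=list)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class IBISeries:
    """Beat times (s) and interbeat intervals (ms) with validity flags.

    ``ibis[i]`` spans ``beat_times[i]`` to ``beat_times[i + 1]``; ``valid``
    has one flag per interval.  Physiologically plausible intervals lie in
    [300, 2400] ms.
    """

    beat_times: np.ndarray
    ibis: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.ibis = np.asarray(self.ibis, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.ibis) != max(len(self.beat_times) - 1, 0):
            raise ValueError("ibis must have len(beat_times) - 1 entries")
        if len(self.valid) != len(self.ibis):
            raise ValueError("valid must have one flag per interval")

    @classmethod
    def from_beat_times(cls, beat_times) -> "IBISeries":
        beat_times = np.asarray(beat_times, dtype=float)
        ibis = np.diff(beat_times) * 1000.0
        return cls(beat_times, ibis, np.ones(len(ibis), dtype=bool))

    @property
    def valid_ibis(self) -> np.ndarray:
        return self.ibis[self.valid]

    def __len__(self) -> int:
        return len(self.ibis)


@dataclass
class GroundTruth:
    """Generator-side truth for one synthetic subject-night."""

    ibi_times: np.ndarray
    ibi_durations: np.ndarray
    artifact_windows: list
    hypnogram_epochs: list
    age: float = float("nan")

    def __post_init__(self) -> None:
        self.ibi_times = np.asarray(self.ibi_times, dtype=float)
        self.ibi_durations = np.asarray(self.ibi_durations, dtype=float)
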