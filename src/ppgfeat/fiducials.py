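"""Pulse segmentation and fiducial-point location.

Beats are delimited by onset troughs found with the two-moving-average
(systolic-block) scheme of Elgendi et al.: the filtered signal is band-passed
to the cardiac band, clipped, squared, and a short "peak" moving average is
compared against a longer "beat" moving average plus an offset; blocks where
the short average wins mark systolic upstrokes.  Troughs between consecutive
systolic peaks delimit pulses, and the final trough of pulse *k* is the
initial trough of pulse *k+1*, which keeps pulse-width durations and
interbeat intervals consistent.

Per pulse, landmarks are located on the waveform (IT, SP, DP, FT), its first
derivative (a1 = maximum systolic velocity, b1 = first minimum after a1, and
the end-diastolic velocity EDV), and its second derivative (a2 = early
maximum, b2 = deepest trough, e2 = the local maximum between b2 and FT that
marks the notch between systolic and diastolic peaks).  A detected systolic
peak at or after e2 is treated as a misdetection (the diastolic peak was
picked) and redefined as the maximum between IT and e2.

All argmax/argmin tie-breaks take the earliest index.  Derivatives are
central differences, with 3-point smoothing of the first derivative before
differentiating again — at 32 Hz raw second differences are too noisy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .preprocess import ArtifactMask
from .records import IBISeries

__all__ = [
    "PulseWave",
    "detect_beats",
    "segment_pulses",
    "locate_derivative_fiducials",
    "refine_systolic_peak",
    "pulses_to_ibi_series",
]

# Elgendi systolic-block parameters (published defaults, scaled to fs)
W_PEAK_S = 0.111
W_BEAT_S = 0.667
BETA = 0.02


@dataclass
class PulseWave:
    """One segmented heartbeat with fiducial indices.

    Indices are 0-based offsets into ``samples``; ``start`` is the absolute
    sample index of IT in the parent record.  ``valid`` requires IT, SP and
    FT (IT and FT are structural here — both troughs delimit the window — so
    validity hinges on a usable SP).  Derivative landmarks may be ``None``;
    consumers emit the affected features as missing.
    """

    samples: np.ndarray
    fs: float
    start: int = 0
    it: int = 0
    sp: int | None = None
    ft: int = field(default=-1)
    dp: int | None = None
    a1: int | None = None
    b1: int | None = None
    a2: int | None = None
    b2: int | None = None
    e2: int | None = None
    d1: np.ndarray | None = None
    d2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.ft < 0:
            self.ft = len(self.samples) - 1

    @property
    def valid(self) -> bool:
        return self.sp is not None and self.it < self.sp < self.ft

    def ensure_derivatives(self) -> None:
        """Central-difference velocity and (smoothed) acceleration, once."""
        if self.d1 is None:
            self.d1 = np.gradient(self.samples) * self.fs
            sm = uniform_filter1d(self.d1, size=3, mode="nearest")
            self.d2 = np.gradient(sm) * self.fs


def _odd(n: int) -> int:
    n = max(int(round(n)), 1)
    return n if n % 2 else n + 1


def detect_beats(x: np.ndarray, fs: float) -> tuple:
    """Locate systolic peaks and the onset troughs between them.

    Returns ``(peaks, troughs)`` as absolute sample indices; ``troughs`` has
    one entry between each consecutive peak pair.
    """
    x = np.asarray(x, dtype=float)
    sos = sps.butter(2, [0.5, 8.0], btype="bandpass", fs=fs, output="sos")
    z = sps.sosfiltfilt(sos, x)
    y = np.square(np.clip(z, 0.0, None))

    w_peak = _odd(W_PEAK_S * fs)
    w_beat = _odd(W_BEAT_S * fs)
    ma_peak = uniform_filter1d(y, size=w_peak, mode="nearest")
    ma_beat = uniform_filter1d(y, size=w_beat, mode="nearest")
    thr1 = ma_beat + BETA * float(np.mean(y))

    above = ma_peak > thr1
    edges = np.flatnonzero(np.diff(np.concatenate([[0], above.astype(np.int8), [0]])))
    peaks = []
    for lo, hi in zip(edges[::2], edges[1::2]):
        if hi - lo >= w_peak:
            peaks.append(lo + int(np.argmax(x[lo:hi])))
    peaks = np.asarray(peaks, dtype=int)

    troughs = np.asarray(
        [p0 + int(np.argmin(x[p0 : p1 + 1])) for p0, p1 in zip(peaks[:-1], peaks[1:])],
        dtype=int,
    )
    return peaks, troughs


def segment_pulses(
    x: np.ndarray,
    fs: float,
    mask: ArtifactMask | None = None,
    locate: bool = True,
) -> list:
    """Cut the filtered signal into trough-delimited pulses.

    Pulses overlapping any artifact-masked sample are dropped.  With
    ``locate=True`` (default) each pulse also gets its derivative fiducials
    and the e2-based systolic-peak refinement.
    """
    x = np.asarray(x, dtype=float)
    _, troughs = detect_beats(x, fs)
    pulses = []
    for lo, hi in zip(troughs[:-1], troughs[1:]):
        if mask is not None and mask.mask[lo : hi + 1].any():
            continue
        win = x[lo : hi + 1]
        if len(win) < 4:
            continue
        sp = int(np.argmax(win))
        pulse = PulseWave(samples=win, fs=fs, start=int(lo), sp=sp if 0 < sp < len(win) - 1 else None)
        if locate and pulse.valid:
            locate_derivative_fiducials(pulse)
            refine_systolic_peak(pulse)
        pulses.append(pulse)
    return pulses


def _first_local_max(y: np.ndarray, lo: int, hi: int) -> int | None:
    """Earliest interior local maximum of ``y`` on (lo, hi), plateau -> first index."""
    for i in range(lo + 1, hi):
        if y[i] >= y[i - 1] and y[i] >= y[i + 1] and (y[i] > y[i - 1] or y[i] > y[i + 1]):
            return i
    return None


def _first_local_min(y: np.ndarray, lo: int, hi: int) -> int | None:
    return _first_local_max(-np.asarray(y), lo, hi)


def locate_derivative_fiducials(pulse: PulseWave) -> PulseWave:
    """Fill a1/b1 (first derivative) and a2/b2/e2 (second derivative).

    a1 is the velocity argmax on (IT, SP); b1 the first velocity minimum
    after a1; a2 the first acceleration local maximum after IT; b2 the
    deepest acceleration trough in (a2, FT); e2 the first acceleration local
    maximum after b2.  Landmarks that cannot be found stay ``None``.
    """
    if not pulse.valid:
        return pulse
    pulse.ensure_derivatives()
    d1, d2 = pulse.d1, pulse.d2
    it, sp, ft = pulse.it, pulse.sp, pulse.ft

    if sp - it >= 2:
        pulse.a1 = it + 1 + int(np.argmax(d1[it + 1 : sp]))
    if pulse.a1 is not None:
        pulse.b1 = _first_local_min(d1, pulse.a1, ft)

    pulse.a2 = _first_local_max(d2, it, ft)
    if pulse.a2 is not None and ft - pulse.a2 >= 2:
        pulse.b2 = pulse.a2 + 1 + int(np.argmin(d2[pulse.a2 + 1 : ft]))
    if pulse.b2 is not None:
        pulse.e2 = _first_local_max(d2, pulse.b2, ft)
        if pulse.e2 is not None:
            # diastolic peak, when present, is the waveform local max after e2
            pulse.dp = _first_local_max(pulse.samples, pulse.e2, ft)
    return pulse


def refine_systolic_peak(pulse: PulseWave) -> PulseWave:
    """Redefine SP as max(IT..e2) when the detected peak sits at/after e2.

    e2 marks the notch between the systolic and diastolic peaks; a "systolic"
    peak at or beyond it means the diastolic peak was picked.  If e2 is
    undetectable the pulse keeps its original SP.  Idempotent.
    """
    if not pulse.valid or pulse.e2 is None:
        return pulse
    if pulse.sp >= pulse.e2:
        new_sp = pulse.it + int(np.argmax(pulse.samples[pulse.it : pulse.e2 + 1]))
        if pulse.it < new_sp:
            pulse.sp = new_sp
            # velocity landmarks depend on SP; redo them on the refined window
            pulse.a1 = pulse.b1 = None
            if pulse.sp - pulse.it >= 2:
                pulse.a1 = pulse.it + 1 + int(np.argmax(pulse.d1[pulse.it + 1 : pulse.sp]))
            if pulse.a1 is not None:
                pulse.b1 = _first_local_min(pulse.d1, pulse.a1, pulse.ft)
    return pulse


def pulses_to_ibi_series(pulses: list) -> IBISeries:
    """Trough-to-trough IBI series from consecutive valid pulses.

    Non-consecutive pulses (gaps from dropped/masked beats) still produce an
    interval, but its duration then spans the gap and is left to the IBI
    validity rules downstream.
    """
    starts = np.asarray([p.start for p in pulses if p.valid], dtype=int)
    if len(starts) == 0:
        return IBISeries(np.empty(0), np.empty(0), np.empty(0, dtype=bool))
    fs = pulses[0].fs
    beat_times = np.sort(starts) / fs
    return IBISeries.from_beat_times(beat_times)
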