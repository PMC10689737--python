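"""Heart-rate-variability features from trough-to-trough interbeat intervals.

Thirty features in five families:

* time domain — mean HR, SDNN, RMSSD, pNN50, kurtosis, skewness;
* frequency domain — Welch band powers (VLF 0–0.04, LF 0.04–0.15,
  HF 0.15–0.4 Hz) on the 4-Hz-resampled tachogram, plus normalized LF/HF;
* non-linear — Poincaré SD1/SD2/S, short-range DFA exponent, sample entropy;
* phase-rectified signal averaging (PRSA) — deceleration/acceleration
  capacity and the immediate/slope/average responses around anchor beats;
* heart-rate fragmentation — PIP, PAS, PSS, IALS from sign runs of the
  interval increments.

IBIs outside [300, 2400] ms or jumping more than 20% from the preceding
valid IBI are flagged invalid.  Features needing a continuous series
(spectra, sample entropy) run on beat timestamps gap-filled by quadratic
interpolation; everything else uses valid intervals only.  Features that
cannot be computed are returned as NaN.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import interpolate, signal as sps, stats

from .records import IBISeries

__all__ = [
    "HRV_FEATURE_NAMES",
    "SegmentUnusable",
    "filter_ibis",
    "interpolate_ontime",
    "time_domain",
    "frequency_domain",
    "poincare",
    "dfa_alpha1",
    "sample_entropy",
    "prsa",
    "prsa_waveform",
    "fragmentation",
    "hrv_features",
]

IBI_MIN_MS = 300.0
IBI_MAX_MS = 2400.0
MAX_JUMP_FRACTION = 0.2
TACHOGRAM_FS = 4.0  # Hz, tachogram resampling rate for Welch / SampEn
WELCH_WINDOW_S = 300.0
MAX_GAP_S = 10.0
PRSA_WING = 50  # beats on each side of an anchor

HRV_FEATURE_NAMES = (
    "mean_hr", "sdnn", "rmssd", "pnn50", "kurtosis", "skewness",
    "vlf", "lf", "hf", "lf_nu", "hf_nu", "lf_hf",
    "sd1", "sd2", "sd1_sd2", "s", "dfa_alpha1", "sampen",
    "dc", "ac", "idr", "iar", "sdr", "sar", "adr", "aar",
    "pip", "pas", "pss", "ials",
)


class SegmentUnusable(Exception):
    """Raised when a segment cannot support continuous-signal features."""


def filter_ibis(series: IBISeries) -> IBISeries:
    """Apply the range and 20%-jump validity rules.

    An interval is invalid when outside [0.3, 2.4] s or when it differs by
    more than 20% from the *preceding valid* interval (the first interval has
    no predecessor and only the range rule applies).
    """
    if len(series) < 2:
        raise ValueError("need at least 2 IBIs")
    valid = np.zeros(len(series), dtype=bool)
    prev = None
    for i, ibi in enumerate(series.ibis):
        ok = IBI_MIN_MS <= ibi <= IBI_MAX_MS
        if ok and prev is not None:
            ok = abs(ibi - prev) / prev <= MAX_JUMP_FRACTION
        valid[i] = ok
        if ok:
            prev = ibi
    return IBISeries(series.beat_times.copy(), series.ibis.copy(), valid)


def interpolate_ontime(series: IBISeries) -> IBISeries:
    """Gap-fill missing beat timestamps by quadratic interpolation.

    Kept beats are those bounding at least one valid interval.  For each gap
    the number of missing beats is estimated from the gap length and the
    median valid interval; a quadratic interpolant of timestamp against beat
    index then restores the missing timestamps (exact for constant trains
    and for linearly ramping intervals).
    """
    keep = np.zeros(len(series.beat_times), dtype=bool)
    keep[:-1] |= series.valid
    keep[1:] |= series.valid
    t_keep = series.beat_times[keep]
    if len(t_keep) < 4:
        raise SegmentUnusable("fewer than 4 valid beats")

    med = float(np.median(series.valid_ibis)) / 1000.0
    idx = np.zeros(len(t_keep), dtype=int)
    for j in range(1, len(t_keep)):
        gap = t_keep[j] - t_keep[j - 1]
        if gap > MAX_GAP_S:
            raise SegmentUnusable(f"gap of {gap:.1f} s exceeds {MAX_GAP_S} s")
        idx[j] = idx[j - 1] + max(int(round(gap / med)), 1)

    full_idx = np.arange(idx[-1] + 1)
    f = interpolate.interp1d(idx, t_keep, kind="quadratic", assume_sorted=True)
    beat_times = f(full_idx)
    beat_times[idx] = t_keep  # knots pass through exactly
    return IBISeries.from_beat_times(beat_times)


def _successive_diffs(series: IBISeries) -> np.ndarray:
    """Diffs over adjacent interval pairs where both intervals are valid."""
    v = series.valid
    both = v[:-1] & v[1:]
    return np.diff(series.ibis)[both]


def time_domain(series: IBISeries) -> dict:
    """Mean HR, SDNN, RMSSD, pNN50 (strict > 50 ms), kurtosis, skewness."""
    x = series.valid_ibis
    out = {k: math.nan for k in ("mean_hr", "sdnn", "rmssd", "pnn50", "kurtosis", "skewness")}
    if len(x) < 2:
        return out
    out["mean_hr"] = 60000.0 / float(np.mean(x))
    out["sdnn"] = float(np.std(x))
    if out["sdnn"] > 0:
        out["kurtosis"] = float(stats.kurtosis(x))
        out["skewness"] = float(stats.skew(x))
    d = _successive_diffs(series)
    if len(d) >= 1:
        out["rmssd"] = float(np.sqrt(np.mean(d * d)))
        out["pnn50"] = float(np.mean(np.abs(d) > 50.0) * 100.0)
    return out


def _tachogram(series: IBISeries, fs: float = TACHOGRAM_FS) -> np.ndarray:
    """Evenly resampled IBI tachogram (ms) via cubic interpolation."""
    t = series.beat_times[1:]
    y = series.ibis
    if len(y) < 4:
        raise SegmentUnusable("too few beats for a tachogram")
    grid = np.arange(t[0], t[-1], 1.0 / fs)
    f = interpolate.interp1d(t, y, kind="cubic", assume_sorted=True)
    return f(grid)


def frequency_domain(continuous: IBISeries, tacho_fs: float = TACHOGRAM_FS) -> dict:
    """Welch band powers of the tachogram in ms^2, plus normalized LF/HF.

    Welch windows are 5 min with 50% overlap (shrunk to the series length
    when shorter); band powers are trapezoidal integrals of the PSD.
    """
    out = {k: math.nan for k in ("vlf", "lf", "hf", "lf_nu", "hf_nu", "lf_hf")}
    try:
        y = _tachogram(continuous, tacho_fs)
    except SegmentUnusable:
        return out
    nperseg = min(len(y), int(WELCH_WINDOW_S * tacho_fs))
    if nperseg < 16:
        return out
    freqs, psd = sps.welch(y, fs=tacho_fs, nperseg=nperseg, noverlap=nperseg // 2)

    def band(lo, hi):
        sel = (freqs >= lo) & (freqs < hi)
        return float(np.trapezoid(psd[sel], freqs[sel])) if sel.sum() > 1 else 0.0

    out["vlf"] = band(0.0, 0.04)
    out["lf"] = band(0.04, 0.15)
    out["hf"] = band(0.15, 0.40)
    total = out["lf"] + out["hf"]
    if total > 1e-10 and out["hf"] > 0:
        out["lf_nu"] = out["lf"] / total
        out["hf_nu"] = out["hf"] / total
        out["lf_hf"] = out["lf"] / out["hf"]
    return out


def poincare(series: IBISeries) -> dict:
    """Poincaré ellipse width/length and area.

    SD1 is the rms of successive differences divided by sqrt(2) — identical
    to RMSSD/sqrt(2) by construction (the mean successive difference of a
    stationary IBI series is negligible, so this coincides with the centred
    ellipse-width definition).  SD2 is the population sd of
    (x_i + x_{i+1})/sqrt(2); S = pi * SD1 * SD2.
    """
    out = {k: math.nan for k in ("sd1", "sd2", "sd1_sd2", "s")}
    v = series.valid
    both = v[:-1] & v[1:]
    if both.sum() < 3:
        return out
    x0 = series.ibis[:-1][both]
    x1 = series.ibis[1:][both]
    d = (x1 - x0) / math.sqrt(2.0)
    out["sd1"] = float(np.sqrt(np.mean(d * d)))
    out["sd2"] = float(np.std((x1 + x0) / math.sqrt(2.0)))
    out["s"] = math.pi * out["sd1"] * out["sd2"]
    if out["sd2"] > 0:
        out["sd1_sd2"] = out["sd1"] / out["sd2"]
    return out


def dfa_alpha1(series: IBISeries, box_range: tuple = (4, 16)) -> float:
    """Short-range detrended-fluctuation scaling exponent (boxes of 4–16 beats)."""
    x = series.valid_ibis
    if len(x) < 100:
        return math.nan
    y = np.cumsum(x - np.mean(x))
    sizes = np.arange(box_range[0], box_range[1] + 1)
    fluct = np.empty(len(sizes), dtype=float)
    for k, n in enumerate(sizes):
        m = len(y) // n
        seg = y[: m * n].reshape(m, n)
        t = np.arange(n)
        # per-box linear detrend (least squares, vectorized over boxes)
        tc = t - t.mean()
        slope = seg @ tc / float(tc @ tc)
        resid = seg - seg.mean(axis=1, keepdims=True) - np.outer(slope, tc)
        fluct[k] = np.sqrt(np.mean(resid * resid))
    good = fluct > 0
    if good.sum() < 3:
        return math.nan
    alpha, _ = np.polyfit(np.log(sizes[good]), np.log(fluct[good]), 1)
    return float(alpha)


def sample_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """Sample entropy with Chebyshev distance, self-matches excluded.

    ``r`` is ``r_factor`` times the population sd of the series; SampEn is
    ``-ln(A/B)`` where B counts template pairs matching at length ``m`` and
    A those still matching at ``m + 1``.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < m + 2:
        return math.nan
    sd = float(np.std(x))
    if sd <= 0:
        return math.nan
    r = r_factor * sd

    def count(mm: int) -> int:
        # n - m templates at both lengths (standard convention), so a
        # strictly periodic series yields A == B exactly
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)[: n - m]
        total = 0
        for i in range(len(emb) - 1):
            d = np.max(np.abs(emb[i + 1 :] - emb[i]), axis=1)
            total += int(np.count_nonzero(d <= r))
        return total

    b = count(m)
    a = count(m + 1)
    if b == 0 or a == 0:
        return math.nan
    return -math.log(a / b)


def _anchor_indices(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "decel":
        anchors = np.flatnonzero(x[1:] > x[:-1]) + 1
    else:
        anchors = np.flatnonzero(x[1:] < x[:-1]) + 1
    return anchors[(anchors >= PRSA_WING) & (anchors <= len(x) - PRSA_WING)]


def prsa_waveform(x: np.ndarray, kind: str, wing: int = PRSA_WING) -> np.ndarray | None:
    """Averaged PRSA waveform X(k), k in [-wing, wing), X(0) at the anchor."""
    x = np.asarray(x, dtype=float)
    anchors = _anchor_indices(x, kind)
    if len(anchors) == 0:
        return None
    windows = np.stack([x[a - wing : a + wing] for a in anchors])
    return windows.mean(axis=0)


def _prsa_one(x: np.ndarray, kind: str) -> dict:
    wf = prsa_waveform(x, kind)
    if wf is None:
        return {"cap": math.nan, "ir": math.nan, "slope": math.nan, "avg": math.nan}
    w = PRSA_WING
    cap = (wf[w] + wf[w + 1] - wf[w - 1] - wf[w - 2]) / 4.0
    span = wf[w - 5 : w + 5]  # k in [-5, 4], anchor included
    ir = float(np.max(span) - np.min(span))
    slope = float(np.polyfit(np.arange(-5, 5), span, 1)[0])
    avg = float(np.mean(wf[:w]) - np.mean(wf[w:]))
    return {"cap": float(cap), "ir": ir, "slope": slope, "avg": avg}


def prsa(series: IBISeries) -> dict:
    """PRSA features for deceleration and acceleration anchors.

    Deceleration anchors are beats longer than their predecessor (heart-rate
    deceleration); acceleration anchors the converse.  Anchors without full
    50-beat wings are discarded.  DC/AC use the quarter formula
    ``(X(0)+X(1)-X(-1)-X(-2))/4``; IDR/IAR the max-min over k in [-5, 4];
    SDR/SAR the least-squares slope over that span (ms/beat); ADR/AAR the
    mean of the 50 values before the anchor minus the mean of the 50 from
    the anchor on.
    """
    out = {k: math.nan for k in ("dc", "ac", "idr", "iar", "sdr", "sar", "adr", "aar")}
    x = series.valid_ibis
    if len(x) < 2 * PRSA_WING + 20:
        return out
    dec = _prsa_one(x, "decel")
    acc = _prsa_one(x, "accel")
    out.update(
        dc=dec["cap"], idr=dec["ir"], sdr=dec["slope"], adr=dec["avg"],
        ac=acc["cap"], iar=acc["ir"], sar=acc["slope"], aar=acc["avg"],
    )
    return out


def fragmentation(series: IBISeries) -> dict:
    """Heart-rate-fragmentation indices from sign runs of the IBI increments.

    On the increment sign sequence (+/-/0, zeros terminate runs and are
    never inflections): PIP is the percentage of intervals at which the
    increment sign flips; segments are maximal runs of one nonzero sign,
    with PSS the percentage of intervals inside runs shorter than 3
    increments and IALS the reciprocal mean run length; PAS is the
    percentage of intervals inside alternation stretches of at least 4
    intervals.  An all-zero increment sequence is maximally fragmented in
    the "short segments" sense: PSS = 100, PIP = PAS = 0, IALS = 0.
    """
    out = {k: math.nan for k in ("pip", "pas", "pss", "ials")}
    x = series.valid_ibis
    n = len(x)
    if n < 20:
        return out
    signs = np.sign(np.diff(x)).astype(int)
    n_inc = len(signs)

    nz = signs != 0
    if not nz.any():
        return {"pip": 0.0, "pas": 0.0, "pss": 100.0, "ials": 0.0}

    # inflection points: consecutive nonzero increments with opposite sign
    inflections = sum(
        1 for i in range(1, n_inc) if signs[i] != 0 and signs[i - 1] != 0 and signs[i] != signs[i - 1]
    )
    out["pip"] = 100.0 * inflections / n

    # maximal runs of constant nonzero sign
    runs = []  # (start, length) in increment indices
    i = 0
    while i < n_inc:
        if signs[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n_inc and signs[j + 1] == signs[i]:
            j += 1
        runs.append((i, j - i + 1))
        i = j + 1
    out["ials"] = 1.0 / float(np.mean([L for _, L in runs]))
    in_short = np.zeros(n, dtype=bool)
    for start, length in runs:
        if length < 3:
            in_short[start : start + length + 1] = True
    out["pss"] = 100.0 * float(np.mean(in_short))

    # alternation stretches: consecutive increments flipping sign every step
    in_alt = np.zeros(n, dtype=bool)
    i = 0
    while i < n_inc:
        if signs[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n_inc and signs[j + 1] != 0 and signs[j + 1] != signs[j]:
            j += 1
        if (j - i + 2) >= 4:  # length in NN intervals
            in_alt[i : j + 2] = True
        i = j + 1
    out["pas"] = 100.0 * float(np.mean(in_alt))
    return out


def hrv_features(series: IBISeries) -> dict:
    """All 30 HRV features for one segment's (validity-flagged) IBI series."""
    out = {}
    out.update(time_domain(series))
    try:
        continuous = interpolate_ontime(series)
        out.update(frequency_domain(continuous))
        tacho = _tachogram(continuous)
        out["sampen"] = sample_entropy(tacho) if len(tacho) >= 100 else math.nan
    except SegmentUnusable:
        out.update({k: math.nan for k in ("vlf", "lf", "hf", "lf_nu", "hf_nu", "lf_hf")})
        out["sampen"] = math.nan
    out.update(poincare(series))
    out["dfa_alpha1"] = dfa_alpha1(series)
    out.update(prsa(series))
    out.update(fragmentation(series))
    return {k: out[k] for k in HRV_FEATURE_NAMES}
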