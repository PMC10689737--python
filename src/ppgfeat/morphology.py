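"""Per-pulse morphology features and their per-segment aggregation.

Thirty-seven features per fully segmented pulse (IT, SP and FT all present),
grouped as amplitudes, time differences, areas, velocity/acceleration,
width ratios, phase ratios, slopes and angles.  Times come from fiducial
index differences over the sampling rate; areas are trapezoidal integrals
above the straight baseline joining IT and FT (so residual baseline wander
does not leak into area features); width levels are measured relative to the
pulse amplitude above the IT level with sub-sample linear interpolation of
the crossings; angles are computed on the amplitude-normalized pulse
(amplitude scaled to 1) so they are unit-independent.

Per segment, each feature is the arithmetic mean over the segment's valid
pulses, ignoring per-pulse missing values; a segment needs at least 10 valid
pulses to report morphology at all.
"""

from __future__ import annotations

import math

import numpy as np

from .fiducials import PulseWave

__all__ = [
    "MORPH_FEATURE_NAMES",
    "MIN_PULSES_PER_SEGMENT",
    "pulse_morphology",
    "aggregate_segment_morphology",
]

MORPH_FEATURE_NAMES = (
    "pwa", "b2_amplitude",
    "pwd", "spd", "dpd", "t_a1", "t_a1b1", "t_a2b2", "t_b2e2", "t_s",
    "auc_total", "auc1", "auc2",
    "mean_v", "idr_v", "mean_acc", "msv", "sfv", "edv",
    "dw10_sw10", "dw25_sw25", "dw50_sw50", "dw60_sw60",
    "t_s_pwd", "t_a1_pwd", "t_a1b1_pwd", "t_a2b2_pwd", "t_b2e2_pwd",
    "b2_a2", "e2_a2", "spd_pwd", "sp_spd", "pulsatility_index",
    "slope_it_sp", "slope_sp_ft", "alpha", "gamma",
)

MIN_PULSES_PER_SEGMENT = 10

WIDTH_LEVELS = {"10": 0.10, "25": 0.25, "50": 0.50, "60": 0.60}


def _rising_crossing(y: np.ndarray, it: int, sp: int, level: float) -> float | None:
    """Sub-sample index of the first upward crossing of ``level`` on [it, sp]."""
    for i in range(it, sp):
        if y[i] <= level <= y[i + 1] and y[i + 1] > y[i]:
            return i + (level - y[i]) / (y[i + 1] - y[i])
    return None


def _falling_crossing(y: np.ndarray, sp: int, ft: int, level: float) -> float | None:
    """Sub-sample index of the *last* downward crossing of ``level`` on [sp, ft].

    With a diastolic peak the falling edge may cross a low level several
    times; the final descent towards FT is the diastolic width boundary.
    """
    for i in range(ft - 1, sp - 1, -1):
        if y[i] >= level >= y[i + 1] and y[i] > y[i + 1]:
            return i + (y[i] - level) / (y[i] - y[i + 1])
    return None


def _chord(y: np.ndarray, it: int, ft: int) -> np.ndarray:
    return np.interp(np.arange(it, ft + 1), [it, ft], [y[it], y[ft]])


def pulse_morphology(pulse: PulseWave) -> dict:
    """All 37 morphology features for one valid pulse.

    Features depending on an undetected derivative landmark come back NaN;
    the rest are computed regardless.
    """
    if not pulse.valid:
        raise ValueError("pulse must have IT, SP and FT")
    pulse.ensure_derivatives()
    y, d1, d2, fs = pulse.samples, pulse.d1, pulse.d2, pulse.fs
    it, sp, ft = pulse.it, pulse.sp, pulse.ft
    out = {k: math.nan for k in MORPH_FEATURE_NAMES}

    pwa = float(y[sp] - y[it])
    pwd = (ft - it) / fs
    spd = (sp - it) / fs
    dpd = (ft - sp) / fs
    out.update(pwa=pwa, pwd=pwd, spd=spd, dpd=dpd, spd_pwd=spd / pwd)
    out["sp_spd"] = float(y[sp]) / spd if spd > 0 else math.nan

    # areas above the IT-FT chord
    base = _chord(y, it, ft)
    rel = y[it : ft + 1] - base
    out["auc_total"] = float(np.trapezoid(rel, dx=1.0 / fs))
    out["auc1"] = float(np.trapezoid(rel[: sp - it + 1], dx=1.0 / fs))
    out["auc2"] = float(np.trapezoid(rel[sp - it :], dx=1.0 / fs))

    # velocity / acceleration
    seg_d1 = d1[it : ft + 1]
    out["mean_v"] = float(np.mean(seg_d1))
    p90, p10 = np.percentile(seg_d1, [90.0, 10.0])
    out["idr_v"] = float(p90 - p10)
    out["mean_acc"] = float(np.mean(d2[it : ft + 1]))
    out["sfv"] = float(d1[it])
    out["edv"] = float(d1[ft])

    # width ratios (diastolic over systolic, per the feature symbols)
    for tag, frac in WIDTH_LEVELS.items():
        level = y[it] + frac * pwa
        r = _rising_crossing(y, it, sp, level)
        f = _falling_crossing(y, sp, ft, level)
        if r is not None and f is not None and sp - r > 0 and f - sp > 0:
            out[f"dw{tag}_sw{tag}"] = (f - sp) / (sp - r)

    # slopes and angles (angles on the amplitude-normalized pulse)
    if pwa > 0:
        out["slope_it_sp"] = pwa / spd if spd > 0 else math.nan
        out["slope_sp_ft"] = float(y[ft] - y[sp]) / dpd if dpd > 0 else math.nan
        if spd > 0:
            out["alpha"] = math.degrees(math.atan(1.0 / spd))
        if dpd > 0:
            out["gamma"] = math.degrees(math.atan((y[ft] - y[sp]) / pwa / dpd))

    # first-derivative landmarks
    if pulse.a1 is not None:
        out["t_a1"] = (pulse.a1 - it) / fs
        out["t_a1_pwd"] = out["t_a1"] / pwd
        out["msv"] = float(d1[pulse.a1])
        out["t_s"] = (sp - pulse.a1) / fs
        out["t_s_pwd"] = out["t_s"] / pwd
        if out["mean_v"] != 0:
            out["pulsatility_index"] = (out["msv"] - out["edv"]) / out["mean_v"]
        if pulse.b1 is not None:
            out["t_a1b1"] = (pulse.b1 - pulse.a1) / fs
            out["t_a1b1_pwd"] = out["t_a1b1"] / pwd

    # second-derivative landmarks
    if pulse.a2 is not None and pulse.b2 is not None:
        a2_amp = float(d2[pulse.a2])
        out["b2_amplitude"] = abs(float(d2[pulse.b2]))
        out["t_a2b2"] = (pulse.b2 - pulse.a2) / fs
        out["t_a2b2_pwd"] = out["t_a2b2"] / pwd
        if a2_amp != 0:
            out["b2_a2"] = out["b2_amplitude"] / a2_amp
        if pulse.e2 is not None:
            out["t_b2e2"] = (pulse.e2 - pulse.b2) / fs
            out["t_b2e2_pwd"] = out["t_b2e2"] / pwd
            if a2_amp != 0:
                out["e2_a2"] = float(d2[pulse.e2]) / a2_amp
    return out


def aggregate_segment_morphology(pulse_features: list) -> tuple:
    """Average per-pulse features over a segment, ignoring missing values.

    Returns ``(features, n_contributing)`` where ``n_contributing`` maps
    each feature to the number of pulses that contributed.  With fewer than
    :data:`MIN_PULSES_PER_SEGMENT` pulses every feature is missing.
    """
    out = {k: math.nan for k in MORPH_FEATURE_NAMES}
    counts = {k: 0 for k in MORPH_FEATURE_NAMES}
    if len(pulse_features) < MIN_PULSES_PER_SEGMENT:
        return out, counts
    for name in MORPH_FEATURE_NAMES:
        vals = np.asarray([f[name] for f in pulse_features], dtype=float)
        good = np.isfinite(vals)
        counts[name] = int(good.sum())
        if counts[name] > 0:
            out[name] = float(np.mean(vals[good]))
    return out, counts
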