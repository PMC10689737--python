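"""Synthetic two-cohort nighttime PPG generator.

Real wristband recordings behind this kind of analysis are rarely shareable,
so every downstream stage is exercised against records built here with known
ground truth: an interbeat-interval (IBI) series with controllable mean heart
rate, RMSSD and LF/HF balance; a two-Gaussian pulse template whose waveform,
velocity and acceleration landmarks are analytically known; additive baseline
wander, white noise and motion-artifact bursts; and a Markov-chain hypnogram
over {Wake, N1/N2, N3, REM}.

The "pregnant-like" cohort B differs from the "non-pregnant-like" cohort A in
the directions reported for pregnancy: higher mean heart rate, shorter
systolic upstroke fraction, reduced short-term variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .records import EPOCH_S, STAGES, GroundTruth, IBISeries, PPGRecord, SubjectMeta

__all__ = [
    "CohortParams",
    "GaussianPulseTemplate",
    "cohort_a_params",
    "cohort_b_params",
    "second_night_params",
    "generate_ibi_series",
    "synthesize_pulse_template",
    "synthesize_ppg",
    "generate_hypnogram",
    "generate_subject",
    "generate_cohort",
]

#: Centre frequency (Hz) of the low-frequency (baroreflex-band) IBI modulation.
LF_FREQ = 0.095

#: White-jitter amplitude relative to the high-frequency sinusoid amplitude.
JITTER_FRAC = 0.3


@dataclass(frozen=True)
class CohortParams:
    """Generator settings for one cohort.

    Rates are per subject-night; ``hr_sd_between_subjects`` spreads subject
    mean heart rates around ``mean_hr``.  ``spd_fraction`` is the fraction of
    the pulse period taken by the systolic upstroke (foot to systolic peak).
    """

    n_subjects: int = 20
    group_label: str = "A"
    mean_hr: float = 60.0  # bpm
    hr_sd_between_subjects: float = 4.0  # bpm
    rmssd_target: float = 45.0  # ms
    lf_hf_ratio_target: float = 0.8
    resp_rate: float = 0.25  # Hz
    spd_fraction: float = 0.30
    diastolic_peak_relative_amplitude: float = 0.35
    diastolic_peak_delay: float = 0.62  # fraction of pulse period
    pulse_amplitude: float = 1.0
    noise_sd: float = 0.03
    artifact_rate: float = 4.0  # events / hour
    artifact_duration: float = 10.0  # s
    recording_hours: float = 8.0
    fs: float = 32.0
    age_range: tuple = (21.0, 28.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_hr <= 0:
            raise ValueError("mean_hr must be positive")
        if not 0.0 < self.spd_fraction < 1.0:
            raise ValueError("spd_fraction must lie in (0, 1)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.recording_hours <= 0 or self.artifact_duration <= 0:
            raise ValueError("durations must be positive")


def cohort_a_params(**overrides) -> CohortParams:
    """Defaults for the non-pregnant-like reference cohort."""
    return replace(CohortParams(group_label="A"), **overrides)


def cohort_b_params(**overrides) -> CohortParams:
    """Pregnant-like cohort: +12 bpm, -20% systolic fraction, -40% RMSSD.

    These shifts mirror the direction and rough size of the largest group
    contrasts the pipeline is meant to detect (mean HR up, systolic phase
    duration down, short-term HRV down), with the sympathovagal balance
    (LF/HF) nudged upward.
    """
    base = CohortParams(
        group_label="B",
        mean_hr=72.0,
        spd_fraction=0.24,
        rmssd_target=27.0,
        lf_hf_ratio_target=1.5,
        age_range=(28.0, 33.0),
    )
    return replace(base, **overrides)


def second_night_params(params: CohortParams) -> CohortParams:
    """Default parameter shift for a follow-up recording night.

    Emulates progressing gestation in the pregnant-like cohort: mean heart
    rate a little higher, short-term variability and pulse amplitude a
    little lower, systolic upstroke fraction unchanged.
    """
    return replace(
        params,
        mean_hr=params.mean_hr + 3.0,
        rmssd_target=params.rmssd_target * 0.85,
        pulse_amplitude=params.pulse_amplitude * 0.9,
    )


def _rmssd(x: np.ndarray) -> float:
    d = np.diff(x)
    return float(np.sqrt(np.mean(d * d))) if len(d) else 0.0


def generate_ibi_series(
    params: CohortParams,
    duration: float,
    rng: np.random.Generator,
    mean_hr: float | None = None,
) -> IBISeries:
    """Generate an IBI series with controlled mean, RMSSD and LF/HF balance.

    The series is ``T0 + m(t)`` where ``T0 = 60000 / mean_hr`` ms and the
    zero-mean modulation ``m`` is the sum of a low-frequency sinusoid (at
    :data:`LF_FREQ`), a high-frequency sinusoid at the respiratory rate, and
    white jitter.  The sinusoid amplitude ratio is set from
    ``lf_hf_ratio_target`` and the whole modulation is rescaled so the
    realised RMSSD equals ``rmssd_target``.  Modulation is evaluated on the
    nominal (unmodulated) beat grid, which keeps the rescaling exact.

    Parameters
    ----------
    duration : float
        Requested length of the series in seconds (> 60).
    mean_hr : float, optional
        Per-subject override of ``params.mean_hr``.
    """
    hr = params.mean_hr if mean_hr is None else mean_hr
    if hr <= 0:
        raise ValueError("mean_hr must be positive")
    if duration <= 60:
        raise ValueError("duration must exceed 60 s")

    t0_ms = 60000.0 / hr
    n_beats = int(math.ceil(duration * 1000.0 / t0_ms)) + 2
    t_nominal = np.arange(n_beats) * (t0_ms / 1000.0)

    phase_lf, phase_hf = rng.uniform(0, 2 * np.pi, size=2)
    a_lf = math.sqrt(max(params.lf_hf_ratio_target, 0.0))
    m = (
        a_lf * np.sin(2 * np.pi * LF_FREQ * t_nominal + phase_lf)
        + np.sin(2 * np.pi * params.resp_rate * t_nominal + phase_hf)
        + JITTER_FRAC * rng.standard_normal(n_beats)
    )
    scale = _rmssd(m)
    if params.rmssd_target > 0 and scale > 0:
        m *= params.rmssd_target / scale
    else:
        m[:] = 0.0

    ibis = np.clip(t0_ms + m, 300.0, 2400.0)
    beat_times = np.concatenate([[0.0], np.cumsum(ibis) / 1000.0])
    # trim to the requested duration (keep the first beat past the end)
    keep = np.searchsorted(beat_times, duration, side="left")
    beat_times = beat_times[: min(keep + 1, len(beat_times))]
    return IBISeries.from_beat_times(beat_times)


@dataclass(frozen=True)
class GaussianPulseTemplate:
    """Two-Gaussian pulse template on the unit period with analytic derivatives.

    ``value`` is the sum of a systolic and a (possibly absent) diastolic
    Gaussian bell, minus the chord joining the raw endpoint values, clipped
    at zero so the template starts and ends exactly at its minimum (0).  The
    clip only touches the far tails; ``d1``/``d2`` are the analytic
    derivatives of the unclipped two-bell-minus-chord function and are exact
    wherever the template is positive (all mid-pulse landmarks).
    """

    spd_fraction: float
    diastolic_peak_relative_amplitude: float = 0.35
    diastolic_peak_delay: float = 0.62
    sigma_sys: float | None = None
    sigma_dia: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.spd_fraction < 1.0:
            raise ValueError("spd_fraction must lie in (0, 1)")
        if (
            self.diastolic_peak_relative_amplitude > 0
            and self.diastolic_peak_delay <= self.spd_fraction
        ):
            raise ValueError("diastolic component must follow the systolic peak")

    @property
    def _sig_s(self) -> float:
        return self.sigma_sys if self.sigma_sys is not None else self.spd_fraction / 3.0

    @property
    def _sig_d(self) -> float:
        if self.sigma_dia is not None:
            return self.sigma_dia
        return max((1.0 - self.diastolic_peak_delay) / 2.5, 1e-3)

    def _bells(self, x):
        x = np.asarray(x, dtype=float)
        zs = (x - self.spd_fraction) / self._sig_s
        zd = (x - self.diastolic_peak_delay) / self._sig_d
        gs = np.exp(-0.5 * zs * zs)
        gd = self.diastolic_peak_relative_amplitude * np.exp(-0.5 * zd * zd)
        return gs, gd, zs, zd

    def _chord(self):
        gs0, gd0, _, _ = self._bells(0.0)
        gs1, gd1, _, _ = self._bells(1.0)
        y0 = float(gs0 + gd0)
        y1 = float(gs1 + gd1)
        return y0, y1 - y0  # intercept, slope

    def value(self, x) -> np.ndarray:
        gs, gd, _, _ = self._bells(x)
        c0, c1 = self._chord()
        return np.maximum(gs + gd - (c0 + c1 * np.asarray(x, dtype=float)), 0.0)

    def d1(self, x) -> np.ndarray:
        gs, gd, zs, zd = self._bells(x)
        _, c1 = self._chord()
        return -zs / self._sig_s * gs - zd / self._sig_d * gd - c1

    def d2(self, x) -> np.ndarray:
        gs, gd, zs, zd = self._bells(x)
        return (zs * zs - 1.0) / self._sig_s**2 * gs + (zd * zd - 1.0) / self._sig_d**2 * gd

    def sample(self, n_samples: int) -> np.ndarray:
        if n_samples < 16:
            raise ValueError("n_samples must be at least 16")
        return self.value(np.arange(n_samples) / n_samples)


def synthesize_pulse_template(
    spd_fraction: float,
    diastolic_peak_relative_amplitude: float,
    diastolic_peak_delay: float,
    n_samples: int,
) -> np.ndarray:
    """Sample one pulse period of the two-Gaussian template (see class docs)."""
    tpl = GaussianPulseTemplate(
        spd_fraction, diastolic_peak_relative_amplitude, diastolic_peak_delay
    )
    return tpl.sample(n_samples)


def _poisson_artifact_windows(
    rng: np.random.Generator, duration: float, rate_per_hour: float, burst_s: float
) -> list:
    n = rng.poisson(rate_per_hour * duration / 3600.0) if rate_per_hour > 0 else 0
    windows = []
    for start in np.sort(rng.uniform(0.0, max(duration - burst_s, 0.0), size=n)):
        windows.append((float(start), float(start + burst_s)))
    return windows


def synthesize_ppg(
    ibis: IBISeries,
    template: GaussianPulseTemplate,
    fs: float,
    rng: np.random.Generator,
    pulse_amplitude: float = 1.0,
    noise_sd: float = 0.0,
    artifact_rate: float = 0.0,
    artifact_duration: float = 10.0,
    baseline_freq: float = 0.03,
) -> tuple:
    """Render an IBI series into a sampled PPG trace plus ground truth.

    Each beat's template is stretched to its IBI duration (phase-continuous
    evaluation of the analytic template, so a constant IBI train at an
    integer number of samples is exactly periodic).  Baseline wander is a
    sub-0.05 Hz sinusoid with amplitude ``4 * noise_sd`` — no noise, no
    wander.  Artifact bursts are high-amplitude uniform noise in windows
    drawn from a Poisson process, all of which are logged.
    """
    if fs not in (32.0, 32, 128.0, 128):
        raise ValueError("fs must be 32 or 128 Hz")
    if len(ibis) == 0:
        raise ValueError("empty IBI series")

    bt = ibis.beat_times
    duration = float(bt[-1])
    n = int(math.floor(duration * fs))
    t = np.arange(n) / fs

    idx = np.clip(np.searchsorted(bt, t, side="right") - 1, 0, len(bt) - 2)
    phase = (t - bt[idx]) / (bt[idx + 1] - bt[idx])
    samples = pulse_amplitude * template.value(phase)

    if noise_sd > 0:
        phase0 = rng.uniform(0, 2 * np.pi)
        samples = samples + 4.0 * noise_sd * np.sin(2 * np.pi * baseline_freq * t + phase0)
        samples = samples + rng.normal(0.0, noise_sd, size=n)

    windows = _poisson_artifact_windows(rng, duration, artifact_rate, artifact_duration)
    for start, stop in windows:
        lo, hi = int(start * fs), min(int(stop * fs), n)
        samples[lo:hi] += rng.uniform(
            -5.0 * pulse_amplitude, 5.0 * pulse_amplitude, size=max(hi - lo, 0)
        )

    gt = GroundTruth(
        ibi_times=bt[:-1].copy(),
        ibi_durations=ibis.ibis.copy(),
        artifact_windows=windows,
        hypnogram_epochs=[],
    )
    return samples, gt


#: Row-stochastic transition matrix over (Wake, N1/N2, N3, REM) per 30-s epoch.
#: Chosen so the stationary share orders N1/N2 > N3 > REM and stage runs long
#: enough for 5-min stage-pure windows to occur.
HYPNOGRAM_TRANSITIONS = np.array(
    [
        [0.60, 0.38, 0.01, 0.01],
        [0.02, 0.88, 0.06, 0.04],
        [0.01, 0.10, 0.88, 0.01],
        [0.02, 0.10, 0.00, 0.88],
    ]
)


def generate_hypnogram(
    duration_h: float,
    rng: np.random.Generator,
    transitions: np.ndarray = HYPNOGRAM_TRANSITIONS,
    initial_stage: str = "Wake",
) -> list:
    """Markov-chain hypnogram of 30-s epochs covering ``duration_h`` hours."""
    if duration_h <= 0:
        raise ValueError("duration_h must be positive")
    n_epochs = int(math.ceil(duration_h * 3600.0 / EPOCH_S))
    state = STAGES.index(initial_stage)
    out = []
    for _ in range(n_epochs):
        out.append(STAGES[state])
        state = rng.choice(len(STAGES), p=transitions[state])
    return out


def generate_subject(
    params: CohortParams,
    subject_id: str,
    rng: np.random.Generator,
    night: int = 1,
) -> tuple:
    """One full synthetic subject-night: (PPGRecord, GroundTruth)."""
    hr = float(rng.normal(params.mean_hr, params.hr_sd_between_subjects))
    hr = float(np.clip(hr, 40.0, 120.0))
    age = float(rng.uniform(*params.age_range))
    duration = params.recording_hours * 3600.0

    ibis = generate_ibi_series(params, duration, rng, mean_hr=hr)
    template = GaussianPulseTemplate(
        params.spd_fraction,
        params.diastolic_peak_relative_amplitude,
        params.diastolic_peak_delay,
    )
    samples, gt = synthesize_ppg(
        ibis,
        template,
        params.fs,
        rng,
        pulse_amplitude=params.pulse_amplitude,
        noise_sd=params.noise_sd,
        artifact_rate=params.artifact_rate,
        artifact_duration=params.artifact_duration,
    )
    hyp = generate_hypnogram(len(samples) / params.fs / 3600.0, rng)
    gt.hypnogram_epochs = hyp
    gt.age = age

    meta = SubjectMeta(subject_id=subject_id, group=params.group_label, age=age, night=night)
    record = PPGRecord(samples=samples, fs=params.fs, meta=meta, hypnogram=hyp)
    return record, gt


def generate_cohort(params: CohortParams, night: int = 1) -> list:
    """Generate ``params.n_subjects`` subject-nights, seeded from ``params.seed``.

    Each subject gets an independent child seed, so cohorts are reproducible
    and individual subjects can be regenerated in isolation.
    """
    seeds = np.random.SeedSequence(params.seed).spawn(params.n_subjects)
    out = []
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        sid = f"{params.group_label}{i:03d}"
        out.append(generate_subject(params, sid, rng, night=night))
    return out
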