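import numpy as np
import pytest

from ppgfeat.preprocess import bandpass_filter
from ppgfeat.records import IBISeries
from ppgfeat.synth import (
    GaussianPulseTemplate,
    cohort_a_params,
    generate_ibi_series,
    synthesize_ppg,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_template():
    return GaussianPulseTemplate(0.30, 0.35, 0.62)


@pytest.fixture(scope="session")
def noiseless_record():
    """10-min noiseless artifact-free record with its ground truth.

    Session-scoped: several modules check recovery against the same truth.
    """
    rng = np.random.default_rng(777)
    params = cohort_a_params(noise_sd=0.0, artifact_rate=0.0)
    ibis = generate_ibi_series(params, 600.0, rng)
    template = GaussianPulseTemplate(
        params.spd_fraction,
        params.diastolic_peak_relative_amplitude,
        params.diastolic_peak_delay,
    )
    samples, gt = synthesize_ppg(ibis, template, 32.0, rng)
    return samples, gt, bandpass_filter(samples, 32.0)


def make_ibi_series(ibis_ms, t0=0.0):
    """IBISeries from a list of interval durations in ms (kept exact)."""
    ibis_ms = np.asarray(ibis_ms, dtype=float)
    beat_times = t0 + np.concatenate([[0.0], np.cumsum(ibis_ms) / 1000.0])
    return IBISeries(beat_times, ibis_ms, np.ones(len(ibis_ms), dtype=bool))
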