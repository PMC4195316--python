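"""Shared fixtures: calibrated cells and one long baseline run reused widely."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mfr.signals import ContinuousSignal, antialiased_decimate, gen_bandlimited_gaussian
from mfr.neurons import (
    NeuronParams,
    calibrate_modulation_amplitude,
    calibrate_tonic_current,
    simulate,
)
from mfr.estimation import sampling_rate_filter

DT = 0.025  # ms
WARMUP_MS = 1000.0


@pytest.fixture(scope="session")
def lif_params():
    return NeuronParams.lif()


@pytest.fixture(scope="session")
def lif_calibration(lif_params):
    """(i0, a_i) for the baseline condition: carrier 40 spikes/s, a = 0.1."""
    i0 = calibrate_tonic_current(lif_params, 40.0, dt=DT)
    a_i = calibrate_modulation_amplitude(lif_params, i0, 0.1, 40.0, dt=DT)
    return i0, a_i


@pytest.fixture(scope="session")
def baseline_run(lif_params, lif_calibration):
    """One 121-s baseline LIF run shared by the spectral/reconstruction tests.

    Returns a dict with the full-rate input/train plus both signals on the
    1-ms analysis grid (warm-up removed, spike output anti-alias decimated).
    """
    i0, a_i = lif_calibration
    x = gen_bandlimited_gaussian(20.0, 121_000.0, DT, seed=11)
    train = simulate(lif_params, i0 + a_i * x.samples, DT)
    warm = int(WARMUP_MS / DT)
    y_full = sampling_rate_filter(train)
    ya = antialiased_decimate(ContinuousSignal(y_full.samples[warm:], DT), 1.0)
    xa = ContinuousSignal(x.samples[warm:][::40][: ya.n], 1.0, "normalized")
    return {
        "params": lif_params,
        "i0": i0,
        "a_i": a_i,
        "x": x,
        "train": train,
        "xa": xa,
        "ya": ya,
    }


@pytest.fixture(scope="session")
def whitenoise_run(lif_params, lif_calibration):
    """121-s LIF run under essentially white (480-Hz) noise drive, 1-ms grid."""
    i0, a_i = lif_calibration
    x = gen_bandlimited_gaussian(480.0, 121_000.0, DT, seed=64)
    train = simulate(lif_params, i0 + a_i * x.samples, DT)
    warm = int(WARMUP_MS / DT)
    y_full = sampling_rate_filter(train)
    ya = antialiased_decimate(ContinuousSignal(y_full.samples[warm:], DT), 1.0)
    xa = antialiased_decimate(ContinuousSignal(x.samples[warm:], DT), 1.0)
    return {"xa": xa, "ya": ya}
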