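"""Stimulus and noise waveform generation.

All experiments in this package are driven by continuous waveforms sampled on
a uniform grid: sinusoidal current modulations, band-limited Gaussian noise
(the signal to be encoded and later reconstructed), and Ornstein-Uhlenbeck
(OU) noise currents.  Gaussian signals follow the ``2*sigma = 1`` amplitude
convention: after generation they are rescaled so their sample standard
deviation is exactly 0.5.  A modulation amplitude ``A`` applied to such a
signal then spans ``+-A`` about the mean roughly 95 % of the time.

Generators are pure functions of their parameters and seed: the same call
returns byte-identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "ContinuousSignal",
    "StimulusSpec",
    "gen_sinusoid",
    "gen_bandlimited_gaussian",
    "gen_ou_noise",
    "invert_signal",
    "decimate_mean",
    "antialiased_decimate",
    "write_signal_csv",
    "read_signal_csv",
]

#: Target sample standard deviation of a "normalized" signal (2*sigma = 1).
NORMALIZED_STD = 0.5

_UNITS = ("pA", "spikes/s", "normalized", "dimensionless")


@dataclass
class ContinuousSignal:
    """A uniformly sampled real-valued waveform.

    Parameters
    ----------
    samples
        Sample values.
    dt
        Step size in milliseconds.
    units
        One of ``pA``, ``spikes/s``, ``normalized`` or ``dimensionless``.
    """

    samples: np.ndarray
    dt: float
    units: str = "dimensionless"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("a signal needs at least 2 samples on a 1-d grid")
        if self.units not in _UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {_UNITS}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Total covered time in ms (n * dt)."""
        return self.n * self.dt

    @property
    def fs_hz(self) -> float:
        """Sampling rate in Hz."""
        return 1000.0 / self.dt

    def times(self) -> np.ndarray:
        """Sample times in ms (grid starts at 0)."""
        return np.arange(self.n) * self.dt

    def std(self) -> float:
        return float(np.std(self.samples))


@dataclass
class StimulusSpec:
    """Declarative description of a stimulus waveform."""

    kind: str  # sinusoid | bandlimited_gaussian | ou_noise
    duration: float  # ms
    dt: float = 0.025  # ms
    f: float | None = None  # Hz, sinusoid
    cutoff: float | None = None  # Hz, band-limited noise
    tau_n: float | None = None  # ms, OU correlation time
    seed: int | None = None

    def realize(self) -> ContinuousSignal:
        if self.kind == "sinusoid":
            return gen_sinusoid(self.f, self.duration, self.dt)
        if self.kind == "bandlimited_gaussian":
            return gen_bandlimited_gaussian(self.cutoff, self.duration, self.dt, self.seed)
        if self.kind == "ou_noise":
            return gen_ou_noise(self.tau_n, self.duration, self.dt, self.seed)
        raise ValueError(f"unknown stimulus kind {self.kind!r}")


def _nyquist_hz(dt: float) -> float:
    return 500.0 / dt  # dt in ms


def _n_samples(duration: float, dt: float) -> int:
    n = int(round(duration / dt))
    if n < 2:
        raise ValueError(f"duration {duration} ms at dt {dt} ms yields < 2 samples")
    return n


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_sinusoid(f: float, duration: float, dt: float = 0.025) -> ContinuousSignal:
    """Unit-amplitude sinusoid ``sin(2*pi*f*t)`` sampled on the grid.

    The caller scales by the modulation amplitude and adds the tonic offset.
    """
    if f <= 0:
        raise ValueError(f"frequency must be positive, got {f} Hz")
    nyq = _nyquist_hz(dt)
    if f > nyq:
        raise ValueError(f"frequency {f} Hz exceeds grid Nyquist {nyq} Hz at dt={dt} ms")
    n = _n_samples(duration, dt)
    t_s = np.arange(n) * (dt / 1000.0)
    return ContinuousSignal(np.sin(2.0 * np.pi * f * t_s), dt, "dimensionless")


def gen_bandlimited_gaussian(
    cutoff: float, duration: float, dt: float = 0.025, seed=None
) -> ContinuousSignal:
    """Zero-mean Gaussian noise with a flat spectrum on (0, cutoff].

    Constructed in the frequency domain: independent complex-Gaussian Fourier
    coefficients up to the cutoff, exactly zero beyond (a brick-wall band
    limit, which a time-domain filter could only approximate).  Normalized to
    sample std 0.5 (the 2*sigma = 1 convention).
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff} Hz")
    nyq = _nyquist_hz(dt)
    if cutoff > nyq:
        raise ValueError(f"cutoff {cutoff} Hz exceeds grid Nyquist {nyq} Hz at dt={dt} ms")
    n = _n_samples(duration, dt)
    fund = 1000.0 / (n * dt)  # lowest nonzero frequency, Hz
    if cutoff < 2.0 * fund:
        raise ValueError(
            f"duration {duration} ms too short to resolve cutoff {cutoff} Hz "
            f"(needs at least 2 periods of the lowest analysis frequency)"
        )
    rng = _as_rng(seed)
    freqs = np.fft.rfftfreq(n, d=dt / 1000.0)
    band = (freqs > 0) & (freqs <= cutoff)
    coef = np.zeros(freqs.size, dtype=complex)
    m = int(band.sum())
    coef[band] = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = np.fft.irfft(coef, n)
    x *= NORMALIZED_STD / np.std(x)
    return ContinuousSignal(x, dt, "normalized")


def gen_ou_noise(tau_n: float, duration: float, dt: float = 0.025, seed=None) -> ContinuousSignal:
    """Stationary Ornstein-Uhlenbeck noise, zero mean, std 0.5.

    Uses the exact discretization ``x[k+1] = a*x[k] + sqrt(1-a^2)*xi`` with
    ``a = exp(-dt/tau_n)``, so the process statistics do not depend on the
    step size.  The recursion runs through :func:`scipy.signal.lfilter`.
    """
    if tau_n <= 0:
        raise ValueError(f"tau_n must be positive, got {tau_n} ms")
    n = _n_samples(duration, dt)
    rng = _as_rng(seed)
    a = np.exp(-dt / tau_n)
    xi = rng.standard_normal(n)
    x0 = rng.standard_normal()  # draw from the stationary distribution
    x, _ = lfilter([np.sqrt(1.0 - a * a)], [1.0, -a], xi, zi=[a * x0])
    x = x - x.mean()
    x *= NORMALIZED_STD / np.std(x)
    return ContinuousSignal(x, dt, "normalized")


def invert_signal(x: ContinuousSignal) -> ContinuousSignal:
    """Return ``-x`` on the same grid (push-pull second sub-population input)."""
    return ContinuousSignal(-x.samples, x.dt, x.units)


def decimate_mean(x: ContinuousSignal, bin_ms: float) -> ContinuousSignal:
    """Block-average ``x`` into bins of ``bin_ms``.

    Used to move band-limited signals from the simulation grid (0.025 ms) to
    the analysis grid (1 ms).  Samples beyond the last full bin are dropped.
    """
    factor = int(round(bin_ms / x.dt))
    if factor < 1 or abs(factor * x.dt - bin_ms) > 1e-9 * bin_ms:
        raise ValueError(f"bin {bin_ms} ms is not a multiple of dt {x.dt} ms")
    if factor == 1:
        return ContinuousSignal(x.samples.copy(), x.dt, x.units)
    nb = x.n // factor
    y = x.samples[: nb * factor].reshape(nb, factor).mean(axis=1)
    return ContinuousSignal(y, bin_ms, x.units)


def antialiased_decimate(x: ContinuousSignal, bin_ms: float, numtaps: int = 400) -> ContinuousSignal:
    """Low-pass filter and downsample ``x`` onto a coarser grid.

    Zero-phase FIR anti-aliasing (no phase distortion of transfer
    estimates), then subsampling.  Required for spike-train signals, whose
    broadband shot power would otherwise fold into the analysis band; for
    signals already band-limited far below the target Nyquist rate it is
    equivalent to plain subsampling.
    """
    from scipy import signal as sps

    factor = int(round(bin_ms / x.dt))
    if factor < 1 or abs(factor * x.dt - bin_ms) > 1e-9 * bin_ms:
        raise ValueError(f"bin {bin_ms} ms is not a multiple of dt {x.dt} ms")
    if factor == 1:
        return ContinuousSignal(x.samples.copy(), x.dt, x.units)
    y = sps.decimate(x.samples, factor, n=numtaps, ftype="fir", zero_phase=True)
    return ContinuousSignal(y, bin_ms, x.units)


def write_signal_csv(x: ContinuousSignal, path) -> None:
    """Two-column CSV export (time_ms, value)."""
    import pandas as pd

    pd.DataFrame({"time_ms": x.times(), "value": x.samples}).to_csv(path, index=False)


def read_signal_csv(path, units: str = "dimensionless") -> ContinuousSignal:
    import pandas as pd

    df = pd.read_csv(path)
    t = df["time_ms"].to_numpy()
    dt = float(t[1] - t[0])
    return ContinuousSignal(df["value"].to_numpy(), dt, units)
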