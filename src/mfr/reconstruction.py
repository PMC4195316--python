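"""Ideal-observer Wiener reconstruction and variance-accounted-for statistics.

The non-causal ideal observer is the linear filter K(f) = P_yx / P_yy that
minimizes the mean-squared error of reconstructing the input x from the
spiking output y.  Its achievable fidelity per frequency is the
variance-accounted-for

    VAF(f) = |P_xy|^2 / (P_xx P_yy)   (magnitude-squared coherence, in %),

and the headline statistic of an experiment is the unweighted mean VAF over
the input band (lowest analysis frequency up to the stimulus cutoff).  VAF
is computed directly from the cross-spectra; the identity between VAF and
the realized reconstruction error is a test, not the definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .signals import ContinuousSignal
from .neurons import SpikeTrain
from .estimation import CrossSpectra, SpectralSettings, welch_csd, _band_mask

__all__ = [
    "VAFSpectrum",
    "SpectralFilter",
    "ReconstructionResult",
    "wiener_filter",
    "reconstruct",
    "filter_kernel",
    "vaf_spectrum",
    "population_output",
]

#: Bins with input power below this fraction of the peak P_xx carry no
#: signal and are excluded from the filter and from band averages.
POWER_FLOOR = 1e-12


@dataclass
class VAFSpectrum:
    """Variance-accounted-for per frequency (%), with its band mean."""

    frequencies: np.ndarray
    vaf: np.ndarray
    mean_vaf: float
    band: tuple

    def __post_init__(self) -> None:
        if np.any(self.vaf < 0.0) or np.any(self.vaf > 100.0):
            raise ValueError("VAF must lie in [0, 100] % in every bin")


@dataclass
class SpectralFilter:
    """A frequency-sampled linear filter (here: the Wiener filter K)."""

    frequencies: np.ndarray
    k: np.ndarray  # complex response on the frequency grid


@dataclass
class ReconstructionResult:
    """Wiener filter, its time-domain kernel, and the reconstructed input."""

    filter: SpectralFilter
    kernel_lags_ms: np.ndarray
    kernel: np.ndarray
    x_est: ContinuousSignal


def wiener_filter(
    x: ContinuousSignal,
    y: ContinuousSignal,
    settings: SpectralSettings | None = None,
    band: tuple | None = None,
) -> SpectralFilter:
    """Optimal linear reconstruction filter K(f) = P_yx / P_yy.

    K is zero outside the input band: bins whose input power P_xx falls
    below ``POWER_FLOOR`` of its peak carry no stimulus energy and cannot be
    reconstructed from.
    """
    settings = settings or SpectralSettings()
    cs = welch_csd(x, y, settings)
    mask = _band_mask(cs.frequencies, band or settings.band)
    mask &= cs.pxx > POWER_FLOOR * cs.pxx.max()
    k = np.zeros(cs.frequencies.size, dtype=complex)
    with np.errstate(divide="ignore", invalid="ignore"):
        k[mask] = cs.pyx[mask] / cs.pyy[mask]
    k[~np.isfinite(k)] = 0.0
    return SpectralFilter(cs.frequencies, k)


def reconstruct(y: ContinuousSignal, filt: SpectralFilter) -> ContinuousSignal:
    """Apply K to y in the frequency domain (non-causal) -> x_est.

    K is interpolated from its Welch grid onto the full-length FFT grid of
    y; frequencies outside the filter grid map to zero.
    """
    freqs = np.fft.rfftfreq(y.n, d=y.dt / 1000.0)
    kr = np.interp(freqs, filt.frequencies, filt.k.real, left=0.0, right=0.0)
    ki = np.interp(freqs, filt.frequencies, filt.k.imag, left=0.0, right=0.0)
    x_est = np.fft.irfft(np.fft.rfft(y.samples - y.samples.mean()) * (kr + 1j * ki), y.n)
    return ContinuousSignal(x_est, y.dt, "normalized")


def filter_kernel(filt: SpectralFilter, dt_ms: float, support_s: float = 4.0):
    """Time-domain kernel of K, centered at lag 0.

    The response is interpolated onto a grid spanning +-``support_s`` so the
    kernel's temporal support (finite for band-limited input, essentially a
    sinc) can be inspected.
    Returns (lags_ms, kernel).
    """
    n = int(round(2.0 * support_s * 1000.0 / dt_ms))
    freqs = np.fft.rfftfreq(n, d=dt_ms / 1000.0)
    kr = np.interp(freqs, filt.frequencies, filt.k.real, left=0.0, right=0.0)
    ki = np.interp(freqs, filt.frequencies, filt.k.imag, left=0.0, right=0.0)
    kernel = np.fft.fftshift(np.fft.irfft(kr + 1j * ki, n)) / (dt_ms / 1000.0)
    lags = (np.arange(n) - n // 2) * dt_ms
    return lags, kernel


def vaf_spectrum(
    x: ContinuousSignal,
    y: ContinuousSignal,
    settings: SpectralSettings | None = None,
    band: tuple | None = None,
) -> VAFSpectrum:
    """Magnitude-squared coherence of (x, y) in %, averaged over the band.

    The band runs from the lowest analysis frequency to the input cutoff;
    bins without input power are excluded (they are unreconstructable, not
    zero-fidelity).  The mean is unweighted across the remaining bins.
    """
    settings = settings or SpectralSettings()
    cs = welch_csd(x, y, settings)
    band = band or settings.band
    mask = _band_mask(cs.frequencies, band)
    mask &= cs.pxx > POWER_FLOOR * cs.pxx.max()
    if not np.any(mask):
        raise ValueError("no frequency bins with input power inside the band")
    vaf = 100.0 * np.clip(cs.coherence()[mask], 0.0, 1.0)
    return VAFSpectrum(cs.frequencies[mask], vaf, float(vaf.mean()), tuple(band))


def population_output(
    trains: Sequence[SpikeTrain],
    signs: Sequence[int] | None = None,
    dt: float | None = None,
    duration: float | None = None,
) -> ContinuousSignal:
    """Summed (sampling-rate-filtered) population output on a common grid.

    With a push-pull sign vector the output is y = y_plus - y_minus, the
    difference of the two sub-population sums.  ``dt`` may be coarser than
    the simulation step, in which case bins hold signed spike counts.
    """
    if not trains:
        raise ValueError("at least one spike train required")
    dt = trains[0].dt if dt is None else dt
    duration = max(t.duration for t in trains) if duration is None else duration
    n = int(round(duration / dt))
    if signs is None:
        signs = np.ones(len(trains), dtype=int)
    y = np.zeros(n)
    for train, s in zip(trains, signs):
        if train.n_spikes == 0:
            continue
        idx = np.clip(np.ceil(train.times / dt).astype(int) - 1, 0, n - 1)
        y += s * np.bincount(idx, minlength=n)
    return ContinuousSignal(y, dt, "dimensionless")
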