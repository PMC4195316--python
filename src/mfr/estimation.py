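"""Spike-train to continuous-signal conversion and transfer-function estimation.

Two estimation routes are implemented.

Sinusoid fit
    The classical Bode-plot procedure: fit c + A*sin(2*pi*f*t + phi) to the
    instantaneous firing rate at the *known* input frequency.  Its reliance
    on prior knowledge of f is exactly what makes it misleading above the
    Nyquist rate of the spike code (half the carrier rate).

Direct estimation
    Convert the spike train with the sampling-rate filter (a binary signal
    that is 1 in a step containing a spike), then estimate
    T(f) = P_xy(f) / P_xx(f) from Welch auto- and cross-spectra.  Gain is
    normalized to unity at the lowest analysis frequency and reported in dB;
    phase is unwrapped and reported in degrees, with lags negative.

The closed-form transfer function of the noise-free leaky IF (derived by
linearizing the threshold-crossing condition, in the spirit of Knight's
classical analysis) is provided as an independent oracle for both routes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signals import ContinuousSignal
from .neurons import NeuronParams, SpikeTrain

__all__ = [
    "SpectralSettings",
    "TransferFunction",
    "CrossSpectra",
    "SinusoidFit",
    "sampling_rate_filter",
    "alpha_filter",
    "instantaneous_rate",
    "sinusoid_fit_transfer",
    "welch_csd",
    "direct_transfer_function",
    "analytic_lif_transfer",
]


@dataclass(frozen=True)
class SpectralSettings:
    """Welch estimation settings.

    Defaults: 2-s Hann-windowed segments with 50 % overlap, giving 0.5 Hz
    resolution (the lowest evaluated frequency), per-segment mean removal so
    the carrier offset does not leak into low-frequency bins, and an analysis
    band of 0.5-200 Hz.
    """

    segment_s: float = 2.0
    window: str = "hann"
    overlap: float = 0.5
    band: tuple = (0.5, 200.0)
    min_segments: int = 10

    @property
    def resolution_hz(self) -> float:
        return 1.0 / self.segment_s

    def nperseg(self, fs_hz: float) -> int:
        return int(round(self.segment_s * fs_hz))

    def noverlap(self, fs_hz: float) -> int:
        return int(round(self.overlap * self.nperseg(fs_hz)))


@dataclass
class TransferFunction:
    """Per-frequency transfer estimate T(f).

    ``gain_db`` is normalized to 0 dB at the lowest frequency of the grid;
    ``phase_deg`` is unwrapped, with delays (lags) negative.
    """

    frequencies: np.ndarray
    gain_db: np.ndarray
    phase_deg: np.ndarray
    raw: np.ndarray

    @property
    def gain(self) -> np.ndarray:
        """Normalized linear gain."""
        return 10.0 ** (self.gain_db / 20.0)


@dataclass
class CrossSpectra:
    """Welch auto- and cross-spectral densities of two processes."""

    frequencies: np.ndarray
    pxx: np.ndarray
    pyy: np.ndarray
    pxy: np.ndarray
    fs_hz: float
    settings: SpectralSettings

    @property
    def pyx(self) -> np.ndarray:
        return np.conj(self.pxy)

    def coherence(self) -> np.ndarray:
        """Magnitude-squared coherence |P_xy|^2 / (P_xx P_yy)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.abs(self.pxy) ** 2 / (self.pxx * self.pyy)
        return np.nan_to_num(c, nan=0.0)


@dataclass
class SinusoidFit:
    """Least-squares sinusoid fit to the instantaneous firing rate."""

    f_hz: float
    offset: float  # spikes/s
    amplitude: float  # spikes/s
    phase_deg: float  # relative to the input sin(2 pi f t); lags negative
    gain: float  # amplitude / A_I if A_I given, else amplitude


def sampling_rate_filter(train: SpikeTrain, dt: float | None = None) -> ContinuousSignal:
    """Binary spike indicator on the simulation grid.

    Each step containing a spike maps to 1, all others to 0 -- the discrete
    approximation of a delta-function filter at the step width.
    """
    dt = train.dt if dt is None else dt
    n = int(round(train.duration / dt))
    y = np.zeros(n)
    if train.n_spikes:
        idx = np.clip(np.ceil(train.times / dt).astype(int) - 1, 0, n - 1)
        if idx.size != np.unique(idx).size:
            warnings.warn("multiple spikes fell into one step; bin value capped at 1")
        y[idx] = 1.0
    return ContinuousSignal(y, dt, "dimensionless") if n >= 2 else ContinuousSignal(y, dt)


def bin_spike_counts(train: SpikeTrain, bin_ms: float, duration: float | None = None) -> ContinuousSignal:
    """Spike counts per bin (decimated stand-in for the sampling-rate filter)."""
    duration = train.duration if duration is None else duration
    n = int(round(duration / bin_ms))
    idx = np.clip(np.ceil(train.times / bin_ms).astype(int) - 1, 0, n - 1)
    y = np.bincount(idx, minlength=n).astype(float)
    return ContinuousSignal(y, bin_ms, "dimensionless")


def alpha_filter(train: SpikeTrain, tau_alpha_ms: float = 100.0, dt: float | None = None) -> ContinuousSignal:
    """Convolve the spike train with the alpha function (t/tau^2) exp(-t/tau).

    The kernel is normalized so each spike contributes unit area; its peak
    follows the spike by tau_alpha.  Mimics a slow synaptic filter.
    """
    dt = train.dt if dt is None else dt
    delta = sampling_rate_filter(train, dt)
    t = np.arange(int(round(10.0 * tau_alpha_ms / dt))) * dt
    kernel = (t / tau_alpha_ms**2) * np.exp(-t / tau_alpha_ms)
    kernel /= kernel.sum() * dt  # unit area per spike, discretely
    y = sps.fftconvolve(delta.samples, kernel, mode="full")[: delta.n]
    return ContinuousSignal(y, dt, "dimensionless")


def instantaneous_rate(train: SpikeTrain):
    """Event series (t_i, 1/ISI_i): rate in spikes/s attached at each spike."""
    if train.n_spikes < 2:
        return np.empty(0), np.empty(0)
    isi = train.isis()
    return train.times[1:], 1000.0 / isi


def sinusoid_fit_transfer(
    train: SpikeTrain,
    f_hz: float,
    *,
    a_i: float | None = None,
    warmup_ms: float = 0.0,
) -> SinusoidFit:
    """Fit a sinusoid at the known input frequency to the instantaneous rate.

    The fit is linear least squares on [1, sin(wt), cos(wt)].  ``gain`` is
    the fitted output modulation amplitude divided by the input amplitude
    ``a_i`` when given.  Raises if there are too few rate points to constrain
    the fit.
    """
    t, r = instantaneous_rate(train)
    keep = t > warmup_ms
    t, r = t[keep], r[keep]
    if t.size < 4:
        raise ValueError("too few spikes to fit a sinusoid to the instantaneous rate")
    w = 2.0 * np.pi * f_hz / 1000.0  # rad/ms
    design = np.column_stack([np.ones_like(t), np.sin(w * t), np.cos(w * t)])
    (c, p, q), *_ = np.linalg.lstsq(design, r, rcond=None)
    amplitude = float(np.hypot(p, q))
    phase = float(np.degrees(np.arctan2(q, p)))
    gain = amplitude / a_i if a_i else amplitude
    return SinusoidFit(f_hz, float(c), amplitude, phase, gain)


def welch_csd(x: ContinuousSignal, y: ContinuousSignal, settings: SpectralSettings | None = None) -> CrossSpectra:
    """Welch auto- and cross-spectral densities of x and y on a shared grid.

    P_xy is conjugate-x convention, so T = P_xy / P_xx maps x to y; P_yx is
    its conjugate.  Requires enough data for ``settings.min_segments``
    averaged segments.
    """
    settings = settings or SpectralSettings()
    if abs(x.dt - y.dt) > 1e-12 * x.dt or x.n != y.n:
        raise ValueError("x and y must share one sampling grid")
    fs = x.fs_hz
    nperseg = settings.nperseg(fs)
    step = nperseg - settings.noverlap(fs)
    n_segments = (x.n - nperseg) // step + 1 if x.n >= nperseg else 0
    if n_segments < settings.min_segments:
        raise ValueError(
            f"signal supports {n_segments} Welch segments; "
            f"at least {settings.min_segments} required"
        )
    kw = dict(
        fs=fs,
        window=settings.window,
        nperseg=nperseg,
        noverlap=settings.noverlap(fs),
        detrend="constant",
    )
    f, pxx = sps.welch(x.samples, **kw)
    _, pyy = sps.welch(y.samples, **kw)
    _, pxy = sps.csd(x.samples, y.samples, **kw)
    return CrossSpectra(f, pxx, pyy, pxy, fs, settings)


def _band_mask(f: np.ndarray, band: tuple) -> np.ndarray:
    eps = 1e-9
    return (f >= band[0] - eps) & (f <= band[1] + eps)


def direct_transfer_function(
    x: ContinuousSignal,
    y: ContinuousSignal,
    settings: SpectralSettings | None = None,
    band: tuple | None = None,
) -> TransferFunction:
    """T(f) = P_xy / P_xx on the analysis band, from the Welch estimates."""
    settings = settings or SpectralSettings()
    cs = welch_csd(x, y, settings)
    mask = _band_mask(cs.frequencies, band or settings.band)
    f = cs.frequencies[mask]
    if f.size == 0:
        raise ValueError("analysis band contains no frequency bins")
    with np.errstate(divide="ignore", invalid="ignore"):
        t_raw = cs.pxy[mask] / cs.pxx[mask]
    return _package_transfer(f, t_raw)


def _package_transfer(f: np.ndarray, t_raw: np.ndarray) -> TransferFunction:
    mag = np.abs(t_raw)
    with np.errstate(divide="ignore"):
        gain_db = 20.0 * np.log10(mag) - 20.0 * np.log10(mag[0])
    phase = np.degrees(np.unwrap(np.angle(t_raw)))
    return TransferFunction(f, gain_db, phase, t_raw)


def analytic_lif_transfer(
    params: NeuronParams,
    f0: float,
    f_grid: np.ndarray,
    kind: str = "spike_train",
) -> TransferFunction:
    """Closed-form transfer function of the noise-free leaky IF at rate F_0.

    Linearizing the threshold condition of the periodically firing cell
    around its steady inter-spike interval T = 1/F_0 gives, for membrane
    time constant tau and angular frequency w (rad/ms),

        H_rate(w)  = (e^{T/tau} - e^{-iwT}) / (T (1/tau + iw))

    for the instantaneous-rate (sinusoid-fit) readout, and

        H_train(w) = iw (e^{T/tau} - e^{-iwT}) / ((1/tau + iw)(1 - e^{-iwT}))

    for the delta-train (sampling-rate-filter) readout, whose poles at
    multiples of F_0 are the spike-locking resonance peaks.  Both reduce to
    the same quasi-static limit as w -> 0.  Used solely as a test oracle.
    """
    if kind not in ("spike_train", "rate"):
        raise ValueError("kind must be 'spike_train' or 'rate'")
    f_grid = np.asarray(f_grid, dtype=float)
    if np.any(f_grid <= 0):
        raise ValueError("f_grid must contain positive frequencies")
    tau = params.tau_m_ms
    t0 = 1000.0 / f0  # ms
    w = 2.0 * np.pi * f_grid / 1000.0  # rad/ms
    num = np.exp(t0 / tau) - np.exp(-1j * w * t0)
    h = num / (t0 * (1.0 / tau + 1j * w))
    if kind == "spike_train":
        denom = 1.0 - np.exp(-1j * w * t0)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = h * (1j * w * t0) / denom
    if params.delta_s_ms:
        h = h * np.exp(-1j * w * params.delta_s_ms)
    return _package_transfer(f_grid, h)
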