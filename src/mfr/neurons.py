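"""Integrate-and-fire neuron models and firing-rate calibration.

Three model kinds are supported:

``lif``
    Passive leaky integrate-and-fire: C dV/dt = -(V - E_R)/R + I_E, spike
    and reset to E_R when V crosses V_th.
``rif``
    Resonant IF: the LIF plus a spike-triggered decaying leak conductance
    I_B = g_b * b * (V - E_R), where b jumps by 1 at each spike and decays
    with time constant tau_b, and an output spike delay Delta_s that shifts
    recorded spike times without affecting the membrane dynamics.  This
    minimal extension mimics the resonance and phase lag of a detailed
    cerebellar granule cell model around its fitted operating point.
``ideal``
    Leak-free integrator with rest/reset 0 and threshold 1, used as a
    rate-to-spike-train encoder (see :func:`simulate_ideal`); it is driven
    by a rate signal, not a current.

The default membrane constants are those fitted to the granule cell:
C = 3 pF, R = 5227 MOhm (tau = 15.7 ms), E_R = -71.5 mV, V_th = -41.8 mV,
g_b = 55.6 pS, tau_b = 19.6 ms, Delta_s = 4.85 ms; the rheobase current is
(V_th - E_R)/R = 5.68 pA.

Calibration follows the modulated-firing-rate conventions: the tonic current
I_0 is chosen (by bisection on simulated steady rates) to give a target
carrier rate F_0, and the modulation amplitude A_I is the extra current that
would raise the tonic rate to (1 + a) * F_0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import _kernels
from .signals import ContinuousSignal

__all__ = [
    "NeuronParams",
    "SpikeTrain",
    "DriveSpec",
    "RateSummary",
    "LowRateCalibration",
    "simulate",
    "simulate_ideal",
    "fI_curve",
    "calibrate_tonic_current",
    "calibrate_modulation_amplitude",
    "firing_rate",
    "measure_rates",
    "calibrate_population_lowrate",
]

DEFAULT_DT = 0.025  # ms, simulation step size


@dataclass(frozen=True)
class NeuronParams:
    """Membrane, threshold and resonance constants for one model cell."""

    c_pf: float = 3.0
    r_mohm: float = 5227.0
    e_r_mv: float = -71.5
    v_th_mv: float = -41.8
    g_b_ps: float = 0.0
    tau_b_ms: float = 19.6
    delta_s_ms: float = 0.0
    kind: str = "lif"

    def __post_init__(self) -> None:
        if self.kind not in ("lif", "rif", "ideal"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind != "ideal":
            if self.c_pf <= 0 or self.r_mohm <= 0:
                raise ValueError("C and R must be positive")
            if self.v_th_mv <= self.e_r_mv:
                raise ValueError("threshold must lie above the reset potential")
        if self.kind == "lif" and (self.g_b_ps != 0.0 or self.delta_s_ms != 0.0):
            raise ValueError("lif requires g_b = 0 and delta_s = 0 (use kind='rif')")

    @classmethod
    def lif(cls, **overrides) -> "NeuronParams":
        """Passive IF with the fitted granule-cell constants."""
        return cls(kind="lif", **overrides)

    @classmethod
    def rif(cls, **overrides) -> "NeuronParams":
        """Resonant IF with the fitted g_b, tau_b and spike delay."""
        kw = dict(g_b_ps=55.6, tau_b_ms=19.6, delta_s_ms=4.85, kind="rif")
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def ideal(cls) -> "NeuronParams":
        return cls(kind="ideal")

    @classmethod
    def preset(cls, kind: str) -> "NeuronParams":
        return {"lif": cls.lif, "rif": cls.rif, "ideal": cls.ideal}[kind]()

    @property
    def tau_m_ms(self) -> float:
        """Membrane time constant R*C in ms."""
        return self.r_mohm * self.c_pf / 1000.0

    @property
    def rheobase_pa(self) -> float:
        """Minimum constant current with sustained spiking, (V_th - E_R)/R."""
        return (self.v_th_mv - self.e_r_mv) / self.r_mohm * 1000.0


@dataclass
class SpikeTrain:
    """Ordered spike times (ms) of one cell over one trial."""

    times: np.ndarray
    dt: float
    duration: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and (
            self.times[0] < 0.0
            or self.times[-1] > self.duration
            or np.any(np.diff(self.times) <= 0.0)
        ):
            raise ValueError("spike times must be strictly increasing within [0, duration]")

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def isis(self) -> np.ndarray:
        return np.diff(self.times)


@dataclass(frozen=True)
class DriveSpec:
    """Amplitudes of the current drive delivered to one cell."""

    i0_pa: float = 0.0
    a_i_pa: float = 0.0
    a_in_pa: float = 0.0
    g_i_ns: float = 0.0
    e_i_mv: float = -65.0

    def __post_init__(self) -> None:
        if self.a_i_pa < 0 or self.a_in_pa < 0 or self.g_i_ns < 0:
            raise ValueError("amplitudes and conductances must be non-negative")


@dataclass
class RateSummary:
    """Population firing-rate statistics (spikes/s)."""

    mean: float
    std: float
    per_cell: np.ndarray


@dataclass
class LowRateCalibration:
    """Per-cell tonic currents calibrated to a target F_eff distribution."""

    i0_pa: np.ndarray
    targets: np.ndarray
    realized: np.ndarray


def _drive_array(drive) -> np.ndarray:
    if isinstance(drive, ContinuousSignal):
        return drive.samples
    return np.asarray(drive, dtype=float)


def simulate(
    params: NeuronParams,
    drive: ContinuousSignal,
    dt: float | None = None,
    *,
    g_i_ns: float = 0.0,
    e_i_mv: float = -65.0,
    v0: float | None = None,
    b0: float = 0.0,
    return_state: bool = False,
):
    """Integrate one cell over a current drive (pA) and return its spikes.

    Threshold crossings are detected at the end of each step; the reset is
    applied immediately and the resonant state b is incremented by 1.  The
    spike delay Delta_s shifts only the recorded spike times.  With
    ``return_state=True`` also returns ``(v, b)`` so a drive can be split
    into segments and resumed without changing the spike train.
    """
    if params.kind == "ideal":
        raise ValueError("use simulate_ideal() for the ideal encoder")
    x = _drive_array(drive)
    if not np.all(np.isfinite(x)):
        raise ValueError("drive contains non-finite samples")
    if dt is None:
        dt = drive.dt if isinstance(drive, ContinuousSignal) else DEFAULT_DT
    if v0 is None:
        v0 = params.e_r_mv

    if params.g_b_ps == 0.0 and g_i_ns == 0.0:
        decay = np.exp(-dt / params.tau_m_ms)
        idx, v = _kernels.lif_passive(
            x, decay, params.r_mohm / 1000.0, params.e_r_mv, params.v_th_mv, v0
        )
        b = 0.0
    else:
        g_l = 1000.0 / params.r_mohm  # nS
        idx, v, b = _kernels.if_conductance(
            x,
            dt,
            params.c_pf,
            g_l,
            params.e_r_mv,
            params.v_th_mv,
            params.g_b_ps * 1e-3,
            params.tau_b_ms,
            g_i_ns,
            e_i_mv,
            v0,
            b0,
        )
    duration = x.size * dt
    times = (idx + 1) * dt + params.delta_s_ms
    times = times[times <= duration]
    train = SpikeTrain(times, dt, duration)
    if return_state:
        return train, (v, b)
    return train


def simulate_ideal(
    rate_signal: ContinuousSignal,
    *,
    acc0: float = 0.0,
    return_state: bool = False,
):
    """Encode a rate signal (spikes/s) with the leak-free unit-threshold IF.

    The accumulator integrates the rectified rate (negative values clipped to
    zero -- the rectification phenomenon itself) and emits a spike whenever
    it reaches 1, subtracting 1.
    """
    x = _drive_array(rate_signal)
    dt = rate_signal.dt if isinstance(rate_signal, ContinuousSignal) else DEFAULT_DT
    idx, acc = _kernels.ideal_encoder(x, dt, acc0)
    duration = x.size * dt
    train = SpikeTrain((idx + 1) * dt, dt, duration)
    if return_state:
        return train, acc
    return train


def _steady_rate(train: SpikeTrain, warmup_ms: float) -> float:
    """Rate estimate from ISIs after the warm-up (exact for periodic firing)."""
    t = train.times[train.times > warmup_ms]
    if t.size < 2:
        return t.size / (train.duration - warmup_ms) * 1000.0
    return (t.size - 1) / (t[-1] - t[0]) * 1000.0


def fI_curve(
    params: NeuronParams,
    i_grid: Sequence[float],
    *,
    dt: float = DEFAULT_DT,
    duration_ms: float = 10_000.0,
    warmup_ms: float = 1_000.0,
) -> np.ndarray:
    """Steady-state firing rate (spikes/s) per constant current (pA)."""
    i_grid = np.asarray(i_grid, dtype=float)
    if np.any(np.diff(i_grid) < 0):
        raise ValueError("i_grid must be sorted ascending")
    n = int(round(duration_ms / dt))
    rates = np.empty(i_grid.size)
    for j, i_pa in enumerate(i_grid):
        train = simulate(params, np.full(n, i_pa), dt)
        rates[j] = firing_rate(train, warmup_ms=warmup_ms)
    return rates


def calibrate_tonic_current(
    params: NeuronParams,
    f0: float,
    *,
    dt: float = DEFAULT_DT,
    duration_ms: float = 10_000.0,
    warmup_ms: float = 1_000.0,
    rtol: float = 0.005,
    max_iter: int = 60,
) -> float:
    """Bisect the constant current I_0 whose tonic rate is F_0 (spikes/s).

    The rate during bisection is read from the inter-spike intervals after a
    warm-up, which for these noise-free cells converges much faster than a
    spike count.  Stops when the simulated rate is within ``rtol`` of F_0.
    """
    if f0 <= 0:
        raise ValueError("F0 must be positive (any subthreshold current gives 0)")
    n = int(round(duration_ms / dt))

    def rate_at(i_pa: float) -> float:
        return _steady_rate(simulate(params, np.full(n, i_pa), dt), warmup_ms)

    lo = params.rheobase_pa
    hi = lo + 1.0
    while rate_at(hi) < f0:
        hi += 2.0 * (hi - lo)
        if hi > lo + 1e5:
            raise RuntimeError(f"could not bracket F0 = {f0} spikes/s")
    mid = 0.5 * (lo + hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = rate_at(mid)
        if abs(r - f0) <= rtol * f0:
            break
        if r < f0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9:
            break
    return mid


def calibrate_modulation_amplitude(
    params: NeuronParams, i0: float, a: float, f0: float, **kwargs
) -> float:
    """Amplitude A_I such that a tonic input I_0 + A_I fires at (1 + a) F_0."""
    if a <= 0:
        raise ValueError("relative modulation a must be positive")
    return calibrate_tonic_current(params, (1.0 + a) * f0, **kwargs) - i0


def firing_rate(train: SpikeTrain, warmup_ms: float = 0.0) -> float:
    """Spike count over duration (spikes/s), after discarding the warm-up."""
    span = train.duration - warmup_ms
    if span <= 0:
        raise ValueError("warm-up exceeds the train duration")
    return float(np.sum(train.times > warmup_ms)) / span * 1000.0


def measure_rates(trains: Sequence[SpikeTrain], warmup_ms: float = 0.0) -> RateSummary:
    """Per-cell rates with population mean and std (spikes/s)."""
    rates = np.array([firing_rate(t, warmup_ms) for t in trains])
    return RateSummary(float(rates.mean()), float(rates.std()), rates)


def calibrate_population_lowrate(
    params: NeuronParams,
    n_cells: int,
    target_mean: float,
    target_std: float,
    *,
    a_i_pa: float,
    x: ContinuousSignal,
    signs: Sequence[int] | None = None,
    noise=None,
    rng: np.random.Generator | int | None = None,
    cal_duration_ms: float = 30_000.0,
    warmup_ms: float = 1_000.0,
    rtol: float = 0.1,
    atol_floor: float = 0.1,
    max_iter: int = 24,
) -> LowRateCalibration:
    """Per-cell tonic currents for a low effective-rate population.

    Each cell receives the fixed modulation ``a_i_pa * sign * x`` (plus an
    optional per-cell noise current, already scaled to pA) and its tonic
    current is bisected until the effective rate F_eff measured over the
    calibration window matches a per-cell target drawn from a
    truncated-at-zero Normal(target_mean, target_std).

    ``noise`` may be None, a sequence of per-cell sample arrays, or a
    callable ``cell_index -> array`` (regenerated on demand so large
    populations need not hold every noise trace in memory at once).
    """
    if target_mean <= 0 or target_std < 0:
        raise ValueError("target rate statistics must be positive")
    if params.kind == "ideal":
        raise ValueError("low-rate calibration applies to membrane models only")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    targets = rng.normal(target_mean, target_std, size=n_cells)
    while np.any(targets < 0):  # truncate at zero by redrawing
        bad = targets < 0
        targets[bad] = rng.normal(target_mean, target_std, size=int(bad.sum()))

    dt = x.dt
    ncal = int(round(cal_duration_ms / dt))
    if ncal > x.n:
        raise ValueError("x is shorter than the calibration window")
    if signs is None:
        signs = np.ones(n_cells, dtype=int)

    i0 = np.empty(n_cells)
    realized = np.empty(n_cells)
    rheo = params.rheobase_pa
    span_rate = 1000.0 / (cal_duration_ms - warmup_ms)
    for c in range(n_cells):
        base = a_i_pa * signs[c] * x.samples[:ncal]
        noise_c = noise(c) if callable(noise) else (None if noise is None else noise[c])
        if noise_c is not None:
            base = base + noise_c[:ncal]
        target = targets[c]
        tol = max(rtol * target, atol_floor)

        def rate_at(i_pa: float) -> float:
            train = simulate(params, base + i_pa, dt)
            return float(np.sum(train.times > warmup_ms)) * span_rate

        lo, hi = 0.0, rheo
        k = 0
        while rate_at(hi) < target:
            hi += 2.0
            k += 1
            if k > 20:
                raise RuntimeError(f"target {target:.2f} spikes/s unreachable for cell {c}")
        mid = 0.5 * (lo + hi)
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            r = rate_at(mid)
            if abs(r - target) <= tol:
                break
            if r < target:
                lo = mid
            else:
                hi = mid
        i0[c] = mid
        realized[c] = rate_at(mid)
    return LowRateCalibration(i0, targets, realized)
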