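"""Rate-coded input spike trains and population input assignments.

A continuous signal x(t) (normalized to 2*sigma = 1) is mapped onto an input
firing rate R(t) = a * F0in * x(t) + F0in about a carrier rate F0in.  Spike
trains are produced either by the deterministic ideal integrate-and-fire
encoder (flat transfer function, near-zero ISI variance at constant rate) or
by an inhomogeneous Poisson process (ISI CV near 1).  Populations can mix
heterogeneous carriers and a push-pull split in which half of the cells
encode the inverted signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import ContinuousSignal
from .neurons import SpikeTrain

__all__ = [
    "RateSignal",
    "PopulationAssignment",
    "make_rate_signal",
    "sample_carrier_rates",
    "encode_poisson",
    "assign_push_pull",
]


@dataclass
class RateSignal:
    """A firing-rate waveform R(t) = a * F0in * x(t) + F0in (spikes/s).

    No clipping is applied here; rectification of negative rates happens in
    the ideal-IF encoder.
    """

    signal: ContinuousSignal
    f0in: float
    a: float

    @property
    def samples(self) -> np.ndarray:
        return self.signal.samples

    @property
    def dt(self) -> float:
        return self.signal.dt


@dataclass
class PopulationAssignment:
    """Per-cell carrier rates and signal signs for a population of encoders."""

    n: int
    signs: np.ndarray
    carrier_rates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signs = np.asarray(self.signs, dtype=int)
        if self.signs.size != self.n or not np.all(np.isin(self.signs, (-1, 1))):
            raise ValueError("signs must be +-1, one per cell")


def make_rate_signal(x: ContinuousSignal, f0in: float, a: float) -> RateSignal:
    """Affine map of a normalized signal onto a modulated firing rate."""
    r = f0in * (1.0 + a * x.samples)
    return RateSignal(ContinuousSignal(r, x.dt, "spikes/s"), f0in, a)


def sample_carrier_rates(
    n_in: int,
    mean: float,
    v: float = 0.5,
    seed=None,
) -> np.ndarray:
    """Draw per-cell carrier rates, Normal(mean, v*mean/2) truncated at 0.

    ``v`` is the relative variance convention 2*std = v*mean; v = 0.5 around
    a 40 spikes/s mean gives std 10 spikes/s, so 95 % of carriers lie in
    [20, 60] spikes/s.
    """
    if mean <= 0 or v < 0:
        raise ValueError("mean must be positive and v non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    std = v * mean / 2.0
    if std == 0.0:
        return np.full(n_in, float(mean))
    rates = rng.normal(mean, std, size=n_in)
    while np.any(rates < 0):
        bad = rates < 0
        rates[bad] = rng.normal(mean, std, size=int(bad.sum()))
    return rates


def encode_poisson(rate, seed=None) -> SpikeTrain:
    """Inhomogeneous Poisson spike train via per-step Bernoulli(R*dt) draws."""
    if isinstance(rate, RateSignal):
        rate = rate.signal
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = np.clip(rate.samples, 0.0, None)
    p = r * rate.dt * 1e-3
    if np.any(p > 1.0):
        raise ValueError("rate too high for the step size (R*dt > 1)")
    idx = np.nonzero(rng.random(r.size) < p)[0]
    return SpikeTrain((idx + 1) * rate.dt, rate.dt, r.size * rate.dt)


def assign_push_pull(n: int, carrier_rates=None) -> PopulationAssignment:
    """Split a population so the second half encodes the inverted signal.

    Deterministic split: the first ceil(n/2) cells keep the signal, the
    remaining floor(n/2) receive -x.
    """
    if n < 2:
        raise ValueError("push-pull coding needs at least 2 cells")
    signs = np.ones(n, dtype=int)
    signs[n - n // 2 :] = -1
    if carrier_rates is not None:
        carrier_rates = np.asarray(carrier_rates, dtype=float)
        if carrier_rates.size != n:
            raise ValueError("one carrier rate per cell required")
    return PopulationAssignment(n, signs, carrier_rates)
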