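"""Run bundles (directory serialization) and deterministic test fixtures.

A :class:`RunBundle` is the on-disk form of one run: ``config.yaml`` (with a
schema version and metadata), ``spikes.csv`` (cell_id, time_ms),
``stimulus.csv`` / ``output.csv`` (time_ms, value), ``results.json`` and
``spectra.csv``.  Everything is plain text; spike times round-trip exactly.

:func:`make_fixture` builds small canned scenarios for the test suite from
fixed seeds -- no stored data files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .signals import ContinuousSignal, gen_bandlimited_gaussian
from .neurons import NeuronParams, SpikeTrain, calibrate_modulation_amplitude, calibrate_tonic_current, simulate

SCHEMA_VERSION = "1"

__all__ = ["RunBundle", "write_bundle", "read_bundle", "make_fixture", "SCHEMA_VERSION"]


@dataclass
class RunBundle:
    """In-memory form of one serialized run directory."""

    config: dict
    spike_trains: list = field(default_factory=list)
    stimulus: ContinuousSignal | None = None
    output: ContinuousSignal | None = None
    results: dict | None = None
    spectra: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)
    missing: tuple = ()  # fields absent on disk when read back


def _write_signal(sig: ContinuousSignal, path: Path) -> None:
    pd.DataFrame({"time_ms": sig.times(), "value": sig.samples}).to_csv(path, index=False)


def _read_signal(path: Path, units: str) -> ContinuousSignal:
    df = pd.read_csv(path, float_precision="round_trip")
    t = df["time_ms"].to_numpy()
    return ContinuousSignal(df["value"].to_numpy(), float(t[1] - t[0]), units)


def write_bundle(bundle: RunBundle, path) -> None:
    """Serialize a bundle into a directory of text files."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    head = {"schema_version": SCHEMA_VERSION, "meta": bundle.meta, "config": bundle.config}
    with open(path / "config.yaml", "w") as fh:
        yaml.safe_dump(head, fh, sort_keys=False)

    rows = []
    for cid, train in enumerate(bundle.spike_trains):
        for t in train.times:
            rows.append((cid, t, train.dt, train.duration))
    pd.DataFrame(rows, columns=["cell_id", "time_ms", "dt_ms", "duration_ms"]).to_csv(
        path / "spikes.csv", index=False
    )
    if bundle.stimulus is not None:
        _write_signal(bundle.stimulus, path / "stimulus.csv")
    if bundle.output is not None:
        _write_signal(bundle.output, path / "output.csv")
    if bundle.results is not None:
        with open(path / "results.json", "w") as fh:
            json.dump(bundle.results, fh, indent=1)
    if bundle.spectra is not None:
        bundle.spectra.to_csv(path / "spectra.csv", index=False)


def read_bundle(path) -> RunBundle:
    """Read a bundle directory; optional files absent are flagged, not fatal."""
    path = Path(path)
    with open(path / "config.yaml") as fh:
        head = yaml.safe_load(fh)
    version = str(head.get("schema_version"))
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"bundle schema version {version} incompatible with reader version {SCHEMA_VERSION}"
        )
    df = pd.read_csv(path / "spikes.csv", float_precision="round_trip")
    trains = []
    if len(df):
        for cid, grp in df.groupby("cell_id"):
            trains.append(
                SpikeTrain(
                    grp["time_ms"].to_numpy(),
                    float(grp["dt_ms"].iloc[0]),
                    float(grp["duration_ms"].iloc[0]),
                )
            )
    missing = []
    stimulus = output = results = spectra = None
    if (path / "stimulus.csv").exists():
        stimulus = _read_signal(path / "stimulus.csv", "normalized")
    else:
        missing.append("stimulus")
    if (path / "output.csv").exists():
        output = _read_signal(path / "output.csv", "dimensionless")
    else:
        missing.append("output")
    if (path / "results.json").exists():
        with open(path / "results.json") as fh:
            results = json.load(fh)
    else:
        missing.append("results")
    if (path / "spectra.csv").exists():
        spectra = pd.read_csv(path / "spectra.csv")
    else:
        missing.append("spectra")
    return RunBundle(
        head.get("config", {}),
        trains,
        stimulus,
        output,
        results,
        spectra,
        head.get("meta", {}),
        tuple(missing),
    )


def make_fixture(name: str) -> RunBundle:
    """Deterministic canned scenarios for tests (generated, never stored).

    ``lif_baseline_12s``
        A 12-s LIF run at the baseline condition (carrier 40 spikes/s,
        a = 0.1, 20-Hz band-limited input).
    ``lti_known``
        (x, y) pair where y is x through a known second-order Butterworth
        low-pass; the designed frequency response is in ``results``.
    ``delay_pair``
        y is x delayed by a known lag; VAF is 100 % and the Wiener filter
        phase slope equals the delay.
    ``independent``
        Two independent band-limited noises; VAF is at chance level.
    """
    from scipy import signal as sps

    if name == "lif_baseline_12s":
        params = NeuronParams.lif()
        f0, a, cutoff, dt = 40.0, 0.1, 20.0, 0.025
        i0 = calibrate_tonic_current(params, f0, dt=dt)
        a_i = calibrate_modulation_amplitude(params, i0, a, f0, dt=dt)
        x = gen_bandlimited_gaussian(cutoff, 12_000.0, dt, 1234)
        train = simulate(params, i0 + a_i * x.samples, dt)
        cfg = {"model": "lif", "f0": f0, "a": a, "cutoff_hz": cutoff, "dt_ms": dt}
        return RunBundle(cfg, [train], stimulus=x, results={"i0_pa": i0, "a_i_pa": a_i})

    dt_ms = 1.0
    if name == "lti_known":
        x = gen_bandlimited_gaussian(200.0, 30_000.0, dt_ms, 77)
        b, bb = sps.butter(2, 50.0, fs=1000.0 / dt_ms)
        y = sps.lfilter(b, bb, x.samples)
        cfg = {"fixture": name, "dt_ms": dt_ms}
        return RunBundle(
            cfg,
            stimulus=x,
            output=ContinuousSignal(y, dt_ms, "dimensionless"),
            results={"butter_order": 2, "butter_cutoff_hz": 50.0, "b": list(b), "a": list(bb)},
        )
    if name == "delay_pair":
        delay_ms = 50.0
        x = gen_bandlimited_gaussian(20.0, 30_000.0, dt_ms, 78)
        y = np.roll(x.samples, int(delay_ms / dt_ms))
        cfg = {"fixture": name, "dt_ms": dt_ms}
        return RunBundle(
            cfg,
            stimulus=x,
            output=ContinuousSignal(y, dt_ms, "dimensionless"),
            results={"delay_ms": delay_ms},
        )
    if name == "independent":
        x = gen_bandlimited_gaussian(20.0, 30_000.0, dt_ms, 79)
        y = gen_bandlimited_gaussian(20.0, 30_000.0, dt_ms, 80)
        cfg = {"fixture": name, "dt_ms": dt_ms}
        return RunBundle(cfg, stimulus=x, output=ContinuousSignal(y.samples, dt_ms, "dimensionless"))
    raise ValueError(f"unknown fixture {name!r}")
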