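"""Record containers and file I/O.

Internal unit system: time in ms, voltage in mV, rates in 1/ms.  Files and
user-facing surfaces may speak Hz; conversion happens at the boundary only
(1 Hz = 1e-3 / ms).

On-disk formats
---------------
* traces: CSV/TSV with header columns ``time_ms,voltage_mV``;
* spike times: one peak time (ms) per line;
* recordings: HDF5 with groups ``/segment_k/{voltage,spikes}`` carrying
  ``dt_ms``/``t0_ms`` attributes, or a pair of CSV files per segment;
* configuration: JSON/YAML key-value file.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VoltageTrace",
    "SpikeTimes",
    "SpikeTrainBinned",
    "Recording",
    "read_trace",
    "read_spike_times",
    "write_trace",
    "write_recording",
    "read_recording",
    "load_config",
    "DEFAULT_CONFIG",
    "hz_to_per_ms",
    "per_ms_to_hz",
]


def hz_to_per_ms(rate_hz: float) -> float:
    return rate_hz * 1e-3


def per_ms_to_hz(rate_per_ms: float) -> float:
    return rate_per_ms * 1e3


@dataclass
class VoltageTrace:
    """Uniformly sampled membrane voltage (mV) with bin width dt (ms)."""

    values: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.values)):
            bad = int(np.flatnonzero(~np.isfinite(self.values))[0])
            raise ValueError(f"non-finite voltage sample at row {bad}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n * self.dt

    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)


@dataclass
class SpikeTimes:
    """Strictly increasing action-potential peak times (ms)."""

    peak_times: np.ndarray

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if self.peak_times.ndim != 1:
            raise ValueError("peak_times must be 1-D")
        if self.peak_times.size > 1 and np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak_times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.peak_times.size


@dataclass
class SpikeTrainBinned:
    """Non-negative spike counts per bin, aligned with a VoltageTrace."""

    counts: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if np.any(np.abs(rounded - counts) > 1e-9):
                raise ValueError("counts must be integers")
            counts = rounded.astype(np.int64)
        self.counts = counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n(self) -> int:
        return self.counts.size

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class Recording:
    """One or more (trace, binned spike train) segments, treated as independent."""

    segments: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.segments) == 0:
            raise ValueError("no segments")
        for k, (tr, sp) in enumerate(self.segments):
            if tr.n != sp.n:
                raise ValueError(f"segment {k}: trace and spike train lengths differ")
            if abs(tr.dt - sp.dt) > 1e-9 * tr.dt:
                raise ValueError(f"segment {k}: trace and spike train dt differ")

    @property
    def dt(self) -> float:
        return self.segments[0][0].dt

    @property
    def n_bins(self) -> int:
        return sum(tr.n for tr, _ in self.segments)

    @property
    def n_spikes(self) -> int:
        return sum(sp.total for _, sp in self.segments)

    @property
    def duration(self) -> float:
        return self.n_bins * self.dt


# ---------------------------------------------------------------------------
# trace / spike-time files


def _read_delimited(path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    expected = {"time_ms", "voltage_mV"}
    if not expected.issubset(df.columns):
        raise ValueError(f"trace file must have columns {sorted(expected)}, got {list(df.columns)}")
    return df


def read_trace(path, format: str | None = None) -> VoltageTrace:
    """Read a voltage trace from CSV/TSV (``time_ms,voltage_mV``) or HDF5."""
    path = Path(path)
    fmt = format or {".csv": "csv", ".tsv": "tsv", ".h5": "hdf5", ".hdf5": "hdf5"}.get(
        path.suffix.lower(), "csv"
    )
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            g = f["segment_0"] if "segment_0" in f else f
            v = np.asarray(g["voltage"])
            return VoltageTrace(v, dt=float(g.attrs["dt_ms"]), t0=float(g.attrs.get("t0_ms", 0.0)))
    if fmt not in ("csv", "tsv"):
        raise ValueError(f"unknown format {fmt!r}")
    try:
        df = _read_delimited(path, "," if fmt == "csv" else "\t")
    except (UnicodeDecodeError, pd.errors.ParserError) as exc:
        raise ValueError(f"file {path} does not match declared format {fmt!r}") from exc
    if df["voltage_mV"].isna().any() or df["time_ms"].isna().any():
        row = int(df.index[df.isna().any(axis=1)][0])
        raise ValueError(f"missing/NaN sample at row {row}")
    t = df["time_ms"].to_numpy(dtype=float)
    v = df["voltage_mV"].to_numpy(dtype=float)
    if t.size < 2:
        return VoltageTrace(v, dt=1.0, t0=float(t[0]) if t.size else 0.0)
    steps = np.diff(t)
    dt = float(np.median(steps))
    if dt <= 0 or np.any(np.abs(steps - dt) > 1e-6 * max(abs(dt), 1.0)):
        raise ValueError("non-uniform sampling in trace file")
    return VoltageTrace(v, dt=dt, t0=float(t[0]))


def read_spike_times(path) -> SpikeTimes:
    """Read one peak time (ms) per line."""
    vals = np.loadtxt(path, ndmin=1, dtype=float)
    return SpikeTimes(vals)


def write_trace(trace: VoltageTrace, path, format: str = "csv") -> None:
    sep = {"csv": ",", "tsv": "\t"}[format]
    df = pd.DataFrame({"time_ms": trace.times(), "voltage_mV": trace.values})
    # %.17g guarantees a bit-exact float64 round trip through text
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# recordings


def write_recording(rec: Recording, path, format: str = "hdf5") -> None:
    """Write a Recording losslessly. HDF5 holds everything in one file; the
    csv/tsv layout writes one ``<stem>_segK.csv`` trace file plus
    ``<stem>_segK_spikes.csv`` counts per segment and a ``<stem>_meta.json``."""
    path = Path(path)
    if format == "hdf5":
        with h5py.File(path, "w") as f:
            f.attrs["metadata_json"] = json.dumps(rec.metadata, default=str)
            for k, (tr, sp) in enumerate(rec.segments):
                g = f.create_group(f"segment_{k}")
                g.create_dataset("voltage", data=tr.values)
                g.create_dataset("spikes", data=sp.counts)
                g.attrs["dt_ms"] = tr.dt
                g.attrs["t0_ms"] = tr.t0
        return
    if format not in ("csv", "tsv"):
        raise ValueError(f"unknown format {format!r}")
    sep = "," if format == "csv" else "\t"
    stem = path.parent / path.stem
    for k, (tr, sp) in enumerate(rec.segments):
        write_trace(tr, f"{stem}_seg{k}{path.suffix}", format)
        pd.DataFrame({"count": sp.counts}).to_csv(f"{stem}_seg{k}_spikes{path.suffix}", sep=sep, index=False)
    meta = dict(rec.metadata)
    meta["_n_segments"] = len(rec.segments)
    meta["_suffix"] = path.suffix
    with open(f"{stem}_meta.json", "w") as fh:
        json.dump(meta, fh, default=str)


def read_recording(path, format: str = "hdf5") -> Recording:
    path = Path(path)
    if format == "hdf5":
        if not h5py.is_hdf5(path):
            raise ValueError(f"format mismatch: {path} is not an HDF5 file")
        segments = []
        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs.get("metadata_json", "{}"))
            keys = sorted((k for k in f if k.startswith("segment_")), key=lambda s: int(s.split("_")[1]))
            for k in keys:
                g = f[k]
                dt = float(g.attrs["dt_ms"])
                tr = VoltageTrace(np.asarray(g["voltage"]), dt=dt, t0=float(g.attrs["t0_ms"]))
                sp = SpikeTrainBinned(np.asarray(g["spikes"]), dt=dt)
                segments.append((tr, sp))
        return Recording(segments, meta)
    if format not in ("csv", "tsv"):
        raise ValueError(f"unknown format {format!r}")
    if h5py.is_hdf5(path):
        raise ValueError(f"format mismatch: {path} is HDF5 but {format} was requested")
    sep = "," if format == "csv" else "\t"
    stem = path.parent / path.stem
    with open(f"{stem}_meta.json") as fh:
        meta = json.load(fh)
    n_seg = meta.pop("_n_segments")
    suffix = meta.pop("_suffix")
    segments = []
    for k in range(n_seg):
        tr = read_trace(f"{stem}_seg{k}{suffix}", format)
        counts = pd.read_csv(f"{stem}_seg{k}_spikes{suffix}", sep=sep)["count"].to_numpy()
        segments.append((tr, SpikeTrainBinned(counts, dt=tr.dt)))
    return Recording(segments, meta)


# ---------------------------------------------------------------------------
# configuration

#: defaults, all in internal units (ms / mV / per-ms)
DEFAULT_CONFIG = {
    "dt_ms": 1.0,
    "u_r_mv": -60.0,
    "r0_per_ms": 4.15e-3,
    "beta_per_mv": 0.374,
    "delta_ms": 4.0,
    "delta_max_ms": 10.0,
    "n_cov_basis": 10,
    "n_adapt_basis": 10,
    "n_spike_kernel_bins": 60,
    "flip_adapt_rates": False,
    "median_width_ms": 1.0,
    "spike_threshold_mv": None,  # None -> automatic (mean + 5 MAD)
    "min_separation_ms": 2.0,
    "n_restarts": 5,
    "max_cycles": 100,
    "tol_per_bin": 1e-8,
    "seed": 0,
}

_UNIT_SCALE = {
    "hz": ("per_ms", 1e-3),
    "khz": ("per_ms", 1.0),
    "per_ms": ("per_ms", 1.0),
    "ms": ("ms", 1.0),
    "s": ("ms", 1e3),
    "mv": ("mv", 1.0),
    "v": ("mv", 1e3),
}


def _parse_quantity(value):
    """Parse '4.15 Hz' / '1 ms' / '2 mV' strings into internal units."""
    if not isinstance(value, str):
        return value
    parts = value.split()
    if len(parts) == 2:
        try:
            num = float(parts[0])
        except ValueError:
            return value
        unit = parts[1].lower().replace("/ms", "per_ms").replace("ms^-1", "per_ms")
        if unit in _UNIT_SCALE:
            return num * _UNIT_SCALE[unit][1]
    return value


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load a JSON/YAML config, fill defaults, normalize units.

    Unknown keys warn (typos should be visible but not fatal); values whose
    type contradicts the default raise.  Quantities written as strings with
    units ('4.15 Hz') are converted to internal units (per-ms, ms, mV).
    """
    cfg = dict(DEFAULT_CONFIG)
    raw = {}
    if path is not None:
        with open(path) as fh:
            text = fh.read()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a key-value mapping")
    if overrides:
        raw.update(overrides)
    for key, value in raw.items():
        if key not in cfg:
            warnings.warn(f"unknown config key {key!r} ignored", stacklevel=2)
            continue
        value = _parse_quantity(value)
        default = cfg[key]
        if default is not None and value is not None:
            if isinstance(default, bool) != isinstance(value, bool):
                raise TypeError(f"config key {key!r}: expected {type(default).__name__}")
            if isinstance(default, (int, float)) and not isinstance(value, (int, float)):
                raise TypeError(f"config key {key!r}: expected a number, got {type(value).__name__}")
        cfg[key] = value
    for key in ("dt_ms", "median_width_ms", "min_separation_ms"):
        if cfg[key] is not None and cfg[key] <= 0:
            raise ValueError(f"config key {key!r} must be positive")
    return cfg
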