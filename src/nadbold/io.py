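"""Readers and writers for electrophysiology traces, BOLD series and masks.

The on-disk layout is deliberately minimal and text-first:

* LFP sessions are a single-channel delimited file with a ``# key: value``
  header plus a sibling ``<stem>.events.csv`` table (``event_type, time_s``),
  or an HDF5 mirror of the same content for speed.
* BOLD volume-of-interest (VOI) series are one-column CSV tables, optionally
  extracted from a 4D NIfTI image with a 3D mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "LfpRecording",
    "BoldSeries",
    "VoiMask",
    "read_lfp",
    "write_lfp",
    "read_bold_series",
    "write_bold_series",
    "extract_voi_series",
    "write_results",
    "FormatError",
    "ValidationError",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """In-memory data violate a container invariant."""


@dataclass
class LfpRecording:
    """A single-channel local field potential trace with scanner/stim events.

    Parameters
    ----------
    samples
        Voltage values in mV.
    sample_rate
        Sampling rate in Hz.
    t0
        Time of the first sample in seconds (recording clock).
    volume_triggers
        Times (s) of the scanner trigger at the start of each fMRI volume.
    stim_pulses
        Times (s) of each electrical stimulation pulse.
    meta
        Free-form labels (animal id, condition, provenance of processing).
    blank_intervals
        Time intervals ``(start, end)`` in seconds whose samples were replaced
        by interpolation (artifact blanking); excluded from amplitude stats.
    processing
        Ordered names of conditioning steps already applied.
    """

    samples: np.ndarray
    sample_rate: float
    t0: float = 0.0
    volume_triggers: np.ndarray = field(default_factory=lambda: np.empty(0))
    stim_pulses: np.ndarray = field(default_factory=lambda: np.empty(0))
    meta: dict = field(default_factory=dict)
    blank_intervals: list = field(default_factory=list)
    processing: list = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.volume_triggers = np.asarray(self.volume_triggers, dtype=float)
        self.stim_pulses = np.asarray(self.stim_pulses, dtype=float)
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        t_end = self.t0 + self.samples.size / self.sample_rate
        for name, ev in (("volume_triggers", self.volume_triggers),
                         ("stim_pulses", self.stim_pulses)):
            if ev.size and (ev.min() < self.t0 - 1e-9 or ev.max() > t_end + 1e-9):
                raise ValidationError(f"{name} outside recording span")
        if self.volume_triggers.size > 1:
            if np.any(np.diff(self.volume_triggers) <= 0):
                raise ValidationError("volume_triggers must be strictly increasing")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sample_rate

    def index_at(self, t: float) -> int:
        """Index of the sample at (or immediately after) time ``t``."""
        return int(np.ceil((t - self.t0) * self.sample_rate - 1e-9))

    def copy_with(self, **kw) -> "LfpRecording":
        out = replace(self, **kw)
        out.meta = dict(kw.get("meta", self.meta))
        out.blank_intervals = list(kw.get("blank_intervals", self.blank_intervals))
        out.processing = list(kw.get("processing", self.processing))
        return out


@dataclass
class BoldSeries:
    """Per-volume BOLD signal in one VOI.

    ``values[k]`` is the signal of volume ``k``; volume ``k`` spans
    ``[k*tr, (k+1)*tr)`` seconds (0-based convention, so volumes 900-959
    cover minutes 30-32 at TR = 2 s).
    """

    values: np.ndarray
    tr: float = 2.0
    stim_volume: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.tr <= 0:
            raise ValidationError("tr must be positive")
        if self.stim_volume is not None and not (0 <= self.stim_volume < self.n_volumes):
            raise ValidationError("stim_volume outside series")

    @property
    def n_volumes(self) -> int:
        return int(self.values.size)


@dataclass
class VoiMask:
    """A set of voxel indices over a 3D grid (e.g. the right dorsal hippocampus)."""

    indices: np.ndarray          # (n, 3) integer voxel coordinates
    grid: tuple                  # (nx, ny, nz)
    label: str = "voi"

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.ndim != 2 or self.indices.shape[1] != 3:
            raise ValidationError("indices must be (n, 3)")
        if self.indices.shape[0] == 0:
            raise ValidationError("mask is empty")
        if np.any(self.indices < 0) or np.any(self.indices >= np.asarray(self.grid)):
            raise ValidationError("mask indices outside grid")

    @classmethod
    def from_array(cls, arr: np.ndarray, label: str = "voi") -> "VoiMask":
        arr = np.asarray(arr)
        return cls(np.argwhere(arr != 0), tuple(arr.shape), label)


# ---------------------------------------------------------------------------
# LFP container
# ---------------------------------------------------------------------------

_LFP_HEADER_KEYS = ("sample_rate", "t0")


def write_lfp(rec: LfpRecording, path, dialect: str = "csv") -> Path:
    """Write a recording in the native container. Returns the main file path."""
    path = Path(path)
    if dialect == "csv":
        header = {"sample_rate": rec.sample_rate, "t0": rec.t0,
                  "meta": json.dumps(rec.meta, sort_keys=True),
                  "processing": json.dumps(rec.processing),
                  "blank_intervals": json.dumps(
                      [[float(a), float(b)] for a, b in rec.blank_intervals])}
        with open(path, "w") as fh:
            for k, v in header.items():
                fh.write(f"# {k}: {v}\n")
            fh.write("sample_mv\n")
            np.savetxt(fh, rec.samples, fmt="%.10g")
        ev = _event_table(rec)
        ev.to_csv(path.with_suffix(path.suffix + ".events.csv"), index=False)
    elif dialect == "hdf5":
        with h5py.File(path, "w") as f:
            d = f.create_dataset("samples", data=rec.samples)
            d.attrs["units"] = "mV"
            f.attrs["sample_rate"] = rec.sample_rate
            f.attrs["t0"] = rec.t0
            f.attrs["meta"] = json.dumps(rec.meta, sort_keys=True)
            f.attrs["processing"] = json.dumps(rec.processing)
            f.create_dataset("volume_triggers", data=rec.volume_triggers)
            f.create_dataset("stim_pulses", data=rec.stim_pulses)
            f.create_dataset("blank_intervals",
                             data=np.asarray(rec.blank_intervals, dtype=float).reshape(-1, 2))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def _event_table(rec: LfpRecording) -> pd.DataFrame:
    rows = [("volume_trigger", t) for t in rec.volume_triggers]
    rows += [("stim_pulse", t) for t in rec.stim_pulses]
    df = pd.DataFrame(rows, columns=["event_type", "time_s"])
    return df.sort_values("time_s", kind="stable").reset_index(drop=True)


def read_lfp(path, dialect: str | None = None) -> LfpRecording:
    """Read a recording written by :func:`write_lfp`.

    The dialect is inferred from the file when not given. Missing
    ``sample_rate`` raises :class:`FormatError`; invariant violations
    (e.g. non-monotone volume triggers) raise :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "hdf5" if h5py.is_hdf5(path) else "csv"
    if dialect == "hdf5":
        with h5py.File(path, "r") as f:
            if "sample_rate" not in f.attrs:
                raise FormatError("header does not declare sample_rate")
            return LfpRecording(
                samples=f["samples"][:],
                sample_rate=float(f.attrs["sample_rate"]),
                t0=float(f.attrs.get("t0", 0.0)),
                volume_triggers=f["volume_triggers"][:] if "volume_triggers" in f else np.empty(0),
                stim_pulses=f["stim_pulses"][:] if "stim_pulses" in f else np.empty(0),
                meta=json.loads(f.attrs.get("meta", "{}")),
                processing=json.loads(f.attrs.get("processing", "[]")),
                blank_intervals=[tuple(r) for r in f["blank_intervals"][:]]
                if "blank_intervals" in f else [],
            )
    header: dict = {}
    samples = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                k, _, v = line.lstrip("# ").partition(":")
                header[k.strip()] = v.strip()
            elif line != "sample_mv":
                samples.append(float(line))
    if "sample_rate" not in header:
        raise FormatError("header does not declare sample_rate")
    vol, stim = np.empty(0), np.empty(0)
    ev_path = path.with_suffix(path.suffix + ".events.csv")
    if ev_path.exists():
        ev = pd.read_csv(ev_path)
        vol = ev.loc[ev.event_type == "volume_trigger", "time_s"].to_numpy()
        stim = ev.loc[ev.event_type == "stim_pulse", "time_s"].to_numpy()
    return LfpRecording(
        samples=np.asarray(samples, dtype=float),
        sample_rate=float(header["sample_rate"]),
        t0=float(header.get("t0", 0.0)),
        volume_triggers=vol,
        stim_pulses=stim,
        meta=json.loads(header.get("meta", "{}")),
        processing=json.loads(header.get("processing", "[]")),
        blank_intervals=[tuple(x) for x in json.loads(header.get("blank_intervals", "[]"))],
    )


# ---------------------------------------------------------------------------
# BOLD series
# ---------------------------------------------------------------------------

def write_bold_series(series: BoldSeries, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# tr: {series.tr}\n")
        fh.write(f"# stim_volume: {'' if series.stim_volume is None else series.stim_volume}\n")
        fh.write(f"# meta: {json.dumps(series.meta, sort_keys=True)}\n")
        pd.DataFrame({"volume": np.arange(series.n_volumes),
                      "value": series.values}).to_csv(fh, index=False)
    return path


def read_bold_series(path) -> BoldSeries:
    path = Path(path)
    header: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                k, _, v = line.lstrip("# ").partition(":")
                header[k.strip()] = v.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh)
    if "tr" not in header:
        raise FormatError("header does not declare tr")
    sv = header.get("stim_volume", "")
    return BoldSeries(values=df["value"].to_numpy(),
                      tr=float(header["tr"]),
                      stim_volume=int(sv) if sv else None,
                      meta=json.loads(header.get("meta", "{}")))


def extract_voi_series(image, mask: VoiMask, tr: float = 2.0,
                       stim_volume: int | None = None) -> BoldSeries:
    """Mean signal over the mask voxels for every volume of a 4D image.

    ``image`` is a path to a NIfTI file or an already-loaded nibabel image.
    Voxel means are computed in double precision regardless of on-disk dtype.
    """
    import nibabel as nib

    img = nib.load(str(image)) if isinstance(image, (str, Path)) else image
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValidationError("expected a 4D image")
    if tuple(data.shape[:3]) != tuple(mask.grid):
        raise ValidationError(f"mask grid {mask.grid} does not match image grid {data.shape[:3]}")
    i, j, k = mask.indices.T
    values = data[i, j, k, :].mean(axis=0)
    return BoldSeries(values=values, tr=tr, stim_volume=stim_volume,
                      meta={"voi": mask.label, "n_voxels": int(mask.indices.shape[0])})


def write_results(tables: dict, path) -> Path:
    """Write a dict of result DataFrames as CSV files under ``path``.

    Column order is preserved as given; files are named ``<key>.csv``.
    Round-trips losslessly via :func:`pandas.read_csv` at full float precision.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(path / f"{name}.csv", index=False, float_format="%.12g")
    return path
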