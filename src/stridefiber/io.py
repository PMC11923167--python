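"""Readers and writers for session containers and result tables.

Two on-disk dialects:

* **HDF5 container** for full 1 kHz sessions (a 30-min session is ~2M
  samples per channel)::

      /photometry/{t, signal, reference}   attrs: sample_rate, signal_wavelength
      /behavior/{t, velocity[, motion_index]}
      /events/{timestamp, label}
      /stim/{onset, duration}              attrs: frequency, power, pulse_width,
                                                  schedule_kind

* **CSV** long-format time series for small files: ``(t, signal,
  reference)`` photometry, ``(t, velocity[, motion_index])`` behavior,
  ``(timestamp, label)`` events, ``(onset, duration, ...)`` stimulation.

Exported tables write floats with 12 significant digits so a re-import
reproduces values to better than 1e-9 relative.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import pandas as pd

from .bouts import BoutTable
from .session import (
    BehaviorTrack,
    PhotometrySession,
    SchemaError,
    SessionBundle,
    StimProtocol,
)

PathLike = Union[str, Path]


def write_session(bundle: SessionBundle, path: PathLike) -> None:
    """Write a bundle to an HDF5 container (layout in the module docstring)."""
    with h5py.File(path, "w") as f:
        f.attrs["subject_id"] = bundle.subject_id
        f.attrs["meta"] = json.dumps(bundle.meta)
        if bundle.photometry is not None:
            ph = bundle.photometry
            g = f.create_group("photometry")
            g.create_dataset("t", data=ph.t)
            g.create_dataset("signal", data=ph.signal)
            g.create_dataset("reference", data=ph.reference)
            g.attrs["sample_rate"] = ph.sample_rate
            g.attrs["signal_wavelength"] = ph.signal_wavelength
            if ph.events:
                ev = f.create_group("events")
                ev.create_dataset(
                    "timestamp", data=np.array([e[0] for e in ph.events])
                )
                ev.create_dataset(
                    "label",
                    data=np.array([e[1] for e in ph.events], dtype=object),
                    dtype=h5py.string_dtype(),
                )
        if bundle.behavior is not None:
            bh = bundle.behavior
            g = f.create_group("behavior")
            g.create_dataset("t", data=bh.t)
            g.create_dataset("velocity", data=bh.velocity)
            if bh.motion_index is not None:
                g.create_dataset("motion_index", data=bh.motion_index)
            g.attrs["calibration"] = bh.calibration
        if bundle.stim is not None:
            st = bundle.stim
            g = f.create_group("stim")
            g.create_dataset("onset", data=st.trial_onsets)
            g.create_dataset("duration", data=st.trial_durations)
            g.attrs["frequency"] = st.pulse_frequency
            g.attrs["pulse_width"] = st.pulse_width
            g.attrs["power"] = st.power
            g.attrs["schedule_kind"] = st.schedule_kind


def _load_hdf5(path: PathLike) -> SessionBundle:
    with h5py.File(path, "r") as f:
        photometry = behavior = stim = None
        if "photometry" in f:
            g = f["photometry"]
            for name in ("t", "signal", "reference"):
                if name not in g:
                    raise SchemaError(f"/photometry missing dataset '{name}'")
            events = []
            if "events" in f:
                ts = f["events"]["timestamp"][()]
                labels = [
                    s.decode() if isinstance(s, bytes) else str(s)
                    for s in f["events"]["label"][()]
                ]
                events = list(zip(map(float, ts), labels))
            photometry = PhotometrySession(
                t=g["t"][()],
                signal=g["signal"][()],
                reference=g["reference"][()],
                sample_rate=float(g.attrs["sample_rate"]),
                signal_wavelength=int(g.attrs.get("signal_wavelength", 465)),
                events=events,
            )
        if "behavior" in f:
            g = f["behavior"]
            for name in ("t", "velocity"):
                if name not in g:
                    raise SchemaError(f"/behavior missing dataset '{name}'")
            behavior = BehaviorTrack(
                t=g["t"][()],
                velocity=g["velocity"][()],
                motion_index=g["motion_index"][()] if "motion_index" in g else None,
                calibration=float(g.attrs.get("calibration", 4.0)),
            )
        if "stim" in f:
            g = f["stim"]
            stim = StimProtocol(
                trial_onsets=g["onset"][()],
                trial_durations=g["duration"][()],
                pulse_frequency=float(g.attrs.get("frequency", 20.0)),
                pulse_width=float(g.attrs.get("pulse_width", 5.0)),
                power=float(g.attrs.get("power", 3.0)),
                schedule_kind=str(g.attrs.get("schedule_kind", "trial_varied")),
            )
        return SessionBundle(
            photometry=photometry,
            behavior=behavior,
            stim=stim,
            subject_id=str(f.attrs.get("subject_id", "")),
            meta=json.loads(f.attrs.get("meta", "{}")),
        )


def write_session_csv(bundle: SessionBundle, directory: PathLike) -> None:
    """Write a bundle as CSV files (photometry/behavior/events/stim) in a
    directory, with full double precision for lossless round-trips."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    fmt = "%.17g"
    if bundle.photometry is not None:
        ph = bundle.photometry
        pd.DataFrame(
            {"t": ph.t, "signal": ph.signal, "reference": ph.reference}
        ).to_csv(d / "photometry.csv", index=False, float_format=fmt)
        if ph.events:
            pd.DataFrame(ph.events, columns=["timestamp", "label"]).to_csv(
                d / "events.csv", index=False, float_format=fmt
            )
    if bundle.behavior is not None:
        bh = bundle.behavior
        cols = {"t": bh.t, "velocity": bh.velocity}
        if bh.motion_index is not None:
            cols["motion_index"] = bh.motion_index
        pd.DataFrame(cols).to_csv(d / "behavior.csv", index=False, float_format=fmt)
    if bundle.stim is not None:
        st = bundle.stim
        pd.DataFrame(
            {
                "onset": st.trial_onsets,
                "duration": st.trial_durations,
                "frequency": st.pulse_frequency,
                "power": st.power,
            }
        ).to_csv(d / "stim.csv", index=False, float_format=fmt)


def _load_csv_dir(d: Path) -> SessionBundle:
    photometry = behavior = stim = None
    if (d / "photometry.csv").exists():
        photometry = _load_csv(d / "photometry.csv").photometry
        if (d / "events.csv").exists():
            ev = pd.read_csv(d / "events.csv", float_precision="round_trip")
            photometry.events = list(
                zip(ev["timestamp"].astype(float), ev["label"].astype(str))
            )
    if (d / "behavior.csv").exists():
        behavior = _load_csv(d / "behavior.csv").behavior
    if (d / "stim.csv").exists():
        st = pd.read_csv(d / "stim.csv", float_precision="round_trip")
        stim = StimProtocol(
            trial_onsets=st["onset"].to_numpy(),
            trial_durations=st["duration"].to_numpy(),
            pulse_frequency=float(st["frequency"].iloc[0]) if "frequency" in st else 20.0,
            power=float(st["power"].iloc[0]) if "power" in st else 3.0,
        )
    return SessionBundle(photometry=photometry, behavior=behavior, stim=stim)


def _load_csv(path: PathLike) -> SessionBundle:
    path = Path(path)
    if path.is_dir():
        return _load_csv_dir(path)
    df = pd.read_csv(path, float_precision="round_trip")
    cols = set(df.columns)
    if {"t", "signal"}.issubset(cols):
        if "reference" not in cols:
            raise SchemaError("photometry CSV missing column 'reference'")
        rate = (len(df) - 1) / (df["t"].iloc[-1] - df["t"].iloc[0])
        return SessionBundle(
            photometry=PhotometrySession(
                t=df["t"].to_numpy(),
                signal=df["signal"].to_numpy(),
                reference=df["reference"].to_numpy(),
                sample_rate=float(round(rate, 6)),
            )
        )
    if {"t", "velocity"}.issubset(cols):
        return SessionBundle(
            behavior=BehaviorTrack(
                t=df["t"].to_numpy(),
                velocity=df["velocity"].to_numpy(),
                motion_index=df["motion_index"].to_numpy()
                if "motion_index" in cols
                else None,
            )
        )
    raise SchemaError(
        "CSV must contain columns (t, signal, reference) or (t, velocity); "
        f"found {sorted(cols)}"
    )


def load_session(path: PathLike, format: Optional[str] = None) -> SessionBundle:
    """Load a session bundle from an HDF5 container or a CSV time series."""
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "csv"
    if format == "hdf5":
        return _load_hdf5(path)
    if format == "csv":
        return _load_csv(path)
    raise ValueError(f"unknown format {format!r}")


def export_tables(
    results: Union[pd.DataFrame, BoutTable], path: PathLike, format: str = "csv"
) -> None:
    """Write a results table as CSV/TSV with 12 significant digits.

    An empty table writes its header only.
    """
    if isinstance(results, BoutTable):
        results = results.df
    if not isinstance(results, pd.DataFrame):
        raise TypeError("export_tables expects a DataFrame or BoutTable")
    sep = {"csv": ",", "tsv": "\t"}.get(format)
    if sep is None:
        raise ValueError(f"unknown table format {format!r}")
    results.to_csv(path, sep=sep, index=False, float_format="%.12g")
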