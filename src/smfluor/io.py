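"""File formats and results serialization.

Photon streams travel as HDF5 (datasets ``/photons/timestamp_us`` and
``/photons/detector`` with the alternation scheme in attributes) or as a
two-column CSV fallback (``t_us,detector`` with detector ∈ {donor,
acceptor}).  Trajectories are long-format CSV (frame, I_donor, I_acceptor,
optional molecule_id).  Results bundles are versioned JSON with floats at
full precision, embedding the exact configuration used so identical config
and inputs reproduce byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .alex import AlternationScheme, BurstTable, PhotonStream
from .tirf import Trajectory

logger = logging.getLogger("smfluor")

RESULTS_SCHEMA_VERSION = "1"
_DETECTOR_NAMES = {0: "donor", 1: "acceptor"}
_DETECTOR_CODES = {"donor": 0, "acceptor": 1}


@dataclasses.dataclass
class RunConfig:
    """The exact knobs of one analysis run; serialized next to every result."""

    seed: int = 0
    period_us: float = 100.0
    dex_window: tuple[float, float] = (0.0, 40.0)
    aex_window: tuple[float, float] = (50.0, 90.0)
    rate_threshold_kHz: float = 3.0
    min_photons: int = 40
    smoothing_window_ms: float = 1.0
    factors_source: str = "auto"
    bin_width: float = 0.025
    R0: float = 60.0
    fcs_w0_m: float = 2.5e-7
    fcs_T_K: float = 303.15
    fcs_eta_Pa_s: float = 0.7972e-3
    fcs_kappa: float = 6.0
    out_dir: str = "."

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _scheme_from_attrs(attrs) -> AlternationScheme:
    return AlternationScheme(
        period_us=float(attrs.get("period_us", 100.0)),
        dex_window=tuple(attrs.get("dex_window", (0.0, 40.0))),
        aex_window=tuple(attrs.get("aex_window", (50.0, 90.0))),
    )


def write_photons(stream: PhotonStream, path) -> None:
    """Write a photon stream to HDF5 (.h5/.hdf5) or CSV (anything else)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            grp = f.create_group("photons")
            grp.create_dataset("timestamp_us", data=np.asarray(stream.timestamps, dtype=np.int64))
            grp.create_dataset("detector", data=np.asarray(stream.detectors, dtype=np.int8))
            grp.attrs["period_us"] = stream.scheme.period_us
            grp.attrs["dex_window"] = stream.scheme.dex_window
            grp.attrs["aex_window"] = stream.scheme.aex_window
    else:
        df = pd.DataFrame({
            "t_us": np.asarray(stream.timestamps, dtype=np.int64),
            "detector": [_DETECTOR_NAMES[int(d)] for d in stream.detectors],
        })
        df.to_csv(path, index=False)


def read_photons(path, scheme: AlternationScheme | None = None) -> PhotonStream:
    """Read a photon stream written by :func:`write_photons`.

    Raises a parse error naming the first offending row on unsorted
    timestamps or unknown detector labels; an empty file yields an empty
    stream with a warning.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            grp = f["photons"]
            ts = grp["timestamp_us"][:]
            det = grp["detector"][:]
            scheme = scheme or _scheme_from_attrs(grp.attrs)
    else:
        df = pd.read_csv(path)
        if df.empty:
            warnings.warn(f"{path} contains no photons", UserWarning)
            return PhotonStream(
                np.array([], dtype=np.int64), np.array([], dtype=np.int8),
                scheme or AlternationScheme(),
            )
        if not {"t_us", "detector"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns t_us,detector, got {list(df.columns)}")
        unknown = ~df["detector"].isin(_DETECTOR_CODES)
        if unknown.any():
            row = int(np.argmax(unknown.to_numpy()))
            raise ValueError(
                f"{path}: unknown detector label {df['detector'].iloc[row]!r} at row {row}"
            )
        ts = df["t_us"].to_numpy(dtype=np.int64)
        det = df["detector"].map(_DETECTOR_CODES).to_numpy(dtype=np.int8)
        scheme = scheme or AlternationScheme()
    if ts.size and np.any(np.diff(ts) <= 0):
        row = int(np.argmax(np.diff(ts) <= 0)) + 1
        raise ValueError(f"{path}: timestamps not strictly increasing at row {row}")
    return PhotonStream(timestamps=ts, detectors=det, scheme=scheme)


def read_trajectories(path) -> list[Trajectory]:
    """Read long-format trajectory CSV into one Trajectory per molecule_id."""
    df = pd.read_csv(path)
    required = {"frame", "I_donor", "I_acceptor"}
    if not required <= set(df.columns):
        missing = sorted(required - set(df.columns))
        raise ValueError(f"{path}: missing required columns {missing}")
    if "molecule_id" not in df.columns:
        df = df.assign(molecule_id="mol0")
    out = []
    for mol, sub in df.groupby("molecule_id", sort=True):
        sub = sub.sort_values("frame")
        out.append(Trajectory(
            I_d=sub["I_donor"].to_numpy(dtype=float),
            I_a=sub["I_acceptor"].to_numpy(dtype=float),
            molecule_id=str(mol),
        ))
    return out


def write_trajectories(trajectories: list[Trajectory], path) -> None:
    frames = []
    for traj in trajectories:
        frames.append(pd.DataFrame({
            "frame": np.arange(traj.n_frames),
            "I_donor": traj.I_d,
            "I_acceptor": traj.I_a,
            "molecule_id": traj.molecule_id or "mol0",
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def write_results(bundle: dict, out_dir, name: str = "results.json") -> Path:
    """Write a self-describing results bundle (schema version + config embedded)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"schema_version": RESULTS_SCHEMA_VERSION, **bundle}
    path = out_dir / name
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default))
    logger.info("wrote %s", path)
    return path


def read_results(path) -> dict:
    return json.loads(Path(path).read_text())


def write_burst_table(table: BurstTable, path) -> None:
    table.df.to_csv(path, index=False)
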