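"""File formats: trajectory/TTL/metrics CSV, photometry and sweep HDF5.

All on-disk formats are plain: CSV for tabular data, HDF5 for sampled
signals, JSON for manifests and sweep sidecars.  Arena geometry is not
serialized with trajectories; the arena name travels in the CSV header
comment and is rebuilt from :mod:`csdsphys.arenas` on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .arenas import make_arena
from .core import PhotometryRecording, SweepSet, Trajectory

__all__ = [
    "write_trajectory_csv", "read_trajectory_csv",
    "write_photometry_h5", "read_photometry_h5",
    "write_ttl_csv", "read_ttl_csv",
    "write_sweepset", "read_sweepset",
    "write_manifest", "read_manifest",
]


def write_trajectory_csv(path: str | Path, traj: Trajectory) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# arena={traj.arena.name}\n")
        pd.DataFrame(
            {"time_s": traj.time_s, "x_cm": traj.x_cm, "y_cm": traj.y_cm}
        ).to_csv(fh, index=False)


def read_trajectory_csv(path: str | Path, arena=None) -> Trajectory:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        df = pd.read_csv(fh)
    if arena is None:
        if not header.startswith("# arena="):
            raise ValueError(f"{path}: missing arena header and no arena given")
        arena = make_arena(header.split("=", 1)[1])
    return Trajectory(
        time_s=df["time_s"].to_numpy(),
        x_cm=df["x_cm"].to_numpy(),
        y_cm=df["y_cm"].to_numpy(),
        arena=arena,
    )


def write_photometry_h5(path: str | Path, rec: PhotometryRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("time_s", data=rec.time_s)
        f.create_dataset("f490", data=rec.f490)
        f.create_dataset("f405", data=rec.f405)
        f.attrs["rate_hz"] = rec.rate_hz
        if rec.sync_events:
            f.create_dataset("sync_time_s", data=[t for t, _ in rec.sync_events])
            f.create_dataset(
                "sync_label",
                data=np.array([lbl for _, lbl in rec.sync_events], dtype="S64"),
            )


def read_photometry_h5(path: str | Path) -> PhotometryRecording:
    with h5py.File(path, "r") as f:
        sync = []
        if "sync_time_s" in f:
            sync = [
                (float(t), lbl.decode())
                for t, lbl in zip(f["sync_time_s"][...], f["sync_label"][...])
            ]
        return PhotometryRecording(
            time_s=f["time_s"][...],
            f490=f["f490"][...],
            f405=f["f405"][...],
            rate_hz=float(f.attrs["rate_hz"]),
            sync_events=sync,
        )


def write_ttl_csv(path: str | Path, events: list[tuple[float, str]]) -> None:
    pd.DataFrame(events, columns=["time_s", "label"]).to_csv(path, index=False)


def read_ttl_csv(path: str | Path) -> list[tuple[float, str]]:
    df = pd.read_csv(path)
    return [(float(t), str(lbl)) for t, lbl in zip(df["time_s"], df["label"])]


def write_sweepset(h5_path: str | Path, sweeps: SweepSet) -> None:
    """HDF5 traces plus a JSON sidecar describing the protocol."""
    h5_path = Path(h5_path)
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("traces", data=sweeps.traces)
    sidecar = {
        "protocol": sweeps.protocol,
        "commands": list(map(float, sweeps.commands)),
        "rate_hz": sweeps.rate_hz,
        "step_on_s": sweeps.step_on_s,
        "step_off_s": sweeps.step_off_s,
    }
    h5_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_sweepset(h5_path: str | Path) -> SweepSet:
    h5_path = Path(h5_path)
    meta = json.loads(h5_path.with_suffix(".json").read_text())
    with h5py.File(h5_path, "r") as f:
        traces = f["traces"][...]
    return SweepSet(
        protocol=meta["protocol"],
        commands=np.asarray(meta["commands"], dtype=float),
        traces=traces,
        rate_hz=float(meta["rate_hz"]),
        step_on_s=float(meta["step_on_s"]),
        step_off_s=float(meta["step_off_s"]),
    )


def read_consumption_csv(path: str | Path) -> pd.DataFrame:
    """Two-bottle consumption records: mouse_id, sucrose_g, water_g per day.

    Rows are summed per mouse across days (bottle sides are irrelevant
    once consumption is attributed), yielding one row per mouse ready
    for :func:`csdsphys.behavior.sucrose_preference`.
    """
    df = pd.read_csv(path)
    required = {"mouse_id", "sucrose_g", "water_g"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"consumption CSV missing columns: {sorted(missing)}")
    return df.groupby("mouse_id", sort=True)[["sucrose_g", "water_g"]].sum().reset_index()


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
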