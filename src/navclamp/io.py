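"""Readers and writers for sweep data.

The on-disk format is a long-form CSV with columns

    cell_id, protocol, sweep_index, sweep_value, time_ms, command_mV, current_pA

plus a JSON sidecar carrying the full protocol declaration and sweep
metadata, so the command trace is exactly reconstructible and a round trip
through disk is lossless.  An HDF5 container with the identical schema is
provided for large recordings.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .protocols import Sweep, SweepSet, VoltageProtocol

__all__ = [
    "sweeps_to_frame",
    "write_sweeps",
    "read_sweeps",
    "write_sweeps_hdf5",
    "read_sweeps_hdf5",
]

CSV_COLUMNS = [
    "cell_id",
    "protocol",
    "sweep_index",
    "sweep_value",
    "time_ms",
    "command_mV",
    "current_pA",
]


def sweeps_to_frame(ss: SweepSet) -> pd.DataFrame:
    """Long-form DataFrame with one row per sample."""
    cell_id = ss.meta.get("cell_id", "")
    frames = []
    for sw in ss.sweeps:
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": cell_id,
                    "protocol": ss.protocol.name,
                    "sweep_index": sw.index,
                    "sweep_value": sw.value,
                    "time_ms": sw.time_ms,
                    "command_mV": sw.command_mv,
                    "current_pA": sw.current_pa,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[CSV_COLUMNS]


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_sweeps(ss: SweepSet, csv_path: str | Path, meta_path: str | Path | None = None) -> None:
    """Write a SweepSet as CSV plus JSON sidecar (default: same stem, .json)."""
    csv_path = Path(csv_path)
    meta_path = Path(meta_path) if meta_path is not None else _sidecar_path(csv_path)
    sweeps_to_frame(ss).to_csv(csv_path, index=False)
    sidecar = {"protocol": ss.protocol.to_dict(), "meta": ss.meta}
    meta_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_sweeps(csv_path: str | Path, meta_path: str | Path | None = None) -> SweepSet:
    """Read a SweepSet written by :func:`write_sweeps`."""
    csv_path = Path(csv_path)
    meta_path = Path(meta_path) if meta_path is not None else _sidecar_path(csv_path)
    sidecar = json.loads(meta_path.read_text())
    protocol = VoltageProtocol.from_dict(sidecar["protocol"])
    df = pd.read_csv(csv_path, float_precision="round_trip")
    sweeps = []
    for idx, sub in df.groupby("sweep_index", sort=True):
        sweeps.append(
            Sweep(
                index=int(idx),
                value=float(sub["sweep_value"].iloc[0]),
                time_ms=sub["time_ms"].to_numpy(),
                command_mv=sub["command_mV"].to_numpy(),
                current_pa=sub["current_pA"].to_numpy(),
            )
        )
    return SweepSet(protocol=protocol, sweeps=sweeps, meta=dict(sidecar["meta"]))


def write_sweeps_hdf5(ss: SweepSet, path: str | Path) -> None:
    """Write a SweepSet to HDF5 (same schema, one group per sweep)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["protocol"] = json.dumps(ss.protocol.to_dict(), sort_keys=True)
        f.attrs["meta"] = json.dumps(ss.meta, sort_keys=True)
        for sw in ss.sweeps:
            grp = f.create_group(f"sweep_{sw.index:04d}")
            grp.attrs["index"] = sw.index
            grp.attrs["value"] = sw.value
            grp.create_dataset("time_ms", data=sw.time_ms)
            grp.create_dataset("command_mV", data=sw.command_mv)
            grp.create_dataset("current_pA", data=sw.current_pa)


def read_sweeps_hdf5(path: str | Path) -> SweepSet:
    import h5py

    with h5py.File(path, "r") as f:
        protocol = VoltageProtocol.from_dict(json.loads(f.attrs["protocol"]))
        meta = json.loads(f.attrs["meta"])
        sweeps = []
        for key in sorted(f.keys()):
            grp = f[key]
            sweeps.append(
                Sweep(
                    index=int(grp.attrs["index"]),
                    value=float(grp.attrs["value"]),
                    time_ms=np.asarray(grp["time_ms"]),
                    command_mv=np.asarray(grp["command_mV"]),
                    current_pa=np.asarray(grp["current_pA"]),
                )
            )
    return SweepSet(protocol=protocol, sweeps=sweeps, meta=meta)
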