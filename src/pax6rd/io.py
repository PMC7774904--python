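"""Result persistence: HDF5 snapshot containers, summary CSVs, manifests."""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .metrics import summarise
from .model import SPECIES
from .params import ModelParameters
from .pde import DomainMask2D, Grid1D, SimulationResult

__all__ = [
    "save_result",
    "load_result",
    "snapshot_metrics",
    "write_manifest",
]


def save_result(result: SimulationResult, path: str | Path) -> None:
    """Persist a SimulationResult to HDF5: one dataset per species per snapshot.

    Layout: ``/snapshots/t{index:05d}/{species}`` datasets with a ``time``
    attribute per group; parameters, geometry and run metadata as root
    attributes.  A sidecar ``<path>.metrics.csv`` of per-snapshot summary
    metrics is written alongside.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["package_version"] = __version__
        f.attrs["variant"] = result.variant
        f.attrs["seed"] = -1 if result.seed is None else int(result.seed)
        f.attrs["scenario"] = result.scenario or ""
        f.attrs["params"] = json.dumps(result.params.to_dict())
        f.attrs["metadata"] = json.dumps(result.metadata, default=float)
        geo = result.geometry
        if isinstance(geo, Grid1D):
            f.attrs["geometry_kind"] = "grid1d"
            f.attrs["geometry"] = json.dumps(
                {"n_points": geo.n_points, "dx": geo.dx, "boundary": geo.boundary}
            )
        else:
            f.attrs["geometry_kind"] = "mask2d"
            f.attrs["geometry"] = json.dumps(
                {
                    "dx": geo.dx,
                    "long_axis": geo.long_axis,
                    "short_axis": geo.short_axis,
                    "orientation_deg": geo.orientation_deg,
                }
            )
            f.create_dataset("mask", data=geo.mask.astype(np.uint8))
        f.create_dataset("times", data=result.times)
        grp = f.create_group("snapshots")
        for i, t in enumerate(result.times):
            g = grp.create_group(f"t{i:05d}")
            g.attrs["time"] = float(t)
            for j, s in enumerate(SPECIES):
                g.create_dataset(s, data=result.snapshots[i, j])
    snapshot_metrics(result).to_csv(path.with_suffix(path.suffix + ".metrics.csv"), index=False)


def load_result(path: str | Path) -> SimulationResult:
    """Read a SimulationResult back from HDF5 (exact round-trip of fields)."""
    with h5py.File(path, "r") as f:
        times = np.array(f["times"])
        params = ModelParameters.from_dict(json.loads(f.attrs["params"]))
        geo_info = json.loads(f.attrs["geometry"])
        if f.attrs["geometry_kind"] == "grid1d":
            geometry: Grid1D | DomainMask2D = Grid1D(**geo_info)
        else:
            geometry = DomainMask2D(mask=np.array(f["mask"]).astype(bool), **geo_info)
        n = len(times)
        snaps = np.stack(
            [
                np.stack([np.array(f[f"snapshots/t{i:05d}/{s}"]) for s in SPECIES])
                for i in range(n)
            ]
        )
        seed = int(f.attrs["seed"])
        return SimulationResult(
            times=times,
            snapshots=snaps,
            params=params,
            variant=str(f.attrs["variant"]),
            geometry=geometry,
            seed=None if seed < 0 else seed,
            scenario=str(f.attrs["scenario"]) or None,
            metadata=json.loads(f.attrs["metadata"]),
        )


def snapshot_metrics(result: SimulationResult) -> pd.DataFrame:
    """Per-snapshot summary metrics: one row per stored time point."""
    rows = []
    for i, t in enumerate(result.times):
        state = result.state(i)
        summ = summarise(state.P, state.B, result.geometry)
        row = {
            "time": float(t),
            "pole_count": summ.pole_count,
            "polarisation_index": summ.polarisation_index,
            "polarisation_angle": summ.polarisation_angle,
            "pax6_receptor_correlation": summ.pax6_receptor_correlation,
            "outcome_class": summ.outcome_class,
        }
        for s in SPECIES:
            arr = getattr(state, s)
            if isinstance(result.geometry, DomainMask2D):
                arr = arr[result.geometry.mask]
            row[f"mean_{s}"] = float(np.mean(arr))
        rows.append(row)
    return pd.DataFrame(rows)


def config_hash(config_dict: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config_dict, sort_keys=True).encode()
    ).hexdigest()[:16]


def write_manifest(
    out_dir: str | Path,
    seed: int,
    configs: dict[str, dict],
    outputs: dict[str, str],
) -> Path:
    """Write a run manifest binding outputs to configs, seed and version."""
    out_dir = Path(out_dir)
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "configs": {name: {"hash": config_hash(c), "config": c} for name, c in configs.items()},
        "outputs": outputs,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=float))
    return path
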