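"""Persistence layer: snapshot / velocity-field / fraction-series CSV files.

CSV is the primary format (human-auditable and diff-able).  Snapshots get a
JSON sidecar recording the well geometry, physics parameters and seed, plus
a genealogy CSV so lineage analyses survive a round trip.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .. import __version__
from ..biofilm_sim.state import PhysicsParams, SimState
from ..selection_fitness import FractionSeries
from ..velocity_analysis import VelocityField
from ..well_geometry import WellSpec

__all__ = [
    "write_snapshot", "read_snapshot", "write_run", "read_run",
    "write_field", "read_field", "write_series", "read_series",
]

SNAPSHOT_COLUMNS = [
    "time_h", "id", "founder_id", "genotype", "strain",
    "x_um", "y_um", "angle_rad", "length_um", "radius_um",
]


def write_snapshot(state: SimState, path) -> None:
    df = pd.DataFrame({
        "time_h": np.full(state.n, state.time),
        "id": state.ids,
        "founder_id": state.founder,
        "genotype": state.genotype,
        "strain": state.strain,
        "x_um": state.x,
        "y_um": state.y,
        "angle_rad": state.angle,
        "length_um": state.length,
        "radius_um": state.radius,
    })
    df.to_csv(path, index=False, float_format="%.10g")


def read_snapshot(path, spec: WellSpec, params: PhysicsParams,
                  parent_of=None) -> SimState:
    df = pd.read_csv(path, float_precision="round_trip")
    state = SimState(spec, params, np.random.default_rng(0))
    n = len(df)
    state.time = float(df["time_h"].iloc[0]) if n else 0.0
    state.ids = df["id"].to_numpy(np.int64)
    state.founder = df["founder_id"].to_numpy(np.int64)
    state.genotype = df["genotype"].to_numpy(np.int64)
    state.strain = df["strain"].to_numpy(np.int8)
    state.x = df["x_um"].to_numpy(float)
    state.y = df["y_um"].to_numpy(float)
    state.angle = df["angle_rad"].to_numpy(float)
    state.length = df["length_um"].to_numpy(float)
    state.radius = df["radius_um"].to_numpy(float)
    state.lth = np.full(n, params.l_div)
    from ..biofilm_sim.mechanics import NWALLS

    state.sp_active = np.zeros((n, NWALLS), dtype=np.bool_)
    state.sp_ax = np.zeros((n, NWALLS))
    state.sp_ay = np.zeros((n, NWALLS))
    state.sp_rest = np.zeros((n, NWALLS))
    state.sp_frac = np.zeros((n, NWALLS))
    state.next_id = int(state.ids.max()) + 1 if n else 0
    state.parent_of = parent_of if parent_of is not None else []
    return state


def write_run(snapshots, out_dir, seed=None, protocol=None) -> None:
    """Write a full run: per-snapshot CSVs, genealogy and a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, snap in enumerate(snapshots):
        write_snapshot(snap, out / f"snapshot_{i:04d}.csv")
    last = snapshots[-1]
    pd.DataFrame({
        "id": np.arange(len(last.parent_of), dtype=np.int64),
        "parent_id": np.array(last.parent_of, dtype=np.int64),
    }).to_csv(out / "genealogy.csv", index=False)
    spec = last.spec
    meta = {
        "version": __version__,
        "seed": seed,
        "well": {
            "width_um": spec.width,
            "height_um": spec.height,
            "period_um": None if spec.flat else spec.period_T,
            "amplitude_um": spec.amplitude_A,
            "flat": spec.flat,
        },
        "physics": dataclasses.asdict(last.params),
        "protocol": getattr(protocol, "phases", protocol),
        "times_h": [s.time for s in snapshots],
    }
    with open(out / "run.json", "w") as fh:
        json.dump(meta, fh, indent=1, default=str)


def read_run(out_dir) -> list:
    """Load all snapshots of a run (sorted by index) with shared genealogy."""
    out = Path(out_dir)
    with open(out / "run.json") as fh:
        meta = json.load(fh)
    w = meta["well"]
    spec = WellSpec(
        width=w["width_um"], height=w["height_um"],
        period_T=math.inf if w["flat"] else w["period_um"],
        amplitude_A=w["amplitude_um"],
    )
    phys = {k: v for k, v in meta["physics"].items()}
    if isinstance(phys.get("cap_fraction"), str):
        phys["cap_fraction"] = None if phys["cap_fraction"] == "None" else float(phys["cap_fraction"])
    params = PhysicsParams(**phys)
    gen = pd.read_csv(out / "genealogy.csv")
    parent_of = gen["parent_id"].tolist()
    snaps = []
    for p in sorted(out.glob("snapshot_*.csv")):
        snaps.append(read_snapshot(p, spec, params, parent_of))
    return snaps


def write_field(field: VelocityField, path) -> None:
    ny, nx = field.vx.shape
    iy, ix = np.mgrid[0:ny, 0:nx]
    df = pd.DataFrame({
        "x_bin": ix.ravel(),
        "y_bin": iy.ravel(),
        "vx": field.vx.ravel(),
        "vy": field.vy.ravel(),
        "count": field.counts.ravel(),
    })
    with open(path, "w") as fh:
        fh.write(f"#meta origin={field.grid_origin[0]!r},{field.grid_origin[1]!r} "
                 f"spacing={field.grid_spacing!r} shape={ny},{nx}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_field(path) -> VelocityField:
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh, float_precision="round_trip")
    parts = dict(p.split("=") for p in header.replace("#meta ", "").split())
    ox, oy = (float(v) for v in parts["origin"].split(","))
    spacing = float(parts["spacing"])
    ny, nx = (int(v) for v in parts["shape"].split(","))
    vx = np.zeros((ny, nx))
    vy = np.zeros((ny, nx))
    counts = np.zeros((ny, nx), dtype=int)
    vx[df["y_bin"], df["x_bin"]] = df["vx"]
    vy[df["y_bin"], df["x_bin"]] = df["vy"]
    counts[df["y_bin"], df["x_bin"]] = df["count"]
    return VelocityField((ox, oy), spacing, vx, vy, counts)


def write_series(series: FractionSeries, path) -> None:
    pd.DataFrame({"time_h": series.times, "fraction": series.fraction}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_series(path, well_type: str = "") -> FractionSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    return FractionSeries(df["time_h"].to_numpy(), df["fraction"].to_numpy(), well_type)
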