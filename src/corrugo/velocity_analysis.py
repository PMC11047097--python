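"""Gridded velocity fields and velocity-derived statistics.

Coarse-grains per-cell displacements between two snapshots into a regular
grid, estimates the local growth rate as the divergence of the velocity
field (continuity equation with local mass generation), and computes
bottom-distance-stratified profiles of the vertical velocity and the
horizontal velocity fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .well_geometry import WellSpec, bottom_height

__all__ = [
    "VelocityField",
    "field_from_snapshots",
    "growth_rate_field",
    "stratified_profiles",
    "synthetic_field",
]


@dataclass
class VelocityField:
    """Per-bin mean velocities on a regular grid; empty bins are masked."""

    grid_origin: tuple
    grid_spacing: float
    vx: np.ndarray  # (ny, nx)
    vy: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.vx = np.asarray(self.vx, dtype=float)
        self.vy = np.asarray(self.vy, dtype=float)
        self.counts = np.asarray(self.counts)

    @property
    def mask(self) -> np.ndarray:
        return self.counts > 0

    def bin_centers(self):
        ny, nx = self.vx.shape
        x = self.grid_origin[0] + (np.arange(nx) + 0.5) * self.grid_spacing
        y = self.grid_origin[1] + (np.arange(ny) + 0.5) * self.grid_spacing
        return np.meshgrid(x, y)


def field_from_snapshots(s0, s1, spacing: float = 2.0) -> VelocityField:
    """Bin per-cell velocities ``(c1 - c0) / dt`` at the midpoint positions."""
    if not s1.time > s0.time:
        raise ValueError("s1 must be later than s0")
    ids0, i0, i1 = np.intersect1d(s0.ids, s1.ids, return_indices=True)
    if ids0.size == 0:
        raise ValueError("snapshots share no cell ids")
    dt = s1.time - s0.time
    vx = (s1.x[i1] - s0.x[i0]) / dt
    vy = (s1.y[i1] - s0.y[i0]) / dt
    xm = 0.5 * (s0.x[i0] + s1.x[i1])
    ym = 0.5 * (s0.y[i0] + s1.y[i1])
    spec = s0.spec
    nx = max(1, int(math.ceil(spec.width / spacing)))
    ny = max(1, int(math.ceil(spec.height / spacing)))
    ix = np.clip((xm / spacing).astype(int), 0, nx - 1)
    iy = np.clip((ym / spacing).astype(int), 0, ny - 1)
    flat = iy * nx + ix
    counts = np.bincount(flat, minlength=nx * ny).reshape(ny, nx)
    sx = np.bincount(flat, weights=vx, minlength=nx * ny).reshape(ny, nx)
    sy = np.bincount(flat, weights=vy, minlength=nx * ny).reshape(ny, nx)
    with np.errstate(invalid="ignore"):
        mvx = np.where(counts > 0, sx / np.maximum(counts, 1), 0.0)
        mvy = np.where(counts > 0, sy / np.maximum(counts, 1), 0.0)
    return VelocityField((0.0, 0.0), spacing, mvx, mvy, counts)


def growth_rate_field(field: VelocityField) -> np.ma.MaskedArray:
    """Local growth rate ``g = dvx/dx + dvy/dy`` by masked finite differences.

    Central differences where both neighbours along an axis are occupied
    (exact for linear fields), one-sided at occupancy edges, masked where no
    neighbour is available.
    """
    occ = field.mask
    h = field.grid_spacing
    dvx = _masked_derivative(field.vx, occ, axis=1, h=h)
    dvy = _masked_derivative(field.vy, occ, axis=0, h=h)
    g = dvx + dvy
    return np.ma.masked_invalid(np.where(occ, g, np.nan))


def _masked_derivative(v, occ, axis: int, h: float):
    v = np.moveaxis(v, axis, 0)
    occ = np.moveaxis(occ, axis, 0)
    n = v.shape[0]
    out = np.full_like(v, np.nan, dtype=float)
    for i in range(n):
        lo = i - 1
        hi = i + 1
        has_lo = lo >= 0
        has_hi = hi < n
        if has_lo and has_hi:
            both = occ[lo] & occ[hi] & occ[i]
            out[i][both] = (v[hi][both] - v[lo][both]) / (2 * h)
            only_hi = occ[hi] & occ[i] & ~occ[lo]
            out[i][only_hi] = (v[hi][only_hi] - v[i][only_hi]) / h
            only_lo = occ[lo] & occ[i] & ~occ[hi]
            out[i][only_lo] = (v[i][only_lo] - v[lo][only_lo]) / h
        elif has_hi:
            fwd = occ[hi] & occ[i]
            out[i][fwd] = (v[hi][fwd] - v[i][fwd]) / h
        elif has_lo:
            bwd = occ[lo] & occ[i]
            out[i][bwd] = (v[i][bwd] - v[lo][bwd]) / h
    return np.moveaxis(out, 0, axis)


def stratified_profiles(field: VelocityField, spec: WellSpec, n_strata: int = 10,
                        speed_floor_fraction: float = 0.01):
    """Mean vy and mean ``|vx| / |v|`` versus distance from the local bottom.

    Bins are assigned ``d = y_center - h(x_center)``; strata with no
    occupied bin yield NaN.  Bins slower than ``speed_floor_fraction`` of
    the 95th-percentile speed are excluded from the horizontal fraction.
    """
    occ = field.mask
    if not np.any(occ):
        raise ValueError("empty velocity field")
    X, Y = field.bin_centers()
    hb = np.asarray(bottom_height(spec, np.clip(X, 0.0, spec.width)))
    d = (Y - hb)[occ]
    vx = field.vx[occ]
    vy = field.vy[occ]
    speed = np.hypot(vx, vy)
    floor = speed_floor_fraction * np.percentile(speed, 95) if speed.size else 0.0
    edges = np.linspace(0.0, max(d.max(), 1e-9), n_strata + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    vy_mean = np.full(n_strata, np.nan)
    hfrac_mean = np.full(n_strata, np.nan)
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_strata - 1)
    for k in range(n_strata):
        sel = idx == k
        if np.any(sel):
            vy_mean[k] = vy[sel].mean()
            fast = sel & (speed > floor)
            if np.any(fast):
                hfrac_mean[k] = np.mean(np.abs(vx[fast]) / speed[fast])
    return centers, vy_mean, hfrac_mean


def synthetic_field(kind: str, params: dict, spacing: float = 2.0,
                    extent: tuple = (40.0, 40.0), noise_sd: float = 0.0,
                    seed: int = 0) -> VelocityField:
    """Analytic velocity field sampled on a grid (fixture generator).

    Kinds: ``linear_shear`` (v = (0, g0 y)), ``rotation`` (v = (-w y, w x)),
    ``divergent`` (v = (alpha x, beta y)), ``perturbed`` (divergent plus
    Gaussian noise of standard deviation ``sigma``).
    """
    nx = max(1, int(math.ceil(extent[0] / spacing)))
    ny = max(1, int(math.ceil(extent[1] / spacing)))
    x = (np.arange(nx) + 0.5) * spacing
    y = (np.arange(ny) + 0.5) * spacing
    X, Y = np.meshgrid(x, y)
    if kind == "linear_shear":
        vx = np.zeros_like(X)
        vy = params.get("g0", 0.3) * Y
    elif kind == "rotation":
        w = params.get("omega", 1.0)
        vx = -w * Y
        vy = w * X
    elif kind in ("divergent", "perturbed"):
        vx = params.get("alpha", 0.1) * X
        vy = params.get("beta", 0.2) * Y
    else:
        raise ValueError(f"unknown synthetic field kind {kind!r}")
    sd = params.get("sigma", noise_sd) if kind == "perturbed" else noise_sd
    if sd < 0:
        raise ValueError("noise sd must be nonnegative")
    if sd > 0:
        rng = np.random.default_rng(seed)
        vx = vx + rng.normal(0.0, sd, vx.shape)
        vy = vy + rng.normal(0.0, sd, vy.shape)
    counts = np.ones((ny, nx), dtype=int)
    return VelocityField((0.0, 0.0), spacing, vx, vy, counts)
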