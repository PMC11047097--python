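"""Well domain geometry.

A well is a 2D rectangular domain, open at the top, whose bottom surface is
either flat or carries a sinusoidal corrugation.  The profile is

    h(x) = (A / 2) * (1 - cos(2 pi x / T))

so grooves (minima, ``h = 0``) sit at ``x = k T`` and ridges (maxima,
``h = A``) at ``x = (k + 1/2) T``.  With this phase convention side walls
abut half-grooves whenever ``T`` divides the width, and the number of
groove-centred pockets is ``width / T + 1``.

Coordinates: origin at the bottom-left groove level, ``y`` increasing toward
the open top.  All lengths are in micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "WellSpec",
    "WallContact",
    "bottom_height",
    "bottom_slope",
    "wall_contact",
    "pocket_index",
    "n_pockets",
]


@dataclass(frozen=True)
class WellSpec:
    """Geometry of one microwell (2D; ``depth_z`` is metadata only)."""

    width: float = 100.0
    height: float = 100.0
    period_T: float = math.inf
    amplitude_A: float = 0.0
    depth_Z: float = 7.0

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError(f"width must be > 0, got {self.width}")
        if not self.height > 0:
            raise ValueError(f"height must be > 0, got {self.height}")
        if self.amplitude_A < 0:
            raise ValueError(f"amplitude_A must be >= 0, got {self.amplitude_A}")
        if self.amplitude_A > 0 and not self.period_T > 0:
            raise ValueError("period_T must be > 0 for a corrugated well")
        if self.amplitude_A >= self.height:
            raise ValueError("amplitude_A must be smaller than the well height")

    @property
    def flat(self) -> bool:
        return self.amplitude_A == 0.0

    @classmethod
    def corrugated(
        cls, period_T: float, amplitude_A: float, width: float = 100.0, height: float = 100.0
    ) -> "WellSpec":
        return cls(width=width, height=height, period_T=period_T, amplitude_A=amplitude_A)

    @classmethod
    def flat_bottom(cls, width: float = 100.0, height: float = 100.0) -> "WellSpec":
        return cls(width=width, height=height, period_T=math.inf, amplitude_A=0.0)


class WallContact(NamedTuple):
    """Signed distance (negative = penetrating) and outward normal of the nearest wall."""

    distance: float
    normal: np.ndarray
    wall_id: str


def _check_x(spec: WellSpec, x, tol: float = 1e-9) -> None:
    x = np.asarray(x, dtype=float)
    if np.any(x < -tol) or np.any(x > spec.width + tol):
        raise ValueError(f"x={x} outside the well [0, {spec.width}]")


def bottom_height(spec: WellSpec, x):
    """Height of the bottom surface above y=0 at lateral position ``x``."""
    _check_x(spec, x)
    if spec.flat:
        return np.zeros_like(np.asarray(x, dtype=float)) if np.ndim(x) else 0.0
    return 0.5 * spec.amplitude_A * (1.0 - np.cos(2.0 * np.pi * np.asarray(x, float) / spec.period_T))


def bottom_slope(spec: WellSpec, x):
    """dh/dx of the bottom profile."""
    _check_x(spec, x)
    if spec.flat:
        return np.zeros_like(np.asarray(x, dtype=float)) if np.ndim(x) else 0.0
    w = 2.0 * np.pi / spec.period_T
    return 0.5 * spec.amplitude_A * w * np.sin(w * np.asarray(x, float))


def _nearest_bottom_point(spec: WellSpec, px: float, py: float) -> tuple[float, float]:
    """Abscissa and signed distance of the nearest point on the bottom curve.

    Global coarse sampling followed by bounded 1D minimisation (tolerance
    well below 1e-6 um).  The sign is taken along the outward normal of the
    curve at the nearest point, so slight penetrations come out negative.
    """
    if spec.flat:
        return px, py
    n_coarse = max(64, int(40 * spec.width / spec.period_T))
    us = np.linspace(0.0, spec.width, n_coarse)
    hs = 0.5 * spec.amplitude_A * (1.0 - np.cos(2.0 * np.pi * us / spec.period_T))
    d2 = (us - px) ** 2 + (hs - py) ** 2
    i = int(np.argmin(d2))
    lo = us[max(i - 1, 0)]
    hi = us[min(i + 1, n_coarse - 1)]

    def d2_of(u: float) -> float:
        h = 0.5 * spec.amplitude_A * (1.0 - math.cos(2.0 * math.pi * u / spec.period_T))
        return (u - px) ** 2 + (h - py) ** 2

    if hi > lo:
        res = minimize_scalar(d2_of, bounds=(lo, hi), method="bounded", options={"xatol": 1e-9})
        u = float(res.x)
    else:
        u = lo
    h = 0.5 * spec.amplitude_A * (1.0 - math.cos(2.0 * math.pi * u / spec.period_T))
    hp = 0.5 * spec.amplitude_A * (2.0 * math.pi / spec.period_T) * math.sin(2.0 * math.pi * u / spec.period_T)
    nn = math.hypot(hp, 1.0)
    nx, ny = -hp / nn, 1.0 / nn
    signed = (px - u) * nx + (py - h) * ny
    return u, signed


def wall_contact(spec: WellSpec, point) -> WallContact:
    """Nearest wall surface (bottom, left or right) for a point in the well.

    Returns the signed distance (negative when penetrating), the outward
    unit normal at the nearest surface point, and the wall identifier.  At
    corners the nearer wall is reported.
    """
    px, py = float(point[0]), float(point[1])
    if spec.flat:
        d_bot = py
        n_bot = np.array([0.0, 1.0])
    else:
        u, d_bot = _nearest_bottom_point(spec, px, py)
        hp = float(bottom_slope(spec, min(max(u, 0.0), spec.width)))
        nn = math.hypot(hp, 1.0)
        n_bot = np.array([-hp / nn, 1.0 / nn])
    candidates = [
        WallContact(d_bot, n_bot, "bottom"),
        WallContact(px, np.array([1.0, 0.0]), "left"),
        WallContact(spec.width - px, np.array([-1.0, 0.0]), "right"),
    ]
    return min(candidates, key=lambda c: abs(c.distance))


def n_pockets(spec: WellSpec) -> int:
    """Number of groove-centred pockets; floor-consistent with (T + width) / T."""
    if spec.flat:
        raise ValueError("a flat well has no pockets")
    return int(math.floor(spec.width / spec.period_T + 1e-9)) + 1

def pocket_index(spec: WellSpec, x: float) -> int:
    """Index of the pocket containing ``x``; pockets are intervals between ridges."""
    if spec.flat:
        raise ValueError("a flat well has no pockets")
    _check_x(spec, x)
    k = int(math.floor(x / spec.period_T + 0.5))
    return min(max(k, 0), n_pockets(spec) - 1)
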