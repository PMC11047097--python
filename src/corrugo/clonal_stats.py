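"""Population-genetic summary statistics on simulation snapshots or transects.

Implements the clone census, near-bottom transect sampling, sector-boundary
densities, mean sector size, the two-strain mixing statistic
``H = f1 f2 / (f1 + f2)`` (0.25 = perfectly mixed, 0 = monoclonal), founder
survival densities and the pocket-count theory line ``N = (T + width) / T``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np

from .well_geometry import WellSpec, bottom_height

UNOCCUPIED = -1

__all__ = [
    "SectorProfile",
    "CloneCensus",
    "census",
    "transect",
    "boundary_positions",
    "boundary_density",
    "mean_sector_size",
    "heterozygosity",
    "intensity_to_freqs",
    "founder_survival_density",
    "theory_clone_count",
]


@dataclass
class SectorProfile:
    """1D transect: genotype labels and/or two-strain frequencies per position."""

    positions: np.ndarray
    labels: Optional[np.ndarray] = None      # int, UNOCCUPIED where empty
    f1: Optional[np.ndarray] = None
    f2: Optional[np.ndarray] = None
    width: Optional[float] = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.width is None:
            self.width = float(self.positions[-1] - self.positions[0])
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
        for name in ("f1", "f2"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if np.any((v < -1e-12) | (v > 1 + 1e-12)):
                    raise ValueError(f"{name} must lie in [0, 1]")
                setattr(self, name, v)

    @property
    def occupied(self) -> np.ndarray:
        if self.labels is not None:
            return self.labels != UNOCCUPIED
        return (self.f1 + self.f2) > 0


@dataclass
class CloneCensus:
    time: float
    clone_sizes: dict
    n_clones: int = field(init=False)
    fractions: dict = field(init=False)

    def __post_init__(self):
        self.clone_sizes = {g: c for g, c in self.clone_sizes.items() if c > 0}
        self.n_clones = len(self.clone_sizes)
        total = sum(self.clone_sizes.values())
        # exact rational fractions so they sum to 1 exactly
        self.fractions = {g: Fraction(c, total) for g, c in self.clone_sizes.items()}

    @property
    def mean_fraction(self) -> float:
        return float(np.mean([float(f) for f in self.fractions.values()]))


def census(state) -> CloneCensus:
    """Count cells per genotype in one snapshot."""
    if state.n == 0:
        raise ValueError("empty population")
    genos, counts = np.unique(state.genotype, return_counts=True)
    return CloneCensus(time=state.time,
                       clone_sizes={int(g): int(c) for g, c in zip(genos, counts)})


def transect(state, spec: Optional[WellSpec] = None, offset: float = 2.0,
             spacing: float = 0.5) -> SectorProfile:
    """Sample genotypes along the line ``y = h(x) + offset`` near the bottom.

    Each sample point takes the genotype of the nearest overlapping cell
    (point within one radius of the cell's centreline); unoccupied points
    are flagged.
    """
    spec = spec if spec is not None else state.spec
    rmax = float(np.max(state.radius)) if state.n else 0.0
    if offset <= rmax:
        raise ValueError("offset must exceed the maximum cell radius")
    xs = np.arange(0.0, spec.width + 0.5 * spacing, spacing)
    xs[-1] = min(xs[-1], spec.width)
    ys = np.asarray(bottom_height(spec, xs)) + offset
    labels = np.full(xs.shape, UNOCCUPIED, dtype=np.int64)
    strains = np.full(xs.shape, -1, dtype=np.int64)
    if state.n:
        ex = np.cos(state.angle)
        ey = np.sin(state.angle)
        hl = 0.5 * state.length
        ax = state.x - hl * ex
        ay = state.y - hl * ey
        # point-segment distance, vectorised over (samples, cells)
        dx = xs[:, None] - ax[None, :]
        dy = ys[:, None] - ay[None, :]
        t = (dx * (2 * hl * ex)[None, :] + dy * (2 * hl * ey)[None, :]) / (
            (2 * hl) ** 2
        )[None, :]
        t = np.clip(t, 0.0, 1.0)
        cx = ax[None, :] + t * (2 * hl * ex)[None, :]
        cy = ay[None, :] + t * (2 * hl * ey)[None, :]
        d = np.hypot(xs[:, None] - cx, ys[:, None] - cy)
        nearest = np.argmin(d, axis=1)
        dmin = d[np.arange(xs.size), nearest]
        hit = dmin <= state.radius[nearest]
        labels[hit] = state.genotype[nearest[hit]]
        strains[hit] = state.strain[nearest[hit]]
    prof = SectorProfile(positions=xs, labels=labels, width=spec.width)
    prof.strains = strains
    return prof


def boundary_positions(profile: SectorProfile) -> np.ndarray:
    """Midpoints between adjacent occupied samples with differing labels."""
    if profile.labels is None:
        raise ValueError("profile has no labels")
    occ = np.nonzero(profile.occupied)[0]
    if occ.size < 2:
        return np.array([])
    lab = profile.labels[occ]
    pos = profile.positions[occ]
    change = lab[1:] != lab[:-1]
    return 0.5 * (pos[1:][change] + pos[:-1][change])


def boundary_density(profiles: Sequence[SectorProfile], n_bins: int = 50):
    """Histogram density of sector-boundary positions over normalized x in [0, 1].

    Returns ``(bin_edges, density, n_boundaries)``; an ensemble without any
    boundary yields a zero density flagged by ``n_boundaries == 0``.
    """
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    all_pos = []
    for p in profiles:
        if p.width is None or p.width <= 0:
            raise ValueError("profiles must carry a positive width")
        all_pos.append(boundary_positions(p) / p.width)
    pos = np.concatenate(all_pos) if all_pos else np.array([])
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    if pos.size == 0:
        return edges, np.zeros(n_bins), 0
    dens, _ = np.histogram(pos, bins=edges, density=True)
    return edges, dens, int(pos.size)


def mean_sector_size(profile: SectorProfile, min_run: int = 1) -> float:
    """Mean run length of constant genotype, as a fraction of the well width."""
    if profile.labels is None:
        raise ValueError("profile has no labels")
    occ = np.nonzero(profile.occupied)[0]
    if occ.size == 0:
        raise ValueError("profile fully unoccupied")
    lab = profile.labels[occ]
    pos = profile.positions[occ]
    # split runs at label changes and at occupancy gaps
    gaps = np.nonzero((lab[1:] != lab[:-1]) | (np.diff(occ) > 1))[0]
    starts = np.concatenate([[0], gaps + 1])
    ends = np.concatenate([gaps, [occ.size - 1]])
    lengths = pos[ends] - pos[starts]
    keep = (ends - starts + 1) >= min_run
    if not np.any(keep):
        raise ValueError("no runs of the requested minimum length")
    # a run of one sample still covers about one sample spacing
    spacing = np.median(np.diff(profile.positions))
    lengths = lengths[keep] + spacing
    return float(np.mean(lengths) / profile.width)


def heterozygosity(profile: SectorProfile, check: bool = True) -> float:
    """Mean of ``H(x) = f1 f2 / (f1 + f2)`` over occupied positions.

    With frequencies normalised to ``f1 + f2 = 1`` this equals the mean of
    ``f1 * f2``; both code paths are evaluated and asserted equal when
    ``check`` is set.
    """
    if profile.f1 is None or profile.f2 is None:
        raise ValueError("profile has no strain frequencies")
    f1, f2 = profile.f1, profile.f2
    tot = f1 + f2
    occ = tot > 0
    if not np.any(occ):
        raise ValueError("profile fully unoccupied")
    h_literal = float(np.mean(f1[occ] * f2[occ] / tot[occ]))
    if check and np.allclose(tot[occ], 1.0):
        h_product = float(np.mean(f1[occ] * f2[occ]))
        assert math.isclose(h_literal, h_product, rel_tol=1e-12, abs_tol=1e-12)
    return h_literal


def intensity_to_freqs(I1, I2, floor_fraction: float = 0.05):
    """Two-channel intensities to per-position strain frequencies.

    ``f_i = I_i / (I1 + I2)``; positions whose summed intensity falls below
    ``floor_fraction`` of the profile's maximum are flagged unoccupied
    (frequencies set to 0).
    """
    I1 = np.asarray(I1, dtype=float)
    I2 = np.asarray(I2, dtype=float)
    if np.any(I1 < 0) or np.any(I2 < 0):
        raise ValueError("intensities must be nonnegative")
    tot = I1 + I2
    floor = floor_fraction * (tot.max() if tot.size else 0.0)
    occ = tot > max(floor, 0.0)
    f1 = np.zeros_like(tot)
    f2 = np.zeros_like(tot)
    f1[occ] = I1[occ] / tot[occ]
    f2[occ] = I2[occ] / tot[occ]
    return f1, f2


def founder_survival_density(snapshots, t0: float, t_end: float, n_bins: int = 20):
    """Density over initial height-above-bottom of cells whose progeny survive.

    Every cell alive at ``t0`` is re-tagged as its own lineage ancestor; a
    lineage survives if any cell at ``t_end`` descends from it (via the
    shared genealogy).  Returns ``(bin_edges, density, d_t0, d_survivors)``
    with the density normalised to integrate to 1.
    """
    s0 = _closest_snapshot(snapshots, t0)
    s1 = _closest_snapshot(snapshots, t_end)
    parent = s1.parent_of
    t0_ids = set(int(i) for i in s0.ids)
    survivors: set[int] = set()
    for cid in s1.ids:
        cur = int(cid)
        while cur not in t0_ids and cur >= 0:
            cur = parent[cur] if cur < len(parent) else -1
        if cur >= 0:
            survivors.add(cur)
    if not survivors:
        raise ValueError("no lineage from t0 survives to t_end")
    d_t0 = s0.heights_above_bottom()
    surv_mask = np.array([int(i) in survivors for i in s0.ids])
    d_surv = d_t0[surv_mask]
    edges = np.linspace(0.0, max(d_t0.max(), 1e-9), n_bins + 1)
    dens, _ = np.histogram(d_surv, bins=edges, density=True)
    return edges, dens, d_t0, d_surv


def _closest_snapshot(snapshots, t: float):
    return min(snapshots, key=lambda s: abs(s.time - t))


def theory_clone_count(spec: WellSpec):
    """Theory line: expected clone count ``(T + width) / T`` and its reciprocal."""
    if spec.flat:
        raise ValueError("theory applies to corrugated wells only")
    n = (spec.period_T + spec.width) / spec.period_T
    return n, 1.0 / n
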