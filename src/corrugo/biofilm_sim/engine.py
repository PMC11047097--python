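"""Agent-based biofilm engine: initialization, forces, stepping, runs.

Dynamics are overdamped: ``v = F / (gamma * extent)`` and
``omega = tau / (gamma_rot * extent^3)``.  The default desk profile caps the
per-step displacement at ``cap_fraction * radius`` (saturated gradient
descent), which keeps stiff contacts bounded while calm regions move at
their physical velocity; with the cap disabled the engine aborts when a
step would exceed ``abort_fraction * radius``.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Optional

import numpy as np

from ..well_geometry import WellSpec, bottom_height
from . import mechanics
from .mechanics import NWALLS
from .state import STRAIN_CODE, STRAINS, Cell, PhysicsParams, SimState

logger = logging.getLogger("corrugo.sim")

__all__ = [
    "StabilityError",
    "initialize",
    "pair_repulsion",
    "wall_forces",
    "adhesion_forces",
    "grow_and_divide",
    "step",
    "advance",
    "run",
]


class StabilityError(RuntimeError):
    """Raised when a step would move a cell too far; reduce dt or soften stiffness."""


# ----------------------------------------------------------------------
# initialization
# ----------------------------------------------------------------------

def initialize(
    spec: WellSpec,
    params: PhysicsParams,
    n_cells: int,
    strain_mix: Optional[dict] = None,
    seed: int = 0,
    max_tries_per_cell: int = 500,
    relax_steps: int = 100,
) -> SimState:
    """Place ``n_cells`` non-overlapping cells uniformly at random in the well.

    Each cell receives a unique genotype and founder id; strains are drawn
    from ``strain_mix`` (fractions summing to 1).  If rejection sampling
    fails, remaining cells are placed with overlaps and the state is relaxed
    mechanically with growth off.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if strain_mix is None:
        strain_mix = {"neutralA": 1.0}
    fracs = np.array(list(strain_mix.values()), dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("strain fractions must sum to 1")
    for name in strain_mix:
        if name not in STRAIN_CODE:
            raise ValueError(f"unknown strain {name!r}; expected one of {STRAINS}")

    rng = np.random.default_rng(seed)
    state = SimState(spec, params, rng)
    r = params.radius
    xs, ys, angs, lens = [], [], [], []
    needs_relax = False
    for _ in range(n_cells):
        placed = False
        for _try in range(max_tries_per_cell):
            ang = rng.uniform(0.0, 2.0 * math.pi)
            ln = rng.uniform(params.l_min, params.l_div)
            hx = 0.5 * ln * math.cos(ang)
            hy = 0.5 * ln * math.sin(ang)
            margin = r + max(abs(hx), 0.0)
            cx = rng.uniform(margin, spec.width - margin)
            cy = rng.uniform(r + abs(hy), spec.height - r - abs(hy))
            ok = _clear_of_walls(spec, cx, cy, hx, hy, r)
            if not ok:
                continue
            for j in range(len(xs)):
                _, _, _, _, _, _, dist = mechanics.segment_closest(
                    cx - hx, cy - hy, 2 * hx, 2 * hy,
                    xs[j] - 0.5 * lens[j] * math.cos(angs[j]),
                    ys[j] - 0.5 * lens[j] * math.sin(angs[j]),
                    lens[j] * math.cos(angs[j]),
                    lens[j] * math.sin(angs[j]),
                )
                if dist < 1.9 * r:
                    ok = False
                    break
            if ok:
                xs.append(cx); ys.append(cy); angs.append(ang); lens.append(ln)
                placed = True
                break
        if not placed:
            if len(xs) + 1 > 0.8 * _capacity_estimate(spec, params):
                raise RuntimeError(
                    f"could not place {n_cells} non-overlapping cells in the well"
                )
            # fallback: place with overlap, relax afterwards
            ang = rng.uniform(0.0, 2.0 * math.pi)
            ln = rng.uniform(params.l_min, params.l_div)
            cx = rng.uniform(r, spec.width - r)
            floor_y = bottom_height(spec, cx)
            cy = rng.uniform(floor_y + r, spec.height - r)
            xs.append(cx); ys.append(cy); angs.append(ang); lens.append(ln)
            needs_relax = True

    n = len(xs)
    state.x = np.array(xs)
    state.y = np.array(ys)
    state.angle = np.array(angs)
    state.length = np.array(lens)
    state.radius = np.full(n, r)
    lth = params.l_div * (1.0 + rng.uniform(
        -params.division_length_noise, params.division_length_noise, n))
    # no cell may start at or beyond its own division threshold
    state.lth = np.maximum(lth, state.length * (1.0 + 1e-9))
    state.ids = np.arange(n, dtype=np.int64)
    state.founder = np.arange(n, dtype=np.int64)
    state.genotype = np.arange(n, dtype=np.int64)
    codes = np.array([STRAIN_CODE[s] for s in strain_mix], dtype=np.int8)
    state.strain = rng.choice(codes, size=n, p=fracs).astype(np.int8)
    state.sp_active = np.zeros((n, NWALLS), dtype=np.bool_)
    state.sp_ax = np.zeros((n, NWALLS))
    state.sp_ay = np.zeros((n, NWALLS))
    state.sp_rest = np.zeros((n, NWALLS))
    state.sp_frac = np.zeros((n, NWALLS))
    state.next_id = n
    state.parent_of = [-1] * n
    if needs_relax:
        saved = params.elongation_rate
        params.elongation_rate = 0.0
        try:
            for _ in range(relax_steps):
                step(state)
            state.time = 0.0
        finally:
            params.elongation_rate = saved
    return state


def _clear_of_walls(spec: WellSpec, cx: float, cy: float, hx: float, hy: float,
                    r: float, slack: float = 1.05) -> bool:
    """True if the three sample points of a candidate cell clear every wall."""
    for f in (-1.0, 0.0, 1.0):
        sx, sy = cx + f * hx, cy + f * hy
        if sx < r * slack or spec.width - sx < r * slack:
            return False
        if spec.flat:
            d = sy
        else:
            if sy - spec.amplitude_A > r * slack:
                continue
            _, _, d, _, _ = mechanics._nearest_bottom(
                sx, sy, spec.amplitude_A, spec.period_T, spec.width
            )
        if d < r * slack:
            return False
    return True


def _capacity_estimate(spec: WellSpec, params: PhysicsParams) -> float:
    open_area = spec.width * spec.height - 0.5 * spec.amplitude_A * spec.width
    mean_cell_area = 2 * params.radius * 0.5 * (params.l_min + params.l_div)
    return open_area / mean_cell_area


# ----------------------------------------------------------------------
# single-cell / single-pair force API (wraps the kernels)
# ----------------------------------------------------------------------

def _cell_arrays(cells: Iterable[Cell]):
    cl = list(cells)
    px = np.array([c.center[0] for c in cl])
    py = np.array([c.center[1] for c in cl])
    ex = np.cos([c.angle for c in cl])
    ey = np.sin([c.angle for c in cl])
    hl = np.array([0.5 * c.length for c in cl])
    rad = np.array([c.radius for c in cl])
    ids = np.array([c.id for c in cl], dtype=np.int64)
    return px, py, ex, ey, hl, rad, ids


def pair_repulsion(cellA: Cell, cellB: Cell, k_cell: float):
    """Hertzian-like contact between two spherocylinders.

    Returns (forceA, forceB, torqueA, torqueB); forces are exactly
    antisymmetric, torques are taken about each cell's center.
    """
    px, py, ex, ey, hl, rad, ids = _cell_arrays([cellA, cellB])
    fx = np.zeros(2)
    fy = np.zeros(2)
    tq = np.zeros(2)
    cs = float(2 * (hl.max() + rad.max()) + 1.0)
    head = np.full(1, -1, dtype=np.int64)
    nxt = np.full(2, -1, dtype=np.int64)
    # shift into a single grid bin so the kernel sees both cells
    ox, oy = px.min() - 0.1, py.min() - 0.1
    mechanics.build_grid(px - ox, py - oy, cs, 1, 1, head, nxt)
    mechanics.pair_forces(px - ox, py - oy, ex, ey, hl, rad, ids, k_cell,
                          cs, 1, 1, head, nxt, fx, fy, tq)
    return (np.array([fx[0], fy[0]]), np.array([fx[1], fy[1]]), tq[0], tq[1])


def _wall_kernel_single(cell: Cell, spec: WellSpec, k_wall: float,
                        adh_on: bool = False, k_adh: float = 0.0,
                        eps_max: float = 0.0, springs=None, n_samples: int = 3):
    px, py, ex, ey, hl, rad, _ = _cell_arrays([cell])
    fx = np.zeros(1)
    fy = np.zeros(1)
    tq = np.zeros(1)
    if springs is None:
        sp_active = np.zeros((1, NWALLS), dtype=np.bool_)
        sp_ax = np.zeros((1, NWALLS))
        sp_ay = np.zeros((1, NWALLS))
        sp_rest = np.zeros((1, NWALLS))
        sp_frac = np.zeros((1, NWALLS))
    else:
        sp_active, sp_ax, sp_ay, sp_rest, sp_frac = springs
    T = spec.period_T if not spec.flat else 1.0
    mechanics.wall_adhesion_forces(
        px, py, ex, ey, hl, rad,
        spec.amplitude_A, T, spec.width, spec.flat,
        k_wall, adh_on, k_adh, eps_max,
        sp_active, sp_ax, sp_ay, sp_rest, sp_frac,
        fx, fy, tq, n_samples,
    )
    return (np.array([fx[0], fy[0]]), tq[0],
            (sp_active, sp_ax, sp_ay, sp_rest, sp_frac))


def wall_forces(cell: Cell, spec: WellSpec, k_wall: float, n_samples: int = 3):
    """Linear wall repulsion sampled at ``n_samples`` centreline points."""
    force, torque, _ = _wall_kernel_single(cell, spec, k_wall, n_samples=n_samples)
    return force, torque


def adhesion_forces(cell: Cell, spec: WellSpec, params: PhysicsParams, springs=None):
    """Adhesion-spring force/torque for one cell; returns updated spring arrays."""
    if params.k_adhesion <= 0:
        raise ValueError("adhesion disabled (stiffness <= 0)")
    force, torque, springs = _wall_kernel_single(
        cell, spec, 0.0, True, params.k_adhesion, params.epsilon_max, springs
    )
    return force, torque, springs


# ----------------------------------------------------------------------
# stepping
# ----------------------------------------------------------------------

def _compute_forces(state: SimState):
    spec = state.spec
    p = state.params
    n = state.n
    fx = np.zeros(n)
    fy = np.zeros(n)
    tq = np.zeros(n)
    ex = np.cos(state.angle)
    ey = np.sin(state.angle)
    hl = 0.5 * state.length
    cs = p.l_div + 2.0 * p.radius + 1.0
    nxg = max(1, int(math.ceil(spec.width / cs)))
    nyg = max(1, int(math.ceil((spec.height + 4.0) / cs)))
    head = np.full(nxg * nyg, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    mechanics.build_grid(state.x, state.y, cs, nxg, nyg, head, nxt)
    e_pair = mechanics.pair_forces(
        state.x, state.y, ex, ey, hl, state.radius, state.ids,
        p.k_cell, cs, nxg, nyg, head, nxt, fx, fy, tq,
    )
    T = spec.period_T if not spec.flat else 1.0
    e_wall, max_pen = mechanics.wall_adhesion_forces(
        state.x, state.y, ex, ey, hl, state.radius,
        spec.amplitude_A, T, spec.width, spec.flat,
        p.k_wall, p.adhesion_enabled, p.k_adhesion, p.epsilon_max,
        state.sp_active, state.sp_ax, state.sp_ay, state.sp_rest, state.sp_frac,
        fx, fy, tq, p.n_wall_samples,
    )
    return fx, fy, tq, e_pair + e_wall, max_pen


def elastic_energy(state: SimState) -> float:
    """Total elastic energy (Hertzian contacts + wall springs + adhesion)."""
    saved = (state.sp_active.copy(), state.sp_ax.copy(), state.sp_ay.copy(),
             state.sp_rest.copy(), state.sp_frac.copy())
    _, _, _, energy, _ = _compute_forces(state)
    (state.sp_active, state.sp_ax, state.sp_ay,
     state.sp_rest, state.sp_frac) = saved
    return energy


def grow_and_divide(state: SimState, dt: float) -> None:
    """Exponential centreline elongation and symmetric division at ``l_div``.

    Division conserves the total spherocylinder extent: daughters' caps
    touch at the split point (no overlap, nothing moves at division), each
    daughter keeps the genotype, founder and strain and gets a fresh id.
    """
    p = state.params
    if p.elongation_rate > 0.0:
        mult = state.multiplier_array()
        state.length = state.length * np.exp(mult * p.elongation_rate * dt)
    _divide_ready(state)


def _divide_ready(state: SimState) -> None:
    """Split every cell whose centreline has reached ``l_div``."""
    p = state.params
    div = np.nonzero(state.length >= state.lth)[0]
    if div.size == 0:
        return
    r = p.radius
    L = state.length[div]
    ld = 0.5 * (L - 2.0 * r)
    off = 0.25 * L + 0.5 * r
    ex = np.cos(state.angle[div])
    ey = np.sin(state.angle[div])
    noise = state.rng.uniform(-p.division_angle_noise, p.division_angle_noise,
                              size=(div.size, 2))
    n_new = div.size
    ids_a = np.arange(state.next_id, state.next_id + n_new, dtype=np.int64)
    ids_b = np.arange(state.next_id + n_new, state.next_id + 2 * n_new, dtype=np.int64)
    state.next_id += 2 * n_new
    for k, parent_idx in enumerate(div):
        pid = int(state.ids[parent_idx])
        state.parent_of.append(pid)  # ids_a[k]
    for k, parent_idx in enumerate(div):
        pid = int(state.ids[parent_idx])
        state.parent_of.append(pid)  # ids_b[k]

    # daughter A replaces the parent row; daughter B is appended
    xb = state.x[div] - off * ex
    yb = state.y[div] - off * ey
    state.x[div] = state.x[div] + off * ex
    state.y[div] = state.y[div] + off * ey
    state.angle[div] = state.angle[div] + noise[:, 0]
    state.length[div] = ld
    state.lth[div] = p.l_div * (1.0 + state.rng.uniform(
        -p.division_length_noise, p.division_length_noise, div.size))
    state.ids[div] = ids_a
    state.sp_active[div, :] = False

    state.x = np.concatenate([state.x, xb])
    state.y = np.concatenate([state.y, yb])
    state.angle = np.concatenate([state.angle, state.angle[div] - noise[:, 0] + noise[:, 1]])
    state.length = np.concatenate([state.length, ld])
    state.lth = np.concatenate([state.lth, p.l_div * (1.0 + state.rng.uniform(
        -p.division_length_noise, p.division_length_noise, n_new))])
    state.radius = np.concatenate([state.radius, np.full(n_new, r)])
    state.ids = np.concatenate([state.ids, ids_b])
    state.founder = np.concatenate([state.founder, state.founder[div]])
    state.genotype = np.concatenate([state.genotype, state.genotype[div]])
    state.strain = np.concatenate([state.strain, state.strain[div]])
    state.sp_active = np.concatenate(
        [state.sp_active, np.zeros((n_new, NWALLS), dtype=np.bool_)]
    )
    for name in ("sp_ax", "sp_ay", "sp_rest", "sp_frac"):
        arr = getattr(state, name)
        setattr(state, name, np.concatenate([arr, np.zeros((n_new, NWALLS))]))


def _remove_escaped(state: SimState) -> None:
    gone = state.y > state.spec.height
    if not np.any(gone):
        return
    state.removed_count += int(np.count_nonzero(gone))
    state.removed_area += float(
        np.sum(2 * state.radius[gone] * state.length[gone]
               + math.pi * state.radius[gone] ** 2)
    )
    keep = ~gone
    for name in ("ids", "founder", "genotype", "strain", "x", "y", "angle",
                 "length", "radius", "lth", "sp_active", "sp_ax", "sp_ay",
                 "sp_rest", "sp_frac"):
        setattr(state, name, getattr(state, name)[keep])


def step(state: SimState, multipliers: Optional[dict] = None) -> SimState:
    """One overdamped time step (forces, motion, growth/division, removal)."""
    p = state.params
    if multipliers is not None:
        state.strain_multipliers = multipliers
    if state.n == 0:
        state.time += p.dt
        return state
    fx, fy, tq, energy, max_pen = _compute_forces(state)
    ext = state.length + 2.0 * state.radius
    vx = fx / (p.gamma * ext)
    vy = fy / (p.gamma * ext)
    om = tq / (p.gamma_rot * ext**3)
    disp = np.hypot(vx, vy) * p.dt + np.abs(om) * p.dt * 0.5 * ext
    if p.cap_fraction is not None:
        cap = p.cap_fraction * state.radius
        scale = np.minimum(1.0, cap / np.maximum(disp, 1e-300))
    else:
        if np.any(disp > p.abort_fraction * state.radius):
            raise StabilityError(
                f"per-step displacement {disp.max():.3g} um exceeds "
                f"{p.abort_fraction} * radius; reduce dt or soften stiffnesses"
            )
        scale = np.ones_like(disp)
    state.x += vx * p.dt * scale
    state.y += vy * p.dt * scale
    state.angle += om * p.dt * scale
    state.elastic_energy = energy
    state.max_wall_penetration = max(state.max_wall_penetration, max_pen)
    grow_and_divide(state, p.dt)
    _remove_escaped(state)
    state.time += p.dt
    return state


def _advance_steps(state: SimState, n_steps: int,
                   multipliers: Optional[dict] = None) -> None:
    """Advance ``n_steps`` with fixed multipliers using the compiled driver.

    Semantically identical to ``n_steps`` calls of :func:`step`: the chunk
    ends whenever a division or removal is due, which is then handled in
    Python before re-entering the kernel.
    """
    p = state.params
    spec = state.spec
    if multipliers is not None:
        state.strain_multipliers = multipliers
    remaining = n_steps
    while remaining > 0:
        if state.n == 0:
            state.time += remaining * p.dt
            return
        n = state.n
        gf = np.exp(state.multiplier_array() * p.elongation_rate * p.dt)
        cs = p.l_div + 2.0 * p.radius + 1.0
        nxg = max(1, int(math.ceil(spec.width / cs)))
        nyg = max(1, int(math.ceil((spec.height + 4.0) / cs)))
        head = np.full(nxg * nyg, -1, dtype=np.int64)
        nxt = np.full(n, -1, dtype=np.int64)
        fx = np.zeros(n)
        fy = np.zeros(n)
        tq = np.zeros(n)
        T = spec.period_T if not spec.flat else 1.0
        done, energy, max_pen, status = mechanics.multi_step(
            state.x, state.y, state.angle, state.length, state.radius,
            state.ids, gf,
            p.k_cell, p.k_wall, spec.amplitude_A, T, spec.width, spec.flat,
            p.adhesion_enabled, p.k_adhesion, p.epsilon_max,
            state.sp_active, state.sp_ax, state.sp_ay, state.sp_rest,
            state.sp_frac,
            p.gamma, p.gamma_rot, p.dt,
            p.cap_fraction if p.cap_fraction is not None else 0.0,
            p.cap_fraction is not None, p.abort_fraction,
            state.lth, spec.height, cs, nxg, nyg, head, nxt, fx, fy, tq,
            p.n_wall_samples, remaining,
        )
        state.time += done * p.dt
        state.elastic_energy = energy
        state.max_wall_penetration = max(state.max_wall_penetration, max_pen)
        if status == 4:
            raise StabilityError(
                "per-step displacement exceeds the abort bound; "
                "reduce dt or soften stiffnesses"
            )
        if status & 1:
            _divide_ready(state)
        if status & 2:
            _remove_escaped(state)
        remaining -= done


def advance(state: SimState, duration: float, protocol=None) -> SimState:
    """Step ``state`` in place for ``duration`` hours."""
    n_steps = max(1, int(round(duration / state.params.dt)))
    done = 0
    while done < n_steps:
        mult = _multipliers_at(protocol, state.time)
        chunk = n_steps - done
        if protocol is not None and not isinstance(protocol, dict):
            chunk = min(chunk, _steps_to_phase_change(protocol, state.time,
                                                      state.params.dt, chunk))
        _advance_steps(state, chunk, mult)
        done += chunk
    return state


def _steps_to_phase_change(protocol, t: float, dt: float, default: int) -> int:
    upcoming = [ts for ts, _ in protocol.phases if ts > t + 0.5 * dt]
    if not upcoming:
        return default
    return max(1, min(default, int(round((upcoming[0] - t) / dt))))


def _multipliers_at(protocol, t: float) -> Optional[dict]:
    if protocol is None:
        return None
    if isinstance(protocol, dict):
        return protocol
    return protocol.multipliers_at(t)


def run(
    spec: WellSpec,
    params: PhysicsParams,
    t_end: float,
    snapshot_every: float = 1.0,
    protocol=None,
    n_cells: int = 50,
    strain_mix: Optional[dict] = None,
    seed: int = 0,
    init_state: Optional[SimState] = None,
) -> list[SimState]:
    """Run the simulator and return snapshots (including the initial state).

    ``protocol`` is either a constant ``{strain: multiplier}`` dict or any
    object with ``multipliers_at(t) -> dict`` (see
    :mod:`corrugo.selection_fitness`).  Fully reproducible given ``seed``.
    """
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    state = init_state if init_state is not None else initialize(
        spec, params, n_cells, strain_mix, seed
    )
    snapshots = [state.copy()]
    if t_end == 0:
        return snapshots
    n_steps = int(round(t_end / params.dt))
    k_snap = max(1, int(round(snapshot_every / params.dt)))
    done = 0
    while done < n_steps:
        chunk = min(k_snap - done % k_snap, n_steps - done)
        advance(state, chunk * params.dt, protocol)
        done += chunk
        if done % k_snap == 0 or done == n_steps:
            snapshots.append(state.copy())
            g = len(np.unique(state.genotype))
            logger.info(
                "t=%.2f h  N=%d  clones=%d  removed=%d",
                state.time, state.n, g, state.removed_count,
            )
    return snapshots
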