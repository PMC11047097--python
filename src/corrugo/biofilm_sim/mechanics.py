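"""Numba kernels for spherocylinder contact mechanics.

Forces follow the mechanical model of growing rod colonies:

* cell-cell: Hertzian-like repulsion ``F = k_cell * overlap**1.5`` along the
  line of closest approach between the two centreline segments;
* cell-wall: linear repulsion ``F = k_wall * penetration`` along the outward
  wall normal, sampled at the two cap centres and the midpoint;
* cell-wall adhesion: breakable elastic springs from a centreline point to
  the wall point of first contact, resisting extension only.

The kernels accumulate forces, 2D torques (scalars) and the total elastic
energy (2/5 k o^{5/2} per contact, 1/2 k p^2 per wall sample, 1/2 k e^2 per
spring).  They operate on flat arrays; the engine owns the state layout.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# wall slots for adhesion springs
BOTTOM, LEFT, RIGHT = 0, 1, 2
NWALLS = 3


@njit(cache=False, fastmath=True)
def segment_closest(p1x, p1y, d1x, d1y, p2x, p2y, d2x, d2y):
    """Closest points of segments [p1, p1+d1] and [p2, p2+d2].

    Returns (s, t, c1x, c1y, c2x, c2y, dist) with s, t in [0, 1].
    """
    rx = p1x - p2x
    ry = p1y - p2y
    a = d1x * d1x + d1y * d1y
    e = d2x * d2x + d2y * d2y
    f = d2x * rx + d2y * ry
    c = d1x * rx + d1y * ry
    b = d1x * d2x + d1y * d2y
    denom = a * e - b * b
    if denom > 1e-14:
        s = (b * f - c * e) / denom
        if s < 0.0:
            s = 0.0
        elif s > 1.0:
            s = 1.0
    else:
        s = 0.0
    if e > 1e-14:
        t = (b * s + f) / e
    else:
        t = 0.0
    if t < 0.0:
        t = 0.0
        if a > 1e-14:
            s = -c / a
            if s < 0.0:
                s = 0.0
            elif s > 1.0:
                s = 1.0
    elif t > 1.0:
        t = 1.0
        if a > 1e-14:
            s = (b - c) / a
            if s < 0.0:
                s = 0.0
            elif s > 1.0:
                s = 1.0
    c1x = p1x + s * d1x
    c1y = p1y + s * d1y
    c2x = p2x + t * d2x
    c2y = p2y + t * d2y
    dx = c2x - c1x
    dy = c2y - c1y
    return s, t, c1x, c1y, c2x, c2y, math.sqrt(dx * dx + dy * dy)


@njit(cache=False, fastmath=True)
def build_grid(px, py, cs, nxg, nyg, head, nxt):
    """Linked-list spatial hash over cell centres (bins clamped to the grid)."""
    head[:] = -1
    n = px.shape[0]
    for i in range(n):
        ix = int(px[i] / cs)
        iy = int(py[i] / cs)
        if ix < 0:
            ix = 0
        elif ix >= nxg:
            ix = nxg - 1
        if iy < 0:
            iy = 0
        elif iy >= nyg:
            iy = nyg - 1
        b = ix + iy * nxg
        nxt[i] = head[b]
        head[b] = i


@njit(cache=False, fastmath=True)
def pair_forces(px, py, ex, ey, hl, rad, ids, k_cell, cs, nxg, nyg, head, nxt, fx, fy, tq):
    """Accumulate cell-cell Hertzian repulsion; returns total pair elastic energy."""
    n = px.shape[0]
    energy = 0.0
    for i in range(n):
        ix = int(px[i] / cs)
        iy = int(py[i] / cs)
        if ix < 0:
            ix = 0
        elif ix >= nxg:
            ix = nxg - 1
        if iy < 0:
            iy = 0
        elif iy >= nyg:
            iy = nyg - 1
        for dy in range(-1, 2):
            jy = iy + dy
            if jy < 0 or jy >= nyg:
                continue
            for dx in range(-1, 2):
                jx = ix + dx
                if jx < 0 or jx >= nxg:
                    continue
                j = head[jx + jy * nxg]
                while j != -1:
                    if j > i:
                        reach = hl[i] + hl[j] + rad[i] + rad[j]
                        ddx = px[j] - px[i]
                        ddy = py[j] - py[i]
                        if ddx * ddx + ddy * ddy < reach * reach:
                            p1x = px[i] - hl[i] * ex[i]
                            p1y = py[i] - hl[i] * ey[i]
                            p2x = px[j] - hl[j] * ex[j]
                            p2y = py[j] - hl[j] * ey[j]
                            s, t, c1x, c1y, c2x, c2y, dist = segment_closest(
                                p1x, p1y, 2.0 * hl[i] * ex[i], 2.0 * hl[i] * ey[i],
                                p2x, p2y, 2.0 * hl[j] * ex[j], 2.0 * hl[j] * ey[j],
                            )
                            o = rad[i] + rad[j] - dist
                            if o > 0.0:
                                if dist > 1e-9:
                                    nx = (c2x - c1x) / dist
                                    ny = (c2y - c1y) / dist
                                else:
                                    # coincident centrelines: deterministic
                                    # perpendicular from a hash of the ids
                                    hsh = (ids[i] * 73856093 + ids[j] * 19349663) % 1024
                                    th = 2.0 * math.pi * hsh / 1024.0
                                    nx = math.cos(th)
                                    ny = math.sin(th)
                                fmag = k_cell * o * math.sqrt(o)
                                energy += 0.4 * k_cell * o * o * math.sqrt(o)
                                fxi = -fmag * nx
                                fyi = -fmag * ny
                                # contact point: midpoint of closest points
                                cxm = 0.5 * (c1x + c2x)
                                cym = 0.5 * (c1y + c2y)
                                fx[i] += fxi
                                fy[i] += fyi
                                tq[i] += (cxm - px[i]) * fyi - (cym - py[i]) * fxi
                                fx[j] -= fxi
                                fy[j] -= fyi
                                tq[j] += (cxm - px[j]) * (-fyi) - (cym - py[j]) * (-fxi)
                    j = nxt[j]
    return energy


@njit(cache=False, fastmath=True)
def _nearest_bottom(px, py, A, T, width, window=1.6):
    """Nearest point on the sine bottom for a point close to it.

    Valid for points whose vertical gap to the curve is below ``window``
    (the nearest abscissa then satisfies |u - px| <= gap): coarse sampling
    over +-window followed by golden-section refinement.
    Returns (u, hx, signed_dist, nx, ny).
    """
    w = 2.0 * math.pi / T
    lo = px - window
    hi = px + window
    if lo < 0.0:
        lo = 0.0
    if hi > width:
        hi = width
    best_u = lo
    best_d2 = 1e30
    for k in range(9):
        u = lo + (hi - lo) * k / 8.0
        h = 0.5 * A * (1.0 - math.cos(w * u))
        d2 = (u - px) ** 2 + (h - py) ** 2
        if d2 < best_d2:
            best_d2 = d2
            best_u = u
    span = (hi - lo) / 8.0
    a = best_u - span
    b = best_u + span
    if a < 0.0:
        a = 0.0
    if b > width:
        b = width
    invphi = 0.6180339887498949
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    hc = 0.5 * A * (1.0 - math.cos(w * c))
    hd = 0.5 * A * (1.0 - math.cos(w * d))
    fc = (c - px) ** 2 + (hc - py) ** 2
    fd = (d - px) ** 2 + (hd - py) ** 2
    for _ in range(11):
        if fc < fd:
            b = d
            d = c
            fd = fc
            c = b - invphi * (b - a)
            hc = 0.5 * A * (1.0 - math.cos(w * c))
            fc = (c - px) ** 2 + (hc - py) ** 2
        else:
            a = c
            c = d
            fc = fd
            d = a + invphi * (b - a)
            hd = 0.5 * A * (1.0 - math.cos(w * d))
            fd = (d - px) ** 2 + (hd - py) ** 2
    u = 0.5 * (a + b)
    h = 0.5 * A * (1.0 - math.cos(w * u))
    hp = 0.5 * A * w * math.sin(w * u)
    nn = math.sqrt(1.0 + hp * hp)
    nx = -hp / nn
    ny = 1.0 / nn
    signed = (px - u) * nx + (py - h) * ny
    return u, h, signed, nx, ny


@njit(cache=False, fastmath=True)
def multi_step(
    px, py, ang, length, rad, ids, gf,
    k_cell, k_wall, A, T, width, flat,
    adh_on, k_adh, eps_max,
    sp_active, sp_ax, sp_ay, sp_rest, sp_frac,
    gamma, gamma_rot, dt, cap_frac, use_cap, abort_frac,
    lth, height, cs, nxg, nyg, head, nxt, fx, fy, tq,
    n_samples, max_steps,
):
    """Run up to ``max_steps`` overdamped steps entirely in compiled code.

    Per-cell growth factors ``gf`` are constant within the chunk.  Returns
    ``(steps_done, elastic_energy, max_penetration, status)`` where status
    flags why the chunk ended early: bit 1 = a division is due, bit 2 = a
    cell crossed the open top, 4 = stability abort (uncapped mode only).
    The caller handles division/removal and re-enters.
    """
    n = px.shape[0]
    ex = np.empty(n)
    ey = np.empty(n)
    hl = np.empty(n)
    energy = 0.0
    max_pen = 0.0
    steps = 0
    for _ in range(max_steps):
        for i in range(n):
            ex[i] = math.cos(ang[i])
            ey[i] = math.sin(ang[i])
            hl[i] = 0.5 * length[i]
            fx[i] = 0.0
            fy[i] = 0.0
            tq[i] = 0.0
        build_grid(px, py, cs, nxg, nyg, head, nxt)
        e1 = pair_forces(px, py, ex, ey, hl, rad, ids, k_cell,
                         cs, nxg, nyg, head, nxt, fx, fy, tq)
        e2, mp = wall_adhesion_forces(
            px, py, ex, ey, hl, rad, A, T, width, flat,
            k_wall, adh_on, k_adh, eps_max,
            sp_active, sp_ax, sp_ay, sp_rest, sp_frac,
            fx, fy, tq, n_samples,
        )
        energy = e1 + e2
        if mp > max_pen:
            max_pen = mp
        trigger = 0
        for i in range(n):
            extn = length[i] + 2.0 * rad[i]
            vx = fx[i] / (gamma * extn)
            vy = fy[i] / (gamma * extn)
            om = tq[i] / (gamma_rot * extn * extn * extn)
            disp = math.hypot(vx, vy) * dt + abs(om) * dt * 0.5 * extn
            if use_cap:
                cap = cap_frac * rad[i]
                sc = 1.0 if disp <= cap else cap / disp
            else:
                if disp > abort_frac * rad[i]:
                    return steps, energy, max_pen, 4
                sc = 1.0
            px[i] += vx * dt * sc
            py[i] += vy * dt * sc
            ang[i] += om * dt * sc
            length[i] *= gf[i]
            if length[i] >= lth[i]:
                trigger |= 1
            if py[i] > height:
                trigger |= 2
        steps += 1
        if trigger != 0:
            return steps, energy, max_pen, trigger
    return steps, energy, max_pen, 0


@njit(cache=False, fastmath=True)
def wall_adhesion_forces(
    px, py, ex, ey, hl, rad,
    A, T, width, flat,
    k_wall,
    adh_on, k_adh, eps_max,
    sp_active, sp_ax, sp_ay, sp_rest, sp_frac,
    fx, fy, tq, n_samples,
):
    """Wall repulsion (``n_samples`` points per centreline) and adhesion springs.

    Mutates the spring arrays in place (creation and breaking).  Returns
    (elastic energy, max wall penetration).
    """
    n = px.shape[0]
    energy = 0.0
    max_pen = 0.0
    # spring-creation bookkeeping: per wall, closest sample (scalar locals
    # rather than small arrays -- this loop is the hottest wall path)
    for i in range(n):
        # early out: cell entirely in the bulk and carrying no spring
        reach = hl[i] + rad[i] + 0.6
        floor_top = 0.0 if flat else A
        if (px[i] > reach and width - px[i] > reach
                and py[i] - floor_top > reach
                and not (sp_active[i, 0] or sp_active[i, 1] or sp_active[i, 2])):
            continue
        bd0 = 1e30; bax0 = 0.0; bay0 = 0.0; bs0 = 0.0
        bd1 = 1e30; bax1 = 0.0; bay1 = 0.0; bs1 = 0.0
        bd2 = 1e30; bax2 = 0.0; bay2 = 0.0; bs2 = 0.0
        for ks in range(n_samples):
            sfrac = -1.0 + 2.0 * ks / (n_samples - 1)
            sx = px[i] + sfrac * hl[i] * ex[i]
            sy = py[i] + sfrac * hl[i] * ey[i]
            # --- bottom
            if flat:
                db = sy
                nxb = 0.0
                nyb = 1.0
                axb = sx
                ayb = 0.0
                consider = db < rad[i] + 0.5
            else:
                consider = False
                db = 1e30
                nxb = 0.0
                nyb = 1.0
                axb = sx
                ayb = 0.0
                if sy - A < rad[i] + 0.5:
                    # cheap prefilter: the curve-distance cannot be below the
                    # radius unless the vertical gap is within slope reach
                    w = 2.0 * math.pi / T
                    gap = sy - 0.5 * A * (1.0 - math.cos(w * sx))
                    smax = 0.5 * A * w
                    if gap < (rad[i] + 0.25) * math.sqrt(1.0 + smax * smax):
                        consider = True
                        u, h, db, nxb, nyb = _nearest_bottom(sx, sy, A, T, width)
                        axb = u
                        ayb = h
            if consider:
                p = rad[i] - db
                if p > 0.0:
                    if p > max_pen:
                        max_pen = p
                    fmag = k_wall * p
                    energy += 0.5 * k_wall * p * p
                    fx[i] += fmag * nxb
                    fy[i] += fmag * nyb
                    tq[i] += (sx - px[i]) * fmag * nyb - (sy - py[i]) * fmag * nxb
                if db < bd0:
                    bd0 = db; bax0 = axb; bay0 = ayb; bs0 = sfrac
            # --- left wall
            dl = sx
            p = rad[i] - dl
            if p > 0.0:
                if p > max_pen:
                    max_pen = p
                fmag = k_wall * p
                energy += 0.5 * k_wall * p * p
                fx[i] += fmag
                tq[i] += (sy - py[i]) * (-fmag)
            if dl < bd1:
                bd1 = dl; bax1 = 0.0; bay1 = sy; bs1 = sfrac
            # --- right wall
            dr = width - sx
            p = rad[i] - dr
            if p > 0.0:
                if p > max_pen:
                    max_pen = p
                fmag = k_wall * p
                energy += 0.5 * k_wall * p * p
                fx[i] -= fmag
                tq[i] += (sy - py[i]) * fmag
            if dr < bd2:
                bd2 = dr; bax2 = width; bay2 = sy; bs2 = sfrac
        if not adh_on:
            continue
        for wall in range(NWALLS):
            if wall == BOTTOM:
                best_d = bd0; best_ax = bax0; best_ay = bay0; best_s = bs0
            elif wall == LEFT:
                best_d = bd1; best_ax = bax1; best_ay = bay1; best_s = bs1
            else:
                best_d = bd2; best_ax = bax2; best_ay = bay2; best_s = bs2
            if not sp_active[i, wall]:
                # first contact -> create a spring anchored at the nearest
                # wall point, rest length = current centreline-anchor distance
                if best_d < rad[i]:
                    sp_active[i, wall] = True
                    sp_ax[i, wall] = best_ax
                    sp_ay[i, wall] = best_ay
                    r0 = best_d
                    if r0 < 0.05 * rad[i]:
                        r0 = 0.05 * rad[i]
                    sp_rest[i, wall] = r0
                    sp_frac[i, wall] = best_s
            if sp_active[i, wall]:
                attx = px[i] + sp_frac[i, wall] * hl[i] * ex[i]
                atty = py[i] + sp_frac[i, wall] * hl[i] * ey[i]
                dx = sp_ax[i, wall] - attx
                dy = sp_ay[i, wall] - atty
                ln = math.sqrt(dx * dx + dy * dy)
                ext = ln - sp_rest[i, wall]
                if ext > eps_max * sp_rest[i, wall]:
                    sp_active[i, wall] = False
                elif ext > 0.0 and ln > 1e-12:
                    fmag = k_adh * ext
                    energy += 0.5 * k_adh * ext * ext
                    fxs = fmag * dx / ln
                    fys = fmag * dy / ln
                    fx[i] += fxs
                    fy[i] += fys
                    tq[i] += (attx - px[i]) * fys - (atty - py[i]) * fxs
    return energy, max_pen
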