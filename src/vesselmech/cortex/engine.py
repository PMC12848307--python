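"""Compiled stepping kernel for the cortex model.

One overdamped explicit-Euler step is: (1) force evaluation — filament
stretching and bending, motor/crosslinker link springs, membrane
stretching/bending/foundation, wall confinement, anchor pins; (2) bead
motion by F*dt/gamma plus optional thermal kicks sqrt(2*kT*dt/gamma);
(3) stochastic kinetics with per-step probabilities 1-exp(-rate*dt):
head binding within the capture radius, unbinding, motor stepping toward
the plus end at v = v0*max(0, 1 - f_par/f_stall) with detachment at the
plus end, plus-end polymerisation / minus-end depolymerisation between
length bounds, and whole-filament turnover of free filaments.  Event
order is fixed as listed and all randomness comes from one seeded stream,
so trajectories are bit-reproducible per (params, seed).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .params import MAX_BEADS, SimParams
from .state import SimulationState

__all__ = ["pack_params", "run_steps", "seed_engine", "step", "compute_forces"]

# indices into the packed parameter vector
(P_DT, P_GAMMA, P_KT, P_NOISE, P_LX, P_LY, P_L0, P_KS, P_KAPPA, P_KLINK,
 P_R0, P_CAPR, P_MO_PON, P_MO_POFF, P_V0, P_FSTALL, P_XL_PON, P_XL_POFF,
 P_TURN, P_POLY, P_DEPOLY, P_MINSEG, P_MAXSEG, P_KMEM, P_KBMEM, P_KFOUND,
 P_GMEM, P_KWALL, P_DEFORM, P_SPACING, P_ENDDWELL, P_MO_OFFRATE,
 P_XL_OFFRATE, P_FDETACH, P_KALIGN, P_XLPROTECT) = range(36)

GRID_CELL = 0.5
GRID_CAP = 24


def pack_params(p: SimParams) -> np.ndarray:
    def prob(rate):
        return 1.0 - math.exp(-rate * p.dt)

    P = np.zeros(36)
    P[P_DT] = p.dt
    P[P_GAMMA] = p.drag
    P[P_KT] = p.kT
    P[P_NOISE] = 1.0 if p.thermal_noise else 0.0
    P[P_LX] = p.Lx
    P[P_LY] = p.Ly
    P[P_L0] = p.segment_rest_length
    P[P_KS] = p.stretch_stiffness
    P[P_KAPPA] = p.bending_rigidity
    P[P_KLINK] = p.link_stiffness
    P[P_R0] = p.link_rest_length
    P[P_CAPR] = p.capture_radius
    P[P_MO_PON] = prob(p.motor_on_rate)
    P[P_MO_POFF] = prob(p.motor_off_rate)
    P[P_V0] = p.motor_speed
    P[P_FSTALL] = p.motor_stall_force
    P[P_XL_PON] = prob(p.xl_on_rate)
    P[P_XL_POFF] = prob(p.xl_off_rate)
    P[P_TURN] = prob(p.turnover_rate)
    P[P_POLY] = prob(p.poly_rate)
    P[P_DEPOLY] = prob(p.depoly_rate)
    P[P_MINSEG] = p.min_segments
    P[P_MAXSEG] = p.max_segments
    P[P_KMEM] = p.membrane_stretch
    P[P_KBMEM] = p.membrane_bending
    P[P_KFOUND] = p.foundation_stiffness
    P[P_GMEM] = p.membrane_drag
    P[P_KWALL] = p.wall_stiffness
    P[P_DEFORM] = 1.0 if p.boundary_mode == "deformable_membrane" else 0.0
    P[P_SPACING] = p.membrane_spacing
    P[P_ENDDWELL] = 1.0 if p.motor_end_dwell else 0.0
    P[P_MO_OFFRATE] = p.motor_off_rate
    P[P_XL_OFFRATE] = p.xl_off_rate
    P[P_FDETACH] = p.detachment_force
    P[P_KALIGN] = p.xl_align_stiffness
    P[P_XLPROTECT] = p.xl_protect_heads
    return P


@njit(cache=True)
def seed_engine(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _wrap_y(y, Ly):
    return y - Ly * math.floor(y / Ly)


@njit(cache=True, inline="always")
def _min_img(dy, Ly):
    return dy - Ly * round(dy / Ly)


@njit(cache=True)
def _head_point(fx, fy, fn, f, s, l0):
    """Position and segment info of a head at arc position s on filament f.

    Returns (x, y, seg, t, tx, ty) with (tx, ty) the plus-direction unit
    vector of the segment."""
    nseg = fn[f] - 1
    seg = int(s / l0)
    if seg > nseg - 1:
        seg = nseg - 1
    if seg < 0:
        seg = 0
    t = s / l0 - seg
    if t < 0.0:
        t = 0.0
    if t > 1.0:
        t = 1.0
    x0, y0 = fx[f, seg], fy[f, seg]
    x1, y1 = fx[f, seg + 1], fy[f, seg + 1]
    dx, dy = x1 - x0, y1 - y0
    d = math.sqrt(dx * dx + dy * dy)
    if d < 1e-12:
        return x0, y0, seg, t, 1.0, 0.0
    return x0 + t * dx, y0 + t * dy, seg, t, dx / d, dy / d


@njit(cache=True)
def _build_grid(fx, fy, fn, Lx, Ly, grid_count, grid_items):
    gnx, gny = grid_count.shape
    grid_count[:, :] = 0
    NF = fx.shape[0]
    for f in range(NF):
        for s in range(fn[f] - 1):
            mx = 0.5 * (fx[f, s] + fx[f, s + 1])
            my = 0.5 * (fy[f, s] + fy[f, s + 1])
            ix = int(mx / GRID_CELL)
            if ix < 0:
                ix = 0
            if ix >= gnx:
                ix = gnx - 1
            myw = _wrap_y(my, Ly)
            iy = int(myw / GRID_CELL)
            if iy >= gny:
                iy = gny - 1
            c = grid_count[ix, iy]
            if c < GRID_CAP:
                grid_items[ix, iy, c] = f * MAX_BEADS + s
                grid_count[ix, iy] = c + 1


@njit(cache=True, fastmath=True)
def _nearest_segment(px, py, exclude_f, fx, fy, fn, l0, Ly, capr,
                     grid_count, grid_items):
    """Nearest filament segment to a point within the capture radius.

    Returns (filament, arc_position) or (-1, 0.0)."""
    gnx, gny = grid_count.shape
    ix0 = int(px / GRID_CELL)
    iy0 = int(_wrap_y(py, Ly) / GRID_CELL)
    best_f = -1
    best_s = 0.0
    best_d2 = capr * capr
    for di in range(-1, 2):
        ix = ix0 + di
        if ix < 0 or ix >= gnx:
            continue
        for dj in range(-1, 2):
            iy = (iy0 + dj) % gny
            for c in range(grid_count[ix, iy]):
                code = grid_items[ix, iy, c]
                f = code // MAX_BEADS
                s = code % MAX_BEADS
                if f == exclude_f:
                    continue
                x0, y0 = fx[f, s], fy[f, s]
                x1, y1 = fx[f, s + 1], fy[f, s + 1]
                ym = 0.5 * (y0 + y1)
                shift = Ly * round((py - ym) / Ly)
                y0 += shift
                y1 += shift
                ex, ey = x1 - x0, y1 - y0
                ee = ex * ex + ey * ey
                if ee < 1e-18:
                    continue
                t = ((px - x0) * ex + (py - y0) * ey) / ee
                if t < 0.0:
                    t = 0.0
                if t > 1.0:
                    t = 1.0
                cx, cy = x0 + t * ex, y0 + t * ey
                dx, dy = px - cx, py - cy
                d2 = dx * dx + dy * dy
                if d2 < best_d2:
                    best_d2 = d2
                    best_f = f
                    # arc position in the rest-length parametrisation used
                    # by _head_point
                    best_s = (s + t) * l0
    return best_f, best_s


@njit(cache=True)
def _unbind_filament(f, mo_f, cl_f):
    for m in range(mo_f.shape[0]):
        for h in range(2):
            if mo_f[m, h] == f:
                mo_f[m, h] = -1
    for m in range(cl_f.shape[0]):
        for h in range(2):
            if cl_f[m, h] == f:
                cl_f[m, h] = -1


@njit(cache=True)
def _shift_arcs(f, l0, mo_f, mo_s, cl_f, cl_s):
    """After minus-end depolymerisation, shift arc positions; heads that
    fall off the removed segment unbind."""
    for m in range(mo_f.shape[0]):
        for h in range(2):
            if mo_f[m, h] == f:
                mo_s[m, h] -= l0
                if mo_s[m, h] < 0.0:
                    mo_f[m, h] = -1
    for m in range(cl_f.shape[0]):
        for h in range(2):
            if cl_f[m, h] == f:
                cl_s[m, h] -= l0
                if cl_s[m, h] < 0.0:
                    cl_f[m, h] = -1


@njit(cache=True, fastmath=True)
def _accumulate_forces(P, fx, fy, fn, anchor_code, mem_y, mem_left, mem_right,
                       mo_f, mo_s, mo_ft, mo_fm, cl_f, cl_s, cl_fm,
                       ffx, ffy, fml, fmr):
    """Fill per-bead force arrays for the current configuration."""
    NF = fx.shape[0]
    ML = mem_y.shape[0]
    l0 = P[P_L0]
    ks = P[P_KS]
    kb = P[P_KAPPA] / l0
    Lx, Ly = P[P_LX], P[P_LY]
    deform = P[P_DEFORM] > 0.5
    spacing = P[P_SPACING]

    ffx[:, :] = 0.0
    ffy[:, :] = 0.0
    fml[:] = 0.0
    fmr[:] = 0.0

    # filament stretching
    for f in range(NF):
        n = fn[f]
        for s in range(n - 1):
            dx = fx[f, s + 1] - fx[f, s]
            dy = fy[f, s + 1] - fy[f, s]
            d = math.sqrt(dx * dx + dy * dy)
            if d < 1e-12:
                continue
            fmag = ks * (d - l0)
            ux, uy = dx / d, dy / d
            ffx[f, s] += fmag * ux
            ffy[f, s] += fmag * uy
            ffx[f, s + 1] -= fmag * ux
            ffy[f, s + 1] -= fmag * uy
        # bending (harmonic in 1 - cos(theta) at each interior bead)
        for b in range(1, n - 1):
            ux = fx[f, b] - fx[f, b - 1]
            uy = fy[f, b] - fy[f, b - 1]
            vx = fx[f, b + 1] - fx[f, b]
            vy = fy[f, b + 1] - fy[f, b]
            lu = math.sqrt(ux * ux + uy * uy)
            lv = math.sqrt(vx * vx + vy * vy)
            if lu < 1e-12 or lv < 1e-12:
                continue
            c = (ux * vx + uy * vy) / (lu * lv)
            if c > 1.0:
                c = 1.0
            if c < -1.0:
                c = -1.0
            # dc/du and dc/dv
            gux = vx / (lu * lv) - c * ux / (lu * lu)
            guy = vy / (lu * lv) - c * uy / (lu * lu)
            gvx = ux / (lu * lv) - c * vx / (lv * lv)
            gvy = uy / (lu * lv) - c * vy / (lv * lv)
            ffx[f, b - 1] -= kb * gux
            ffy[f, b - 1] -= kb * guy
            ffx[f, b] += kb * (gux - gvx)
            ffy[f, b] += kb * (guy - gvy)
            ffx[f, b + 1] += kb * gvx
            ffy[f, b + 1] += kb * gvy

    # motor and crosslinker link springs; force clamped at 3x the
    # detachment scale (slip bonds release well below such loads)
    klink = P[P_KLINK]
    r0 = P[P_R0]
    fcap = 3.0 * P[P_FDETACH]
    for m in range(mo_f.shape[0]):
        mo_ft[m, 0] = 0.0
        mo_ft[m, 1] = 0.0
        mo_fm[m] = 0.0
        f0, f1 = mo_f[m, 0], mo_f[m, 1]
        if f0 >= 0 and f1 >= 0:
            x0, y0, s0, t0, tx0, ty0 = _head_point(fx, fy, fn, f0, mo_s[m, 0], l0)
            x1, y1, s1, t1, tx1, ty1 = _head_point(fx, fy, fn, f1, mo_s[m, 1], l0)
            dx = x1 - x0
            dy = _min_img(y1 - y0, Ly)
            d = math.sqrt(dx * dx + dy * dy)
            if d > 1e-12:
                fmag = klink * (d - r0)
                if fmag > fcap:
                    fmag = fcap
                elif fmag < -fcap:
                    fmag = -fcap
                ux, uy = dx / d, dy / d
                # head 0 pulled toward head 1, head 1 toward head 0
                fh0x, fh0y = fmag * ux, fmag * uy
                fh1x, fh1y = -fmag * ux, -fmag * uy
                ffx[f0, s0] += (1 - t0) * fh0x
                ffy[f0, s0] += (1 - t0) * fh0y
                ffx[f0, s0 + 1] += t0 * fh0x
                ffy[f0, s0 + 1] += t0 * fh0y
                ffx[f1, s1] += (1 - t1) * fh1x
                ffy[f1, s1] += (1 - t1) * fh1y
                ffx[f1, s1 + 1] += t1 * fh1x
                ffy[f1, s1 + 1] += t1 * fh1y
                mo_ft[m, 0] = fh0x * tx0 + fh0y * ty0
                mo_ft[m, 1] = fh1x * tx1 + fh1y * ty1
                mo_fm[m] = abs(fmag)
    kalign = P[P_KALIGN]
    for m in range(cl_f.shape[0]):
        cl_fm[m] = 0.0
        f0, f1 = cl_f[m, 0], cl_f[m, 1]
        if f0 >= 0 and f1 >= 0:
            x0, y0, s0, t0, tx0, ty0 = _head_point(fx, fy, fn, f0, cl_s[m, 0], l0)
            x1, y1, s1, t1, tx1, ty1 = _head_point(fx, fy, fn, f1, cl_s[m, 1], l0)
            if kalign > 0.0:
                # nematic alignment torque of a bundling crosslinker:
                # E = -k_align * (u0 . u1)^2 on the two bridged segments
                c = tx0 * tx1 + ty0 * ty1
                La = math.sqrt((fx[f0, s0 + 1] - fx[f0, s0]) ** 2
                               + (fy[f0, s0 + 1] - fy[f0, s0]) ** 2)
                Lb = math.sqrt((fx[f1, s1 + 1] - fx[f1, s1]) ** 2
                               + (fy[f1, s1 + 1] - fy[f1, s1]) ** 2)
                if La > 1e-12 and Lb > 1e-12:
                    pref = 2.0 * kalign * c
                    gax = pref * (tx1 - c * tx0) / La
                    gay = pref * (ty1 - c * ty0) / La
                    gbx = pref * (tx0 - c * tx1) / Lb
                    gby = pref * (ty0 - c * ty1) / Lb
                    ffx[f0, s0] -= gax
                    ffy[f0, s0] -= gay
                    ffx[f0, s0 + 1] += gax
                    ffy[f0, s0 + 1] += gay
                    ffx[f1, s1] -= gbx
                    ffy[f1, s1] -= gby
                    ffx[f1, s1 + 1] += gbx
                    ffy[f1, s1 + 1] += gby
            dx = x1 - x0
            dy = _min_img(y1 - y0, Ly)
            d = math.sqrt(dx * dx + dy * dy)
            if d > 1e-12:
                fmag = klink * (d - r0)
                if fmag > fcap:
                    fmag = fcap
                elif fmag < -fcap:
                    fmag = -fcap
                ux, uy = dx / d, dy / d
                ffx[f0, s0] += (1 - t0) * fmag * ux
                ffy[f0, s0] += (1 - t0) * fmag * uy
                ffx[f0, s0 + 1] += t0 * fmag * ux
                ffy[f0, s0 + 1] += t0 * fmag * uy
                ffx[f1, s1] -= (1 - t1) * fmag * ux
                ffy[f1, s1] -= (1 - t1) * fmag * uy
                ffx[f1, s1 + 1] -= t1 * fmag * ux
                ffy[f1, s1 + 1] -= t1 * fmag * uy
                cl_fm[m] = abs(fmag)

    # wall / membrane confinement of filament beads (one-way)
    kwall = P[P_KWALL]
    for f in range(NF):
        for b in range(fn[f]):
            x = fx[f, b]
            if deform:
                yw = _wrap_y(fy[f, b], Ly)
                u = yw / spacing
                i = int(u)
                if i >= ML - 1:
                    i = ML - 2
                t = u - i
                xl = mem_left[i] * (1 - t) + mem_left[i + 1] * t
                xr = mem_right[i] * (1 - t) + mem_right[i + 1] * t
            else:
                xl = 0.0
                xr = Lx
            if x < xl:
                ffx[f, b] += kwall * (xl - x)
            elif x > xr:
                ffx[f, b] -= kwall * (x - xr)

    # membrane internal forces
    if deform:
        kmem = P[P_KMEM]
        kfound = P[P_KFOUND]
        kbm = P[P_KBMEM] / (spacing * spacing * spacing)
        for side in range(2):
            for i in range(ML - 1):
                if side == 0:
                    dx = mem_left[i + 1] - mem_left[i]
                else:
                    dx = mem_right[i + 1] - mem_right[i]
                d = math.sqrt(dx * dx + spacing * spacing)
                fmag = kmem * (d - spacing)
                fxc = fmag * dx / d
                if side == 0:
                    fml[i] += fxc
                    fml[i + 1] -= fxc
                else:
                    fmr[i] += fxc
                    fmr[i + 1] -= fxc
            for i in range(1, ML - 1):
                if side == 0:
                    lap = mem_left[i - 1] - 2 * mem_left[i] + mem_left[i + 1]
                    fml[i - 1] -= kbm * lap
                    fml[i] += 2 * kbm * lap
                    fml[i + 1] -= kbm * lap
                else:
                    lap = mem_right[i - 1] - 2 * mem_right[i] + mem_right[i + 1]
                    fmr[i - 1] -= kbm * lap
                    fmr[i] += 2 * kbm * lap
                    fmr[i + 1] -= kbm * lap
            for i in range(ML):
                if side == 0:
                    fml[i] -= kfound * mem_left[i]
                else:
                    fmr[i] -= kfound * (mem_right[i] - Lx)


@njit(cache=True, fastmath=True)
def run_steps(nsteps, P, fx, fy, fn, anchor_code, anchor_idx,
              anchor_fx, anchor_fy, anchor_ux, anchor_uy,
              mem_y, mem_left, mem_right,
              mo_f, mo_s, cl_f, cl_s,
              ffx, ffy, fml, fmr, mo_ft, mo_fm, cl_fm, xl_heads,
              grid_count, grid_items):
    """Advance the state by ``nsteps`` steps in place.

    Returns 0 on success, or the (1-based) step index at which a bead
    displacement exceeded the segment rest length (numerical blow-up).
    With ``nsteps == 0`` only the force arrays are filled.
    """
    NF = fx.shape[0]
    ML = mem_y.shape[0]
    dt = P[P_DT]
    gamma = P[P_GAMMA]
    l0 = P[P_L0]
    Lx, Ly = P[P_LX], P[P_LY]
    deform = P[P_DEFORM] > 0.5
    noise_amp = math.sqrt(2.0 * P[P_KT] * dt / gamma) if P[P_NOISE] > 0.5 else 0.0
    maxdisp = l0

    if nsteps == 0:
        _accumulate_forces(P, fx, fy, fn, anchor_code, mem_y, mem_left,
                           mem_right, mo_f, mo_s, mo_ft, mo_fm, cl_f, cl_s,
                           cl_fm, ffx, ffy, fml, fmr)
        return 0

    for istep in range(nsteps):
        _accumulate_forces(P, fx, fy, fn, anchor_code, mem_y, mem_left,
                           mem_right, mo_f, mo_s, mo_ft, mo_fm, cl_f, cl_s,
                           cl_fm, ffx, ffy, fml, fmr)

        # anchored end segments (beads 0 and 1 are clamped): transfer
        # their net force to the pin
        for f in range(NF):
            code = anchor_code[f]
            if code == 1:
                fml[anchor_idx[f]] += ffx[f, 0] + ffx[f, 1]
            elif code == 2:
                fmr[anchor_idx[f]] += ffx[f, 0] + ffx[f, 1]
            # code 3 (fixed point): force absorbed by the pin

        # membrane motion (interior beads only; endpoints pinned)
        if deform:
            gmem = P[P_GMEM]
            for i in range(1, ML - 1):
                mem_left[i] += fml[i] * dt / gmem
                mem_right[i] += fmr[i] * dt / gmem

        # filament bead motion
        blowup = 0
        for f in range(NF):
            b0 = 2 if anchor_code[f] != 0 else 0
            for b in range(b0, fn[f]):
                dxs = ffx[f, b] * dt / gamma
                dys = ffy[f, b] * dt / gamma
                dd = math.sqrt(dxs * dxs + dys * dys)
                if dd > 2.0 * maxdisp:
                    blowup = 1
                cap = 0.2 * maxdisp
                if dd > cap:
                    # clip rare overlarge moves (stacked links); keeps the
                    # integrator bounded without touching typical dynamics
                    dxs *= cap / dd
                    dys *= cap / dd
                if noise_amp > 0.0:
                    # variance-matched uniform kicks: sqrt(3)*U(-1,1) has
                    # unit variance; successive-step sums Gaussianize
                    dxs += noise_amp * 1.7320508075688772 * (
                        2.0 * np.random.random() - 1.0)
                    dys += noise_amp * 1.7320508075688772 * (
                        2.0 * np.random.random() - 1.0)
                fx[f, b] += dxs
                fy[f, b] += dys
            # snap clamped end segments onto their (possibly moved) anchor
            code = anchor_code[f]
            if code != 0:
                if code == 1:
                    ax, ay = mem_left[anchor_idx[f]], mem_y[anchor_idx[f]]
                elif code == 2:
                    ax, ay = mem_right[anchor_idx[f]], mem_y[anchor_idx[f]]
                else:
                    ax, ay = anchor_fx[f], anchor_fy[f]
                fx[f, 0] = ax
                fy[f, 0] = ay
                fx[f, 1] = ax + l0 * anchor_ux[f]
                fy[f, 1] = ay + l0 * anchor_uy[f]
        if blowup:
            return istep + 1

        # ---- stochastic kinetics ----
        _build_grid(fx, fy, fn, Lx, Ly, grid_count, grid_items)
        capr = P[P_CAPR]

        # motors: unbind, walk, bind
        v0 = P[P_V0]
        fstall = P[P_FSTALL]
        fdet = P[P_FDETACH]
        for m in range(mo_f.shape[0]):
            # load-dependent (slip-bond) unbinding
            bell = math.exp(mo_fm[m] / fdet) if mo_fm[m] > 0.0 else 1.0
            poff = 1.0 - math.exp(-P[P_MO_OFFRATE] * bell * dt)
            for h in range(2):
                if mo_f[m, h] >= 0 and np.random.random() < poff:
                    mo_f[m, h] = -1
            for h in range(2):
                f = mo_f[m, h]
                if f < 0:
                    continue
                ft = mo_ft[m, h]
                load = ft if ft < 0.0 else 0.0
                v = v0 * (1.0 + load / fstall)
                if v < 0.0:
                    v = 0.0
                if v > v0:
                    v = v0
                mo_s[m, h] += v * dt
                if mo_s[m, h] > (fn[f] - 1) * l0:
                    if P[P_ENDDWELL] > 0.5:
                        mo_s[m, h] = (fn[f] - 1) * l0  # dwell at the plus end
                    else:
                        mo_f[m, h] = -1  # detach at the plus end
            b0 = mo_f[m, 0] >= 0
            b1 = mo_f[m, 1] >= 0
            if not b0 and not b1:
                if np.random.random() < P[P_MO_PON]:
                    px = np.random.random() * Lx
                    py = np.random.random() * Ly
                    f, s = _nearest_segment(px, py, -1, fx, fy, fn, l0, Ly,
                                            capr, grid_count, grid_items)
                    if f >= 0:
                        mo_f[m, 0] = f
                        mo_s[m, 0] = s
            elif b0 != b1:
                if np.random.random() < P[P_MO_PON]:
                    hb = 0 if b0 else 1
                    fb = mo_f[m, hb]
                    hx, hy, _, _, _, _ = _head_point(fx, fy, fn, fb,
                                                     mo_s[m, hb], l0)
                    f, s = _nearest_segment(hx, hy, fb, fx, fy, fn, l0, Ly,
                                            capr, grid_count, grid_items)
                    if f >= 0:
                        hf = 1 - hb
                        mo_f[m, hf] = f
                        mo_s[m, hf] = s

        # crosslinkers: unbind, bind (no walking)
        for m in range(cl_f.shape[0]):
            bell = math.exp(cl_fm[m] / fdet) if cl_fm[m] > 0.0 else 1.0
            poff = 1.0 - math.exp(-P[P_XL_OFFRATE] * bell * dt)
            for h in range(2):
                if cl_f[m, h] >= 0 and np.random.random() < poff:
                    cl_f[m, h] = -1
            b0 = cl_f[m, 0] >= 0
            b1 = cl_f[m, 1] >= 0
            if not b0 and not b1:
                if np.random.random() < P[P_XL_PON]:
                    px = np.random.random() * Lx
                    py = np.random.random() * Ly
                    f, s = _nearest_segment(px, py, -1, fx, fy, fn, l0, Ly,
                                            capr, grid_count, grid_items)
                    if f >= 0:
                        cl_f[m, 0] = f
                        cl_s[m, 0] = s
            elif b0 != b1:
                if np.random.random() < P[P_XL_PON]:
                    hb = 0 if b0 else 1
                    fb = cl_f[m, hb]
                    hx, hy, _, _, _, _ = _head_point(fx, fy, fn, fb,
                                                     cl_s[m, hb], l0)
                    f, s = _nearest_segment(hx, hy, fb, fx, fy, fn, l0, Ly,
                                            capr, grid_count, grid_items)
                    if f >= 0:
                        hf = 1 - hb
                        cl_f[m, hf] = f
                        cl_s[m, hf] = s

        # filament kinetics: turnover (free only), polymerisation, depoly.
        # Filaments held by >= 2 crosslinker heads are protected from
        # whole-filament turnover: bundled actin resists severing, which
        # is what lets bundles outlive the surrounding mesh.
        minseg = int(P[P_MINSEG])
        maxseg = int(P[P_MAXSEG])
        protect = int(P[P_XLPROTECT])
        if protect > 0:
            xl_heads[:] = 0
            for m in range(cl_f.shape[0]):
                for h in range(2):
                    if cl_f[m, h] >= 0:
                        xl_heads[cl_f[m, h]] += 1
        for f in range(NF):
            if anchor_code[f] != 0:
                continue
            if protect > 0 and xl_heads[f] >= protect:
                continue
            if np.random.random() < P[P_TURN]:
                # atomic delete + reinsert: count conserved
                _unbind_filament(f, mo_f, cl_f)
                nseg = minseg + int(np.random.random() * (maxseg - minseg + 1))
                if nseg > maxseg:
                    nseg = maxseg
                fn[f] = nseg + 1
                length = nseg * l0
                theta = np.random.random() * math.pi
                half = length / 2.0
                cx = half + 0.2 + np.random.random() * (Lx - 2 * (half + 0.2))
                cy = np.random.random() * Ly
                ct, st = math.cos(theta), math.sin(theta)
                for b in range(nseg + 1):
                    t = (b - nseg / 2.0) * l0
                    fx[f, b] = cx + t * ct
                    fy[f, b] = cy + t * st
                continue
            n = fn[f]
            if n - 1 < maxseg and np.random.random() < P[P_POLY]:
                dx = fx[f, n - 1] - fx[f, n - 2]
                dy = fy[f, n - 1] - fy[f, n - 2]
                d = math.sqrt(dx * dx + dy * dy)
                if d > 1e-12:
                    fx[f, n] = fx[f, n - 1] + l0 * dx / d
                    fy[f, n] = fy[f, n - 1] + l0 * dy / d
                    fn[f] = n + 1
            n = fn[f]
            if n - 1 > minseg and np.random.random() < P[P_DEPOLY]:
                for b in range(n - 1):
                    fx[f, b] = fx[f, b + 1]
                    fy[f, b] = fy[f, b + 1]
                fn[f] = n - 1
                _shift_arcs(f, l0, mo_f, mo_s, cl_f, cl_s)
    return 0


# ------------------------------------------------------------ python wrappers

def _work_arrays(state: SimulationState):
    p = state.params
    NF = state.fx.shape[0]
    ML = state.mem_y.shape[0]
    gnx = max(1, int(math.ceil(p.Lx / GRID_CELL)))
    gny = max(1, int(math.ceil(p.Ly / GRID_CELL)))
    return (np.zeros((NF, MAX_BEADS)), np.zeros((NF, MAX_BEADS)),
            np.zeros(ML), np.zeros(ML),
            np.zeros((p.n_motors, 2)), np.zeros(p.n_motors),
            np.zeros(p.n_crosslinkers), np.zeros(NF, dtype=np.int64),
            np.zeros((gnx, gny), dtype=np.int64),
            np.zeros((gnx, gny, GRID_CAP), dtype=np.int64))


def _advance(state: SimulationState, nsteps: int, work=None) -> int:
    if work is None:
        work = _work_arrays(state)
    ffx, ffy, fml, fmr, mo_ft, mo_fm, cl_fm, xlh, gc, gi = work
    status = run_steps(
        nsteps, pack_params(state.params),
        state.fx, state.fy, state.fn, state.anchor_code, state.anchor_idx,
        state.anchor_x, state.anchor_y, state.anchor_ux, state.anchor_uy,
        state.mem_y, state.mem_left,
        state.mem_right, state.mo_f, state.mo_s, state.cl_f, state.cl_s,
        ffx, ffy, fml, fmr, mo_ft, mo_fm, cl_fm, xlh, gc, gi,
    )
    if status != 0:
        raise RuntimeError("unstable step; reduce dt")
    state.time += nsteps * state.params.dt
    return status


def step(state: SimulationState, nsteps: int = 1) -> SimulationState:
    """Advance a state by ``nsteps`` overdamped Euler steps (in place;
    the state is also returned for convenience)."""
    _advance(state, nsteps)
    return state


def compute_forces(state: SimulationState):
    """Per-bead force arrays (ffx, ffy) of the engine's force evaluation
    for the current configuration, without moving anything."""
    work = _work_arrays(state)
    ffx, ffy, fml, fmr, mo_ft, mo_fm, cl_fm, xlh, gc, gi = work
    run_steps(
        0, pack_params(state.params),
        state.fx, state.fy, state.fn, state.anchor_code, state.anchor_idx,
        state.anchor_x, state.anchor_y, state.anchor_ux, state.anchor_uy,
        state.mem_y, state.mem_left,
        state.mem_right, state.mo_f, state.mo_s, state.cl_f, state.cl_s,
        ffx, ffy, fml, fmr, mo_ft, mo_fm, cl_fm, xlh, gc, gi,
    )
    return ffx, ffy
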