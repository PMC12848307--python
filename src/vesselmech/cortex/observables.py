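"""Measurements on simulation states: virial stress, circumferential
alignment, vessel width, and potential energy.

The 2D virial stress is sigma_ab = (1/A) * sum_{i>j} f_ij,a * r_ij,b over
interacting pairs, with tensile (stretched-spring) contributions positive
on the diagonal.  The pair ledger contains the harmonic interactions:
filament stretching springs and motor/crosslinker link springs (bending,
anchor pins and wall confinement are not pairwise central forces and are
excluded).  Region filtering is by pair midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import _head_point  # rest-length head parametrisation
from .state import SimulationState

__all__ = [
    "Region",
    "StressTensor",
    "pair_force_ledger",
    "compute_stress",
    "compute_alignment",
    "vessel_width",
    "potential_energy",
    "central_region",
    "peripheral_regions",
]


@dataclass(frozen=True)
class Region:
    """Axis-aligned rectangle (x0, x1, y0, y1) in unwrapped-x, wrapped-y
    coordinates."""

    x0: float
    x1: float
    y0: float
    y1: float

    @property
    def area(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    def contains(self, x, y, Ly):
        yw = np.mod(y, Ly)
        return (x >= self.x0) & (x < self.x1) & (yw >= self.y0) & (yw < self.y1)


@dataclass(frozen=True)
class StressTensor:
    sigma_xx: float
    sigma_yy: float
    sigma_xy: float
    region: Region
    window: float = 0.0   # s; 0 = instantaneous, >0 = sliding-average width


def central_region(state_or_params, band: float | None = None) -> Region:
    """The bundle readout region: full circumferential width crossed with
    the anchored y-band where bundles are seeded (bundles grow inward
    from the anchors, so the readout spans wall to wall)."""
    p = getattr(state_or_params, "params", state_or_params)
    b = p.anchored_band if band is None else band
    return Region(0.0, p.Lx, (p.Ly - b) / 2.0, (p.Ly + b) / 2.0)


def peripheral_regions(state_or_params, band: float | None = None) -> list[Region]:
    """Full-width complement of the central band."""
    p = getattr(state_or_params, "params", state_or_params)
    b = p.anchored_band if band is None else band
    return [Region(0.0, p.Lx, 0.0, (p.Ly - b) / 2.0),
            Region(0.0, p.Lx, (p.Ly + b) / 2.0, p.Ly)]


def _min_img(dy, Ly):
    return dy - Ly * np.round(dy / Ly)


def pair_force_ledger(state: SimulationState):
    """All pairwise central-force interactions of the current state.

    Returns arrays (xi, yi, xj, yj, fijx, fijy) where (fijx, fijy) is the
    force exerted on particle j by particle i and r_ij = r_i - r_j (y by
    minimum image).
    """
    p = state.params
    l0 = p.segment_rest_length
    xi, yi, xj, yj, fx_, fy_ = [], [], [], [], [], []

    # filament stretching springs
    for f in range(state.n_filaments):
        n = int(state.fn[f])
        ax, ay = state.fx[f, : n - 1], state.fy[f, : n - 1]
        bx, by = state.fx[f, 1:n], state.fy[f, 1:n]
        dx, dy = bx - ax, by - ay
        d = np.hypot(dx, dy)
        good = d > 1e-12
        tension = p.stretch_stiffness * (d - l0)
        # force on bead j(=a) by bead i(=b): pulls a toward b when stretched
        with np.errstate(invalid="ignore", divide="ignore"):
            ux, uy = np.where(good, dx / d, 0.0), np.where(good, dy / d, 0.0)
        xi.append(bx); yi.append(by); xj.append(ax); yj.append(ay)
        fx_.append(tension * ux); fy_.append(tension * uy)

    def link_pairs(ent_f, ent_s):
        for m in range(ent_f.shape[0]):
            f0, f1 = int(ent_f[m, 0]), int(ent_f[m, 1])
            if f0 < 0 or f1 < 0:
                continue
            x0, y0, *_ = _head_point(state.fx, state.fy, state.fn, f0,
                                     float(ent_s[m, 0]), l0)
            x1, y1, *_ = _head_point(state.fx, state.fy, state.fn, f1,
                                     float(ent_s[m, 1]), l0)
            dx = x1 - x0
            dy = float(_min_img(np.array(y1 - y0), p.Ly))
            d = np.hypot(dx, dy)
            if d < 1e-12:
                continue
            fmag = p.link_stiffness * (d - p.link_rest_length)
            # force on head 0 (j) by head 1 (i)
            xi.append(np.array([x0 + dx])); yi.append(np.array([y0 + dy]))
            xj.append(np.array([x0])); yj.append(np.array([y0]))
            fx_.append(np.array([fmag * dx / d]))
            fy_.append(np.array([fmag * dy / d]))

    link_pairs(state.mo_f, state.mo_s)
    link_pairs(state.cl_f, state.cl_s)

    return (np.concatenate(xi), np.concatenate(yi), np.concatenate(xj),
            np.concatenate(yj), np.concatenate(fx_), np.concatenate(fy_))


def compute_stress(state: SimulationState, region: Region | None = None,
                   ledger=None) -> StressTensor:
    """Instantaneous virial stress over a region (default: whole domain).

    sigma_ab = (1/A) sum_pairs f_ij,a * r_ij,b, restricted to pairs whose
    midpoint lies in the region, divided by the region area.
    """
    p = state.params
    if region is None:
        region = Region(0.0, p.Lx, 0.0, p.Ly)
    if region.area <= 0:
        raise ValueError("empty region")
    if ledger is None:
        ledger = pair_force_ledger(state)
    xi, yi, xj, yj, fijx, fijy = ledger
    rx = xi - xj
    ry = _min_img(yi - yj, p.Ly)
    mx = 0.5 * (xi + xj)
    my = yj + 0.5 * ry
    sel = region.contains(mx, my, p.Ly)
    A = region.area
    return StressTensor(
        sigma_xx=float(np.sum(fijx[sel] * rx[sel]) / A),
        sigma_yy=float(np.sum(fijy[sel] * ry[sel]) / A),
        sigma_xy=float(np.sum(0.5 * (fijx[sel] * ry[sel] + fijy[sel] * rx[sel])) / A),
        region=region,
    )


def compute_alignment(state: SimulationState, region: Region) -> tuple[float, int]:
    """Circumferential alignment N_x^2 = sum_i n_ix^2 over the unit
    orientations of segments whose midpoint lies in the region, plus the
    segment count S.  N_x^2 + N_y^2 = S exactly."""
    x0, y0, x1, y1 = state.segments()
    dx, dy = x1 - x0, y1 - y0
    d = np.hypot(dx, dy)
    good = d > 1e-12
    mx, my = 0.5 * (x0 + x1), 0.5 * (y0 + y1)
    sel = good & region.contains(mx, my, state.params.Ly)
    nx2 = float(np.sum((dx[sel] / d[sel]) ** 2))
    return nx2, int(np.count_nonzero(sel))


def vessel_width(state: SimulationState, region: Region | None = None) -> float:
    """Mean left-right membrane gap over the region's y-range (linear
    membrane interpolation, trapezoidal mean).  Fixed walls return Lx."""
    p = state.params
    if p.boundary_mode != "deformable_membrane":
        return p.Lx
    if region is None:
        region = central_region(state)
    y = np.linspace(region.y0, region.y1, 65)
    xl = np.interp(y, state.mem_y, state.mem_left)
    xr = np.interp(y, state.mem_y, state.mem_right)
    gap = xr - xl
    if np.any(gap <= 0):
        raise ValueError("membrane collision")
    return float(np.trapezoid(gap, y) / (region.y1 - region.y0))


def potential_energy(state: SimulationState) -> float:
    """Total elastic energy: filament stretch + bending, link springs,
    membrane stretch/bending/foundation.  Used as a bookkeeping oracle —
    with motors and noise off it must not increase."""
    p = state.params
    l0 = p.segment_rest_length
    E = 0.0
    for f in range(state.n_filaments):
        n = int(state.fn[f])
        dx = np.diff(state.fx[f, :n])
        dy = np.diff(state.fy[f, :n])
        d = np.hypot(dx, dy)
        E += 0.5 * p.stretch_stiffness * np.sum((d - l0) ** 2)
        if n >= 3:
            ux, uy = dx[:-1], dy[:-1]
            vx, vy = dx[1:], dy[1:]
            c = (ux * vx + uy * vy) / (np.hypot(ux, uy) * np.hypot(vx, vy))
            E += (p.bending_rigidity / l0) * np.sum(1.0 - np.clip(c, -1, 1))
    for ent_f, ent_s in ((state.mo_f, state.mo_s), (state.cl_f, state.cl_s)):
        for m in range(ent_f.shape[0]):
            f0, f1 = int(ent_f[m, 0]), int(ent_f[m, 1])
            if f0 < 0 or f1 < 0:
                continue
            x0, y0, *_ = _head_point(state.fx, state.fy, state.fn, f0,
                                     float(ent_s[m, 0]), l0)
            x1, y1, *_ = _head_point(state.fx, state.fy, state.fn, f1,
                                     float(ent_s[m, 1]), l0)
            d = np.hypot(x1 - x0, float(_min_img(np.array(y1 - y0), p.Ly)))
            E += 0.5 * p.link_stiffness * (d - p.link_rest_length) ** 2
    if p.boundary_mode == "deformable_membrane":
        ds = p.membrane_spacing
        for mx, rest in ((state.mem_left, 0.0), (state.mem_right, p.Lx)):
            seg = np.hypot(np.diff(mx), ds)
            E += 0.5 * p.membrane_stretch * np.sum((seg - ds) ** 2)
            lap = mx[:-2] - 2 * mx[1:-1] + mx[2:]
            E += 0.5 * (p.membrane_bending / ds**3) * np.sum(lap**2)
            E += 0.5 * p.foundation_stiffness * np.sum((mx - rest) ** 2)
    return float(E)
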