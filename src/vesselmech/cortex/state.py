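"""Simulation state: filaments, motors, crosslinkers and membranes as
flat numpy arrays (the layout the compiled stepping kernel operates on).

Filaments are bead chains ordered minus end -> plus end, stored in fixed
slabs of ``MAX_BEADS`` beads.  Anchor codes: 0 free, 1/2 pinned to the
left/right membrane bead ``anchor_idx``, 3 pinned to the fixed point
(anchor_x, anchor_y) (midline mode).  The anchor clamps the end segment
(beads 0 and 1), fixing the filament's direction at the pin along
(anchor_ux, anchor_uy); the distal part flexes freely.  Motor/crosslinker heads store the
filament index (-1 when unbound) and the arc position from the minus end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import MAX_BEADS, SimParams

__all__ = ["SimulationState", "init_state"]

FREE, ANCH_LEFT, ANCH_RIGHT, ANCH_FIXED = 0, 1, 2, 3


@dataclass
class SimulationState:
    params: SimParams
    time: float
    # filaments
    fx: np.ndarray            # (NF, MAX_BEADS)
    fy: np.ndarray
    fn: np.ndarray            # (NF,) bead counts
    anchor_code: np.ndarray   # (NF,)
    anchor_idx: np.ndarray    # (NF,) membrane bead index
    anchor_x: np.ndarray      # (NF,) fixed anchor point
    anchor_y: np.ndarray
    anchor_ux: np.ndarray     # (NF,) clamped anchor direction (unit)
    anchor_uy: np.ndarray
    # membranes (x positions per bead; y grid fixed)
    mem_y: np.ndarray         # (ML,)
    mem_left: np.ndarray      # (ML,)
    mem_right: np.ndarray     # (ML,)
    # motors / crosslinkers: head filament (-1 unbound) and arc position
    mo_f: np.ndarray          # (NM, 2) int64
    mo_s: np.ndarray          # (NM, 2) float64
    cl_f: np.ndarray          # (NC, 2)
    cl_s: np.ndarray          # (NC, 2)

    @property
    def n_filaments(self) -> int:
        return self.fx.shape[0]

    def segments(self):
        """All segment endpoints as arrays (x0, y0, x1, y1), minus->plus."""
        xs0, ys0, xs1, ys1 = [], [], [], []
        for f in range(self.n_filaments):
            n = int(self.fn[f])
            xs0.append(self.fx[f, : n - 1])
            ys0.append(self.fy[f, : n - 1])
            xs1.append(self.fx[f, 1:n])
            ys1.append(self.fy[f, 1:n])
        return (np.concatenate(xs0), np.concatenate(ys0),
                np.concatenate(xs1), np.concatenate(ys1))

    def copy(self) -> "SimulationState":
        return SimulationState(
            params=self.params, time=self.time,
            fx=self.fx.copy(), fy=self.fy.copy(), fn=self.fn.copy(),
            anchor_code=self.anchor_code.copy(),
            anchor_idx=self.anchor_idx.copy(),
            anchor_x=self.anchor_x.copy(), anchor_y=self.anchor_y.copy(),
            anchor_ux=self.anchor_ux.copy(), anchor_uy=self.anchor_uy.copy(),
            mem_y=self.mem_y.copy(), mem_left=self.mem_left.copy(),
            mem_right=self.mem_right.copy(),
            mo_f=self.mo_f.copy(), mo_s=self.mo_s.copy(),
            cl_f=self.cl_f.copy(), cl_s=self.cl_s.copy(),
        )


def init_state(params: SimParams) -> SimulationState:
    """Initial configuration: free filaments uniformly placed with uniform
    random orientations; anchored filaments pinned by their minus end to
    membrane beads (oriented inward along x, alternating sides, evenly
    spaced in the central band) or to midline points (oriented along y);
    motors and crosslinkers start unbound.  Deterministic per seed."""
    p = params
    rng = np.random.default_rng(p.seed)
    NF = p.n_filaments
    l0 = p.segment_rest_length

    fx = np.zeros((NF, MAX_BEADS))
    fy = np.zeros((NF, MAX_BEADS))
    fn = np.zeros(NF, dtype=np.int64)
    anchor_code = np.zeros(NF, dtype=np.int64)
    anchor_idx = np.zeros(NF, dtype=np.int64)
    anchor_x = np.zeros(NF)
    anchor_y = np.zeros(NF)
    anchor_ux = np.zeros(NF)
    anchor_uy = np.zeros(NF)

    # membranes: beads on a fixed y grid, endpoints pinned
    ML = int(round(p.Ly / p.membrane_spacing)) + 1
    mem_y = np.linspace(0.0, p.Ly, ML)
    mem_left = np.zeros(ML)
    mem_right = np.full(ML, p.Lx)

    n_anch = p.n_anchored if p.anchoring_mode != "none" else 0
    anch_segs = max(1, int(round(p.anchored_length / l0)))
    if anch_segs + 1 > MAX_BEADS:
        raise ValueError("anchored_length too long for the bead slab")
    band_lo = (p.Ly - p.anchored_band) / 2.0
    if p.anchoring_mode == "longitudinal_membrane":
        # facing left/right pairs at matched y, so bundles can bridge the
        # anchored filaments on opposite sides
        n_pairs = max(1, (n_anch + 1) // 2)
        pair_y = band_lo + (np.arange(n_pairs) + 0.5) * (p.anchored_band / n_pairs)
        band_y = np.repeat(pair_y, 2)[:n_anch]
    else:
        band_y = band_lo + (np.arange(max(n_anch, 1)) + 0.5) * (
            p.anchored_band / max(n_anch, 1)
        )

    for f in range(n_anch):
        fn[f] = anch_segs + 1
        yb = band_y[f]
        if p.anchoring_mode == "longitudinal_membrane":
            side = f % 2  # alternate left/right
            idx = int(np.argmin(np.abs(mem_y - yb)))
            anchor_code[f] = ANCH_LEFT if side == 0 else ANCH_RIGHT
            anchor_idx[f] = idx
            x0 = mem_left[idx] if side == 0 else mem_right[idx]
            direction = 1.0 if side == 0 else -1.0  # inward along x
            fx[f, : fn[f]] = x0 + direction * l0 * np.arange(fn[f])
            fy[f, : fn[f]] = mem_y[idx]
            anchor_ux[f] = direction
        else:  # midline, oriented along y (alternating up/down)
            anchor_code[f] = ANCH_FIXED
            anchor_x[f] = p.Lx / 2.0
            anchor_y[f] = yb
            direction = 1.0 if f % 2 == 0 else -1.0
            fx[f, : fn[f]] = p.Lx / 2.0
            fy[f, : fn[f]] = yb + direction * l0 * np.arange(fn[f])
            anchor_uy[f] = direction

    # free filaments: straight, random midpoint and orientation
    margin = 0.2
    for f in range(n_anch, NF):
        nseg = int(rng.integers(p.min_segments, p.max_segments + 1))
        fn[f] = nseg + 1
        length = nseg * l0
        theta = rng.uniform(0.0, np.pi)
        cx = rng.uniform(margin + length / 2, p.Lx - margin - length / 2)
        cy = rng.uniform(0.0, p.Ly)
        t = (np.arange(nseg + 1) - nseg / 2.0) * l0
        fx[f, : nseg + 1] = cx + t * np.cos(theta)
        fy[f, : nseg + 1] = cy + t * np.sin(theta)
    if 2 * (margin + p.max_segments * l0 / 2) >= p.Lx:
        raise ValueError("overcrowded initialization: domain too narrow")

    return SimulationState(
        params=p, time=0.0,
        fx=fx, fy=fy, fn=fn,
        anchor_code=anchor_code, anchor_idx=anchor_idx,
        anchor_x=anchor_x, anchor_y=anchor_y,
        anchor_ux=anchor_ux, anchor_uy=anchor_uy,
        mem_y=mem_y, mem_left=mem_left, mem_right=mem_right,
        mo_f=np.full((p.n_motors, 2), -1, dtype=np.int64),
        mo_s=np.zeros((p.n_motors, 2)),
        cl_f=np.full((p.n_crosslinkers, 2), -1, dtype=np.int64),
        cl_s=np.zeros((p.n_crosslinkers, 2)),
    )
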