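"""Strain decomposition of vessel remodelling.

For a geometric quantity X measured at two timepoints the strain is
``eps_X = (X2 - X1)/X1``.  Vessel strain (from diameter D radially, length
L axially) decomposes multiplicatively into a cell-deformation part (from
cell width w / length l) and a cell-number part (from the effective cell
numbers N_eff = pi*D/w and L/l):

    (1 + eps_D) = (1 + eps_w) * (1 + eps_N,radial)
    (1 + eps_L) = (1 + eps_l) * (1 + eps_N,axial)

Both identities are exact when all quantities are computed from the same
group means, which is how this module computes them: cells are not tracked
across days, so strains compare per-stage population averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .morphometrics import effective_cell_numbers

__all__ = [
    "GroupSummary",
    "IntervalStrains",
    "strain",
    "summarize_group",
    "decompose_interval",
    "label_mechanism",
    "strains_to_frame",
]


def strain(X1: float, X2: float) -> float:
    """Relative change (X2 - X1)/X1 between two timepoints."""
    if X1 <= 0:
        raise ValueError("invalid reference value: X1 must be positive")
    return (X2 - X1) / X1


@dataclass(frozen=True)
class GroupSummary:
    """Population means of vessel and cell geometry at one timepoint."""

    timepoint: str
    mean_D: float
    mean_L: float
    mean_w: float
    mean_l: float
    n_vessels: int
    n_cells: int

    def __post_init__(self):
        if min(self.mean_D, self.mean_L, self.mean_w, self.mean_l) <= 0:
            raise ValueError("group means must be positive")
        if self.n_vessels < 1 or self.n_cells < 1:
            raise ValueError("counts must be at least 1")


@dataclass(frozen=True)
class IntervalStrains:
    """The six strains between two timepoints, radial and axial."""

    interval: tuple[str, str]
    eps_vessel_radial: float
    eps_vessel_axial: float
    eps_cell_radial: float
    eps_cell_axial: float
    eps_number_radial: float
    eps_number_axial: float

    @property
    def radial_residual(self) -> float:
        """(1+eps_D) - (1+eps_w)(1+eps_N,rad); zero up to rounding."""
        return (1 + self.eps_vessel_radial) - (1 + self.eps_cell_radial) * (
            1 + self.eps_number_radial
        )

    @property
    def axial_residual(self) -> float:
        return (1 + self.eps_vessel_axial) - (1 + self.eps_cell_axial) * (
            1 + self.eps_number_axial
        )


def summarize_group(
    vessels: pd.DataFrame, cells: pd.DataFrame, timepoint: str
) -> GroupSummary:
    """Arithmetic means of D, L, w, l over all vessels/cells at a timepoint.

    ``vessels`` needs columns (vessel_id, timepoint, diameter_um, length_um);
    ``cells`` needs (cell_id, timepoint, width_um, length_um) — see
    :func:`vesselmech.morphometrics.cell_table_from_measurements`.
    """
    v = vessels[vessels["timepoint"] == timepoint]
    c = cells[cells["timepoint"] == timepoint]
    if len(v) == 0 or len(c) == 0:
        raise ValueError(f"no observations at timepoint {timepoint!r}")
    return GroupSummary(
        timepoint=timepoint,
        mean_D=float(v["diameter_um"].mean()),
        mean_L=float(v["length_um"].mean()),
        mean_w=float(c["width_um"].mean()),
        mean_l=float(c["length_um"].mean()),
        n_vessels=len(v),
        n_cells=len(c),
    )


def decompose_interval(s1: GroupSummary, s2: GroupSummary) -> IntervalStrains:
    """Six strains between two group summaries.

    N_eff at each timepoint is recomputed from that timepoint's mean D, L,
    w, l, which makes the multiplicative decomposition identities exact.
    """
    n1 = effective_cell_numbers(s1.mean_D, s1.mean_L, s1.mean_w, s1.mean_l)
    n2 = effective_cell_numbers(s2.mean_D, s2.mean_L, s2.mean_w, s2.mean_l)
    return IntervalStrains(
        interval=(s1.timepoint, s2.timepoint),
        eps_vessel_radial=strain(s1.mean_D, s2.mean_D),
        eps_vessel_axial=strain(s1.mean_L, s2.mean_L),
        eps_cell_radial=strain(s1.mean_w, s2.mean_w),
        eps_cell_axial=strain(s1.mean_l, s2.mean_l),
        eps_number_radial=strain(n1.radial, n2.radial),
        eps_number_axial=strain(n1.axial, n2.axial),
    )


def _role(component: float, vessel: float, tol: float) -> str:
    if abs(component) <= tol or abs(vessel) <= tol:
        return "neutral"
    return "contributing" if np.sign(component) == np.sign(vessel) else "opposing"


def label_mechanism(strains: IntervalStrains, tol: float = 0.02) -> dict:
    """Tag cell-deformation and cell-number contributions per axis.

    Each of {cell, number} is labelled contributing / opposing / neutral
    relative to the sign of the vessel strain on that axis, with a
    dead-band ``tol`` below which a strain counts as neutral.  E.g. a
    radial constriction with cells widening but strong radial-to-axial
    rearrangement is "constriction via rearrangement opposed by cell
    widening".
    """
    out = {}
    for axis, ev, ec, en in [
        ("radial", strains.eps_vessel_radial, strains.eps_cell_radial,
         strains.eps_number_radial),
        ("axial", strains.eps_vessel_axial, strains.eps_cell_axial,
         strains.eps_number_axial),
    ]:
        if ev < -tol:
            vessel = "constriction" if axis == "radial" else "shortening"
        elif ev > tol:
            vessel = "dilation" if axis == "radial" else "elongation"
        else:
            vessel = "neutral"
        out[axis] = {
            "vessel": vessel,
            "cell": _role(ec, ev, tol),
            "number": _role(en, ev, tol),
        }
    return out


def strains_to_frame(intervals: list[IntervalStrains]) -> pd.DataFrame:
    """Long-format table of strains, one row per (interval, axis)."""
    rows = []
    for s in intervals:
        rows.append(
            dict(interval=f"{s.interval[0]}->{s.interval[1]}", axis="radial",
                 eps_vessel=s.eps_vessel_radial, eps_cell=s.eps_cell_radial,
                 eps_number=s.eps_number_radial,
                 identity_residual=s.radial_residual)
        )
        rows.append(
            dict(interval=f"{s.interval[0]}->{s.interval[1]}", axis="axial",
                 eps_vessel=s.eps_vessel_axial, eps_cell=s.eps_cell_axial,
                 eps_number=s.eps_number_axial,
                 identity_residual=s.axial_residual)
        )
    return pd.DataFrame(rows)
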