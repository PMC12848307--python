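"""Vessel- and cell-level geometric measurements.

Vessel diameter is estimated from a fluorescence intensity profile drawn
perpendicularly across the vessel: the two wall peaks are located, the
half-maximum crossings of each wall define a wall centre, and the diameter
is the centre-to-centre distance.  Cell width ``w`` and length ``l`` are
derived from the segmented cell area ``a`` and aspect ratio ``r`` via
``w = sqrt(a/r)``, ``l = sqrt(r*a)``, and effective cell numbers along the
radial and axial axes are ``pi*D/w`` and ``L/l``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "IntensityProfile",
    "DiameterEstimate",
    "VesselGeometry",
    "CellShapeRecord",
    "EffectiveCellNumber",
    "WallsNotFoundError",
    "WallsUnresolvableError",
    "diameter_from_profile",
    "mean_diameter",
    "polyline_length",
    "cell_width_length",
    "effective_cell_numbers",
    "cell_table_from_measurements",
    "profile_from_image",
]


class WallsNotFoundError(ValueError):
    """Fewer than two wall peaks with the required prominence."""


class WallsUnresolvableError(ValueError):
    """The two walls' half-maximum intervals overlap."""


@dataclass(frozen=True)
class IntensityProfile:
    """A 1D intensity profile sampled along a line, positions in micrometres."""

    positions: np.ndarray
    intensities: np.ndarray
    pixel_size: float

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if pos.ndim != 1 or inten.ndim != 1 or pos.size != inten.size:
            raise ValueError("positions and intensities must be 1D and equal length")
        if pos.size >= 2 and not np.all(np.diff(pos) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)


@dataclass(frozen=True)
class DiameterEstimate:
    diameter: float
    wall_positions: tuple[float, float]
    n_profiles_averaged: int = 1


@dataclass(frozen=True)
class VesselGeometry:
    vessel_id: str
    timepoint: str
    diameter: float
    length: float
    ec_count: int | None = None

    def __post_init__(self):
        if self.diameter <= 0 or self.length <= 0:
            raise ValueError("diameter and length must be positive")
        if self.ec_count is not None and self.ec_count < 0:
            raise ValueError("ec_count must be non-negative")


@dataclass(frozen=True)
class CellShapeRecord:
    """Per-cell area/aspect ratio with derived radial width and axial length."""

    cell_id: str
    timepoint: str
    area: float
    aspect_ratio: float
    width: float = field(init=False)
    length: float = field(init=False)

    def __post_init__(self):
        w, l = cell_width_length(self.area, self.aspect_ratio)
        object.__setattr__(self, "width", w)
        object.__setattr__(self, "length", l)


@dataclass(frozen=True)
class EffectiveCellNumber:
    radial: float
    axial: float

    def __post_init__(self):
        if self.radial <= 0 or self.axial <= 0:
            raise ValueError("effective cell numbers must be positive")


def _baseline(intensities: np.ndarray, edge_fraction: float = 0.1) -> float:
    # robust baseline: median of the outer 10% of samples on each side
    n = intensities.size
    k = max(1, int(round(edge_fraction * n)))
    edges = np.concatenate([intensities[:k], intensities[-k:]])
    return float(np.median(edges))


def _half_max_crossings(pos, inten, peak_idx, half):
    """Linear-interpolated positions where the profile crosses ``half`` on
    either side of ``peak_idx``, scanning outward from the peak."""
    left = None
    for i in range(peak_idx, 0, -1):
        if inten[i - 1] <= half <= inten[i]:
            t = (half - inten[i - 1]) / (inten[i] - inten[i - 1])
            left = pos[i - 1] + t * (pos[i] - pos[i - 1])
            break
    right = None
    for i in range(peak_idx, len(inten) - 1):
        if inten[i + 1] <= half <= inten[i]:
            t = (inten[i] - half) / (inten[i] - inten[i + 1])
            right = pos[i] + t * (pos[i + 1] - pos[i])
            break
    return left, right


def diameter_from_profile(
    profile: IntensityProfile, min_prominence: float = 0.2
) -> DiameterEstimate:
    """Estimate vessel diameter from a profile with two wall peaks.

    Parameters
    ----------
    profile
        Intensity profile across the vessel with baseline-dominated ends.
    min_prominence
        Minimum peak prominence, as a fraction of (max - baseline).

    Returns
    -------
    DiameterEstimate
        Wall centres are the midpoints of each wall's half-maximum
        crossings; the diameter is their separation.
    """
    pos, inten = profile.positions, profile.intensities
    if pos.size < 8:
        raise ValueError("profile too short: need at least 8 samples")
    base = _baseline(inten)
    amplitude = float(inten.max() - base)
    if amplitude <= 0:
        raise WallsNotFoundError("walls not found: profile is flat")
    peaks, props = find_peaks(inten, prominence=min_prominence * amplitude)
    if peaks.size < 2:
        raise WallsNotFoundError(
            f"walls not found: {peaks.size} peak(s) at prominence "
            f">= {min_prominence:.2f} of amplitude"
        )
    # two most prominent peaks are taken as the vessel walls
    order = np.argsort(props["prominences"])[::-1][:2]
    walls = np.sort(peaks[order])
    centers = []
    intervals = []
    for pk in walls:
        half = base + 0.5 * (inten[pk] - base)
        left, right = _half_max_crossings(pos, inten, pk, half)
        if left is None or right is None:
            raise WallsUnresolvableError(
                "walls unresolvable: half-maximum crossing not found"
            )
        centers.append(0.5 * (left + right))
        intervals.append((left, right))
    if intervals[0][1] > intervals[1][0]:
        raise WallsUnresolvableError("walls unresolvable: half-max intervals overlap")
    c1, c2 = centers
    return DiameterEstimate(diameter=abs(c2 - c1), wall_positions=(c1, c2))


def mean_diameter(
    estimates: list[DiameterEstimate], strict: bool = False
) -> DiameterEstimate:
    """Average repeated diameter measurements of the same vessel.

    At least three measurements per vessel are expected; fewer raises a
    warning (or an error when ``strict``).
    """
    if len(estimates) == 0:
        raise ValueError("no estimates to average")
    if len(estimates) < 3:
        msg = f"insufficient measurements: {len(estimates)} < 3"
        if strict:
            raise ValueError(msg)
        import warnings

        warnings.warn(msg, stacklevel=2)
    d = float(np.mean([e.diameter for e in estimates]))
    w0 = float(np.mean([e.wall_positions[0] for e in estimates]))
    w1 = float(np.mean([e.wall_positions[1] for e in estimates]))
    return DiameterEstimate(d, (w0, w1), n_profiles_averaged=len(estimates))


def polyline_length(points) -> float:
    """Length of a polyline traced along the vessel spine (2D or 3D)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("degenerate polyline: need at least 2 points")
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def cell_width_length(a: float, r: float) -> tuple[float, float]:
    """Radial width and axial length of a cell from area and aspect ratio.

    ``w = sqrt(a/r)``, ``l = sqrt(r*a)``; hence ``w*l = a`` and ``l/w = r``.
    """
    if a <= 0 or r <= 0:
        raise ValueError("invalid shape: area and aspect ratio must be positive")
    return float(np.sqrt(a / r)), float(np.sqrt(r * a))


def effective_cell_numbers(D: float, L: float, w: float, l: float) -> EffectiveCellNumber:
    """Number of cells spanning the circumference (``pi*D/w``) and the
    vessel length (``L/l``)."""
    if min(D, L, w, l) <= 0:
        raise ValueError("invalid geometry: all inputs must be positive")
    return EffectiveCellNumber(radial=np.pi * D / w, axial=L / l)


def cell_table_from_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Attach derived width/length columns to a (cell_id, timepoint,
    area_um2, aspect_ratio) table."""
    out = df.copy()
    a = out["area_um2"].to_numpy(float)
    r = out["aspect_ratio"].to_numpy(float)
    if np.any(a <= 0) or np.any(r <= 0):
        raise ValueError("invalid shape: area and aspect ratio must be positive")
    out["width_um"] = np.sqrt(a / r)
    out["length_um"] = np.sqrt(r * a)
    return out


def profile_from_image(
    image: np.ndarray,
    start: tuple[float, float],
    end: tuple[float, float],
    pixel_size: float,
) -> IntensityProfile:
    """Extract an intensity profile along a line of a 2D image.

    ``start``/``end`` are (row, col) pixel coordinates; positions are
    returned in micrometres along the line.
    """
    from skimage.measure import profile_line

    values = profile_line(image, start, end, mode="constant", order=1)
    positions = np.arange(values.size) * pixel_size
    return IntensityProfile(positions, values, pixel_size)
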