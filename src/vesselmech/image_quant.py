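"""Intensity-trace and kymograph quantifications.

Covers the image-derived measurements around the vessel-constriction
analysis: background subtraction and log10 max-min normalization of
actin/myosin traces, junction-to-cortex intensity ratios, laser-ablation
recoil velocimetry from kymographs (gap edge tracing, mean velocity over
the first 10 s, three-ROI averaging), cross-correlation lag estimation,
and a structure-tensor classifier for cortical actin organisation
(circumferential / mesh / longitudinal).  The classifier is an explicitly
approximate automated stand-in for manual annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "IntensityTrace",
    "Kymograph",
    "RecoilResult",
    "JunctionCortexMeasurement",
    "OrientationCall",
    "background_subtract",
    "log_minmax_normalize",
    "junction_cortex_ratio",
    "trace_gap_edges",
    "recoil_velocity",
    "recoil_from_rois",
    "crosscorr_curve",
    "crosscorr_lag",
    "classify_orientation",
    "combine_views",
]


@dataclass(frozen=True)
class IntensityTrace:
    times: np.ndarray
    values: np.ndarray
    channel: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size != v.size:
            raise ValueError("times and values must have equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class Kymograph:
    """Space x time intensity matrix along a line ROI."""

    matrix: np.ndarray             # shape (n_space, n_time)
    pixel_size: float              # um/px along the space axis
    frame_interval: float          # s
    ablation_frame: int = 0

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("kymograph matrix must be 2D (space x time)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not (0 <= self.ablation_frame < m.shape[1]):
            raise ValueError("ablation_frame out of range")
        object.__setattr__(self, "matrix", m)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.matrix.shape[1]) * self.frame_interval


@dataclass(frozen=True)
class RecoilResult:
    per_roi_velocity: tuple[float, ...]
    mean_velocity: float
    window: float


@dataclass(frozen=True)
class JunctionCortexMeasurement:
    """Mean intensities of manually drawn ROIs for one vessel: junctional,
    cortical, and background regions (default 6 / 10 / 2)."""

    junction_means: np.ndarray
    cortex_means: np.ndarray
    background_means: np.ndarray

    def __post_init__(self):
        for name in ("junction_means", "cortex_means", "background_means"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))


@dataclass(frozen=True)
class OrientationCall:
    label: str                 # C, M or L
    dominant_angle: float      # degrees, 0 = vessel long axis
    coherence: float           # [0, 1]


def background_subtract(trace: IntensityTrace, background_mean: float) -> IntensityTrace:
    """Shift a trace by the mean of a background region."""
    if not np.isfinite(background_mean):
        raise ValueError("background_mean must be finite")
    return IntensityTrace(trace.times, trace.values - background_mean, trace.channel)


def log_minmax_normalize(
    trace: IntensityTrace, floor_fraction: float = 1e-4
) -> IntensityTrace:
    """log10 then max-min scale a trace onto [0, 1].

    Values at or below ``floor_fraction * max`` (e.g. negatives left by
    background subtraction) are clipped to the floor before the log, with
    a warning, preserving monotonicity.
    """
    v = trace.values
    if v.size < 2:
        raise ValueError("need at least 2 samples")
    vmax = float(v.max())
    if vmax <= 0:
        raise ValueError("zero dynamic range: no positive values")
    floor = floor_fraction * vmax
    if np.any(v < floor):
        warnings.warn("clipping values below the log floor", stacklevel=2)
        v = np.clip(v, floor, None)
    logv = np.log10(v)
    rng = logv.max() - logv.min()
    if rng == 0:
        raise ValueError("zero dynamic range: constant series")
    return IntensityTrace(trace.times, (logv - logv.min()) / rng, trace.channel)


def junction_cortex_ratio(m: JunctionCortexMeasurement) -> float:
    """log10 ratio of mean junctional to mean cortical intensity, each
    background-subtracted; one value per vessel."""
    bg = float(m.background_means.mean())
    j = float(m.junction_means.mean()) - bg
    c = float(m.cortex_means.mean()) - bg
    if j <= 0 or c <= 0:
        raise ValueError("signal below background")
    return float(np.log10(j / c))


# ------------------------------------------------------------- recoil analysis

def trace_gap_edges(k: Kymograph, threshold_fraction: float = 0.5) -> np.ndarray:
    """Per-frame gap distance (um) between the ablation gap's edges.

    For each post-ablation time column, the gap edges are the inner
    crossings, nearest the intensity minimum, of a threshold set at
    ``threshold_fraction`` of the way from the local minimum up to each
    flanking maximum; crossings are located to sub-pixel precision by
    linear interpolation.  Frames before the ablation, or columns without
    a resolvable gap, are NaN.
    """
    n_space, n_time = k.matrix.shape
    x = np.arange(n_space) * k.pixel_size
    gaps = np.full(n_time, np.nan)
    for j in range(k.ablation_frame, n_time):
        col = k.matrix[:, j]
        i_min = int(np.argmin(col))
        if i_min == 0 or i_min == n_space - 1:
            continue
        v_min = col[i_min]
        left_flank = col[: i_min + 1].max()
        right_flank = col[i_min:].max()
        # require real contrast between gap and flanks
        contrast = min(left_flank, right_flank) - v_min
        if contrast <= 0.2 * (col.max() - col.min()):
            continue
        thr_l = v_min + threshold_fraction * (left_flank - v_min)
        thr_r = v_min + threshold_fraction * (right_flank - v_min)
        xl = xr = None
        for i in range(i_min, 0, -1):
            if col[i] <= thr_l <= col[i - 1]:
                t = (thr_l - col[i]) / (col[i - 1] - col[i])
                xl = x[i] - t * k.pixel_size
                break
        for i in range(i_min, n_space - 1):
            if col[i] <= thr_r <= col[i + 1]:
                t = (thr_r - col[i]) / (col[i + 1] - col[i])
                xr = x[i] + t * k.pixel_size
                break
        if xl is not None and xr is not None and xr > xl:
            gaps[j] = xr - xl
    return gaps


def recoil_velocity(
    times: np.ndarray,
    gaps: np.ndarray,
    ablation_time: float = 0.0,
    window: float = 10.0,
) -> tuple[float, float]:
    """Mean recoil velocity over the first ``window`` seconds after ablation.

    Primary estimate: gap displacement between the first and last valid
    frames of the window divided by the elapsed time — for uniform
    sampling this equals the mean of per-frame delta-d / delta-t.  A
    least-squares slope over the same frames is returned alongside as an
    independent cross-check.

    Returns
    -------
    (velocity, ls_slope) in um/s.
    """
    times = np.asarray(times, dtype=float)
    gaps = np.asarray(gaps, dtype=float)
    if window <= 0:
        raise ValueError("window must be positive")
    sel = (times >= ablation_time) & (times <= ablation_time + window) & np.isfinite(gaps)
    t, d = times[sel], gaps[sel]
    if t.size < 2:
        raise ValueError("window too short: fewer than 2 valid frames")
    velocity = (d[-1] - d[0]) / (t[-1] - t[0])
    ls_slope = float(np.polyfit(t, d, 1)[0])
    return float(velocity), ls_slope


def recoil_from_rois(
    roi_series: list[tuple[np.ndarray, np.ndarray]],
    ablation_time: float = 0.0,
    window: float = 10.0,
) -> RecoilResult:
    """Final mean recoil velocity of one vessel from (typically three)
    line-ROI gap series, averaging the per-ROI window velocities."""
    if len(roi_series) == 0:
        raise ValueError("need at least one ROI series")
    vels = tuple(
        recoil_velocity(t, d, ablation_time, window)[0] for t, d in roi_series
    )
    return RecoilResult(per_roi_velocity=vels,
                        mean_velocity=float(np.mean(vels)), window=window)


# --------------------------------------------------------- cross-correlation

def crosscorr_curve(
    a: np.ndarray,
    b: np.ndarray,
    frame_interval: float,
    max_lag: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized cross-correlation at every integer-frame shift.

    Returns (lags, correlations); positive lag means ``a`` leads ``b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("series must have equal length")
    n = a.size
    max_shift = int(np.floor(max_lag / frame_interval))
    if max_shift >= n // 2:
        raise ValueError("insufficient samples: max_lag >= half the record")
    if n - max_shift < 3:
        raise ValueError("insufficient samples")

    def corr_at(shift: int) -> float:
        if shift >= 0:
            x, y = a[: n - shift], b[shift:]
        else:
            x, y = a[-shift:], b[: n + shift]
        if x.std() == 0 or y.std() == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    shifts = np.arange(-max_shift, max_shift + 1)
    corrs = np.array([corr_at(s) for s in shifts])
    return shifts * frame_interval, corrs


def crosscorr_lag(
    a: np.ndarray,
    b: np.ndarray,
    frame_interval: float,
    max_lag: float,
    mode: str = "extremum",
) -> tuple[float, float]:
    """Lag of the normalized cross-correlation extremum between two series.

    Positive lag means ``a`` leads ``b``.  Pearson correlation is computed
    on the overlapping samples at each integer-frame lag, then the
    extremum is refined by parabolic interpolation of the correlation
    around the best integer lag.

    ``mode`` selects the extremum: ``"extremum"`` (largest |r|),
    ``"negative"`` (most negative r) or ``"positive"`` (largest r).

    Returns
    -------
    (lag, correlation): lag in time units, signed Pearson r at the extremum.
    """
    lag_grid, corrs = crosscorr_curve(a, b, frame_interval, max_lag)
    shifts = np.round(lag_grid / frame_interval).astype(int)
    if mode == "negative":
        i = int(np.argmin(corrs))
    elif mode == "positive":
        i = int(np.argmax(corrs))
    else:
        i = int(np.argmax(np.abs(corrs)))
    lag = shifts[i] * frame_interval
    peak = corrs[i]
    # a perfect discrete match needs no sub-sample correction
    if 0 < i < shifts.size - 1 and abs(abs(peak) - 1.0) > 1e-9:
        y0, y1, y2 = corrs[i - 1], corrs[i], corrs[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            delta = 0.5 * (y0 - y2) / denom
            if abs(delta) < 1:
                lag = (shifts[i] + delta) * frame_interval
                peak = y1 - 0.25 * (y0 - y2) * delta
    return float(lag), float(peak)


# ------------------------------------------------- orientation classification

def classify_orientation(
    image: np.ndarray,
    vessel_axis_angle: float = 0.0,
    coherence_threshold: float = 0.2,
    angle_band: float = 30.0,
    sigma: float = 2.0,
) -> OrientationCall:
    """Classify a cortical actin texture as C, M or L via the structure tensor.

    The gradient structure tensor is averaged over the image; its
    anisotropy (lambda1-lambda2)/(lambda1+lambda2) gives an orientation
    coherence in [0, 1] and its minor eigenvector gives the dominant
    stripe direction.  Low coherence is mesh (M); otherwise the stripe
    angle relative to the vessel long axis decides: within ``angle_band``
    of 90 deg is circumferential (C), within ``angle_band`` of 0 deg is
    longitudinal (L), anything else M.

    ``vessel_axis_angle`` is the long-axis direction in image coordinates
    (degrees from the column axis, 0 = rows run along the vessel).
    """
    from skimage.feature import structure_tensor

    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2D")
    if img.max() == img.min():
        raise ValueError("no texture: image is flat")
    Arr, Arc, Acc = structure_tensor(img, sigma=sigma, order="rc")
    jrr, jrc, jcc = Arr.mean(), Arc.mean(), Acc.mean()
    tr = jrr + jcc
    disc = np.sqrt((jrr - jcc) ** 2 + 4 * jrc**2)
    lam1, lam2 = (tr + disc) / 2, (tr - disc) / 2
    coherence = float(disc / tr) if tr > 0 else 0.0
    # major eigenvector = dominant gradient direction; stripes run
    # perpendicular to it.  Angle of the gradient direction w.r.t. columns:
    grad_angle = 0.5 * np.degrees(np.arctan2(2 * jrc, jcc - jrr))
    stripe_angle = grad_angle + 90.0
    # angle of the stripes relative to the vessel long axis, folded to [0, 90]
    rel = (stripe_angle - vessel_axis_angle) % 180.0
    rel = min(rel, 180.0 - rel)
    if coherence < coherence_threshold:
        label = "M"
    elif rel >= 90.0 - angle_band:
        label = "C"
    elif rel <= angle_band:
        label = "L"
    else:
        label = "M"
    return OrientationCall(label=label, dominant_angle=float(rel),
                           coherence=coherence)


_COMBINE_ORDER = {"C": 0, "M": 1, "L": 2}


def combine_views(front: OrientationCall | str, back: OrientationCall | str) -> str:
    """Vessel-level label from front and back views.

    Equal labels collapse; differing labels give the ordered combined
    category, e.g. front M + back C -> "C-M".
    """
    f = front.label if isinstance(front, OrientationCall) else front
    b = back.label if isinstance(back, OrientationCall) else back
    for lab in (f, b):
        if lab not in _COMBINE_ORDER:
            raise ValueError(f"unknown label {lab!r}")
    if f == b:
        return f
    first, second = sorted((f, b), key=_COMBINE_ORDER.get)
    return f"{first}-{second}"
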