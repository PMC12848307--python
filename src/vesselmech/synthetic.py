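"""Seeded synthetic-data generators with attached ground truth.

Every input the measurement pipeline consumes can be generated here with
known truth: wall-peak intensity profiles, per-cell shape tables with
prescribed strain trajectories, post-ablation kymographs widening at a
known velocity, lagged series pairs, and oriented textures
(circumferential / mesh / longitudinal).  Generators are deterministic
given their spec (which includes the seed) and target the statistical
structure the downstream estimators assume, not photorealism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .morphometrics import IntensityProfile, cell_width_length
from .strain import GroupSummary, IntervalStrains, decompose_interval

__all__ = [
    "WallProfileSpec",
    "CellTrajectorySpec",
    "KymographSpec",
    "LaggedSeriesSpec",
    "TextureSpec",
    "gen_wall_profile",
    "gen_cell_shape_table",
    "gen_kymograph",
    "gen_lagged_series",
    "gen_oriented_texture",
]


# ---------------------------------------------------------------- wall profile

@dataclass(frozen=True)
class WallProfileSpec:
    """Two wall peaks on a flat baseline, triangle or gaussian shaped."""

    pixel_size: float = 0.1          # um/px, ~60x/NA1.2 regime
    wall_centers: tuple[float, float] = (2.0, 8.0)
    wall_shape: str = "gaussian"     # or "triangle"
    wall_halfwidth: float = 0.4      # um (sigma for gaussian, half-base for triangle)
    wall_height: float = 1.0
    baseline: float = 0.1
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.wall_centers[0] == self.wall_centers[1]:
            raise ValueError("wall_centers must be distinct")
        if self.wall_halfwidth <= 0:
            raise ValueError("wall_halfwidth must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.wall_shape not in ("triangle", "gaussian"):
            raise ValueError("wall_shape must be 'triangle' or 'gaussian'")


def _wall_shape(x, center, shape, hw, height):
    if shape == "triangle":
        return height * np.clip(1.0 - np.abs(x - center) / hw, 0.0, None)
    return height * np.exp(-0.5 * ((x - center) / hw) ** 2)


def wall_profile_noiseless(spec: WallProfileSpec, positions: np.ndarray) -> np.ndarray:
    """Analytic (noise-free) profile evaluated on an arbitrary grid."""
    y = np.full_like(positions, spec.baseline, dtype=float)
    for c in spec.wall_centers:
        y += _wall_shape(positions, c, spec.wall_shape, spec.wall_halfwidth,
                         spec.wall_height)
    return y


def gen_wall_profile(spec: WallProfileSpec) -> tuple[IntensityProfile, float]:
    """Generate a two-wall profile; returns (profile, true_diameter).

    The true diameter is the wall-centre separation, matching the
    centre-to-centre convention of the diameter estimator.
    """
    lo, hi = sorted(spec.wall_centers)
    if hi - lo < 2 * spec.wall_halfwidth:
        raise ValueError("walls unresolvable: separation < 2*halfwidth")
    margin = 6 * spec.wall_halfwidth + 10 * spec.pixel_size
    start = lo - margin
    n = int(np.ceil((hi + margin - start) / spec.pixel_size)) + 1
    positions = start + np.arange(n) * spec.pixel_size
    values = wall_profile_noiseless(spec, positions)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=n)
    return IntensityProfile(positions, values, spec.pixel_size), float(hi - lo)


# ------------------------------------------------------------ cell shape table

@dataclass(frozen=True)
class CellTrajectorySpec:
    """Prescribed per-timepoint truth for cell shape and vessel geometry.

    Noise is multiplicative: each observed value is truth * (1 + cv*z),
    z ~ N(0,1), so the standard error of a per-timepoint mean is
    truth * cv / sqrt(n).
    """

    n_cells: int = 200
    n_vessels: int = 10
    timepoints: tuple[str, ...] = ("2dpf", "3dpf", "4dpf")
    true_area_per_tp: tuple[float, ...] = (420.0, 340.0, 300.0)     # um^2
    true_aspect_per_tp: tuple[float, ...] = (2.0, 2.3, 2.6)
    true_diameter_per_tp: tuple[float, ...] = (9.0, 7.4, 6.8)       # um
    true_length_per_tp: tuple[float, ...] = (110.0, 125.0, 135.0)   # um
    noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self):
        ntp = len(self.timepoints)
        for name in ("true_area_per_tp", "true_aspect_per_tp",
                     "true_diameter_per_tp", "true_length_per_tp"):
            vals = getattr(self, name)
            if len(vals) != ntp:
                raise ValueError(f"{name} must have one value per timepoint")
            if any(v <= 0 for v in vals):
                raise ValueError(f"{name} values must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.n_cells < 1 or self.n_vessels < 1:
            raise ValueError("counts must be at least 1")


def true_summaries(spec: CellTrajectorySpec) -> list[GroupSummary]:
    """Noise-free group summaries implied by the prescribed truth."""
    out = []
    for i, tp in enumerate(spec.timepoints):
        w, l = cell_width_length(spec.true_area_per_tp[i], spec.true_aspect_per_tp[i])
        out.append(
            GroupSummary(tp, spec.true_diameter_per_tp[i],
                         spec.true_length_per_tp[i], w, l,
                         n_vessels=spec.n_vessels, n_cells=spec.n_cells)
        )
    return out


def true_interval_strains(spec: CellTrajectorySpec) -> list[IntervalStrains]:
    """Closed-form ground-truth strains between consecutive timepoints."""
    s = true_summaries(spec)
    return [decompose_interval(s[i], s[i + 1]) for i in range(len(s) - 1)]


def gen_cell_shape_table(
    spec: CellTrajectorySpec,
) -> tuple[pd.DataFrame, pd.DataFrame, list[IntervalStrains]]:
    """Generate (cells, vessels, true_strains).

    ``cells`` has columns (cell_id, timepoint, area_um2, aspect_ratio,
    width_um, length_um); ``vessels`` has (vessel_id, timepoint,
    diameter_um, length_um, ec_count).
    """
    rng = np.random.default_rng(spec.seed)

    def noisy(truth, n):
        if spec.noise_cv == 0:
            return np.full(n, truth)
        vals = truth * (1.0 + spec.noise_cv * rng.standard_normal(n))
        return np.clip(vals, truth * 1e-3, None)  # keep strictly positive

    cell_rows, vessel_rows = [], []
    for i, tp in enumerate(spec.timepoints):
        a = noisy(spec.true_area_per_tp[i], spec.n_cells)
        r = noisy(spec.true_aspect_per_tp[i], spec.n_cells)
        for j in range(spec.n_cells):
            w, l = cell_width_length(a[j], r[j])
            cell_rows.append(dict(cell_id=f"c{j:03d}", timepoint=tp,
                                  area_um2=a[j], aspect_ratio=r[j],
                                  width_um=w, length_um=l))
        D = noisy(spec.true_diameter_per_tp[i], spec.n_vessels)
        L = noisy(spec.true_length_per_tp[i], spec.n_vessels)
        for j in range(spec.n_vessels):
            vessel_rows.append(dict(vessel_id=f"v{j:02d}", timepoint=tp,
                                    diameter_um=D[j], length_um=L[j],
                                    ec_count=int(rng.integers(3, 8))))
    return (pd.DataFrame(cell_rows), pd.DataFrame(vessel_rows),
            true_interval_strains(spec))


# ------------------------------------------------------------------ kymograph

@dataclass(frozen=True)
class KymographSpec:
    """Space x time image of a bright cortex with a dark ablation gap
    widening at constant velocity."""

    true_velocity: float = 0.4     # um/s
    frame_interval: float = 0.25   # s
    n_frames: int = 50
    n_pre_frames: int = 4          # frames before the ablation pulse
    pixel_size: float = 0.1        # um/px
    initial_gap: float = 0.6       # um
    edge_blur: float = 0.15        # um
    noise_sd: float = 0.0
    field_width: float = 12.0      # um
    seed: int = 0

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.true_velocity < 0:
            raise ValueError("true_velocity must be non-negative")


def kymograph_noiseless_column(spec: KymographSpec, x: np.ndarray, gap: float):
    """Analytic intensity across the gap: bright (1) outside, dark (0)
    inside, edges smoothed by a gaussian-CDF ramp of width edge_blur."""
    from scipy.special import erf

    c = spec.field_width / 2.0
    lo, hi = c - gap / 2.0, c + gap / 2.0
    if spec.edge_blur > 0:
        s = spec.edge_blur * np.sqrt(2.0)
        return 1.0 - 0.5 * (erf((x - lo) / s) - erf((x - hi) / s))
    return np.where((x >= lo) & (x <= hi), 0.0, 1.0)


def gen_kymograph(spec: KymographSpec):
    """Generate (Kymograph, true_gap_series).

    ``true_gap_series`` is NaN before the ablation frame and
    ``initial_gap + v * t_since_ablation`` after it.
    """
    from .image_quant import Kymograph

    n_space = int(round(spec.field_width / spec.pixel_size)) + 1
    x = np.arange(n_space) * spec.pixel_size
    final_gap = spec.initial_gap + spec.true_velocity * (
        (spec.n_frames - spec.n_pre_frames - 1) * spec.frame_interval
    )
    if final_gap >= spec.field_width - 2.0:
        raise ValueError("gap out of field: widen field_width or shorten movie")
    rng = np.random.default_rng(spec.seed)
    mat = np.empty((n_space, spec.n_frames))
    truth = np.full(spec.n_frames, np.nan)
    for k in range(spec.n_frames):
        if k < spec.n_pre_frames:
            col = np.ones(n_space)
        else:
            gap = spec.initial_gap + spec.true_velocity * (
                (k - spec.n_pre_frames) * spec.frame_interval
            )
            truth[k] = gap
            col = kymograph_noiseless_column(spec, x, gap)
        mat[:, k] = col
    if spec.noise_sd > 0:
        mat = mat + rng.normal(0.0, spec.noise_sd, size=mat.shape)
    kym = Kymograph(matrix=mat, pixel_size=spec.pixel_size,
                    frame_interval=spec.frame_interval,
                    ablation_frame=spec.n_pre_frames)
    return kym, truth


# -------------------------------------------------------------- lagged series

@dataclass(frozen=True)
class LaggedSeriesSpec:
    """Pair of band-limited series where B(t) = s * A(t - true_lag) + noise;
    positive true_lag means A leads B."""

    n_frames: int = 240
    frame_interval: float = 0.25   # time units per frame
    true_lag: float = 2.5          # same time units, signed
    correlation_sign: str = "negative"
    noise_sd: float = 0.1
    n_modes: int = 12
    period_range: tuple[float, float] = (8.0, 40.0)
    seed: int = 0

    def __post_init__(self):
        if abs(self.true_lag) >= self.n_frames * self.frame_interval / 2:
            raise ValueError("|true_lag| must be < half the record length")
        if self.correlation_sign not in ("positive", "negative"):
            raise ValueError("correlation_sign must be 'positive' or 'negative'")


def gen_lagged_series(spec: LaggedSeriesSpec):
    """Generate (times, A, B).  A is a random sum of sinusoids, so the
    shifted copy B is exact even for non-integer-frame lags."""
    rng = np.random.default_rng(spec.seed)
    periods = rng.uniform(*spec.period_range, size=spec.n_modes)
    phases = rng.uniform(0, 2 * np.pi, size=spec.n_modes)
    amps = rng.uniform(0.5, 1.0, size=spec.n_modes)

    def signal(t):
        t = np.asarray(t, dtype=float)[:, None]
        return (amps * np.sin(2 * np.pi * t / periods + phases)).sum(axis=1)

    t = np.arange(spec.n_frames) * spec.frame_interval
    a = signal(t)
    sgn = 1.0 if spec.correlation_sign == "positive" else -1.0
    b = sgn * signal(t - spec.true_lag)
    if spec.noise_sd > 0:
        scale = spec.noise_sd * a.std()
        a = a + rng.normal(0, scale, spec.n_frames)
        b = b + rng.normal(0, scale, spec.n_frames)
    return t, a, b


# ----------------------------------------------------------- oriented texture

@dataclass(frozen=True)
class TextureSpec:
    """Striped or mesh texture emulating cortical actin organisations.

    Convention: the vessel long axis runs along image rows (angle 0).
    C = stripes perpendicular to the long axis (circumferential bundles),
    L = stripes parallel to it, M = superposed cross-hatch (mesh).
    """

    label: str = "C"
    image_size: tuple[int, int] = (128, 128)
    stripe_period: int = 12        # px
    angle_jitter_sd: float = 0.0   # degrees
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.label not in ("C", "M", "L"):
            raise ValueError("label must be one of C, M, L")
        if self.stripe_period < 2:
            raise ValueError("stripe_period must be >= 2 px")


def gen_oriented_texture(spec: TextureSpec) -> np.ndarray:
    """Generate a labelled texture image (float, roughly in [0, 1])."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    jitter = np.deg2rad(rng.normal(0.0, spec.angle_jitter_sd))
    # rotate coordinates by the jitter angle
    u = cols * np.cos(jitter) - rows * np.sin(jitter)
    v = cols * np.sin(jitter) + rows * np.cos(jitter)
    k = 2 * np.pi / spec.stripe_period
    stripes_across = 0.5 * (1 + np.sin(k * u))  # varies along the long axis -> C
    stripes_along = 0.5 * (1 + np.sin(k * v))   # varies across the vessel -> L
    if spec.label == "C":
        img = stripes_across
    elif spec.label == "L":
        img = stripes_along
    else:  # mesh: balanced cross-hatch, no dominant orientation
        img = 0.5 * (stripes_across + stripes_along)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return img


def gen_texture_panel(n_per_class: int = 20, seed: int = 0,
                      jitter_sd: float = 6.0):
    """A labelled panel of C/M/L textures with mixed stripe periods and
    orientation jitter, for classifier evaluation."""
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for label in ("C", "M", "L"):
        for _ in range(n_per_class):
            spec = TextureSpec(
                label=label,
                stripe_period=int(rng.integers(8, 20)),
                angle_jitter_sd=jitter_sd,
                noise_sd=0.1,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            images.append(gen_oriented_texture(spec))
            labels.append(label)
    return images, labels
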