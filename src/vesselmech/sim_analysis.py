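"""Post-processing of cortex-model trajectories.

Detects bundle episodes (intervals of elevated normalised circumferential
alignment in the central region), estimates the lag between vessel width
and central alignment by cross-correlation, and summarises runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend

from .cortex.run import TrajectoryRecord
from .image_quant import crosscorr_curve, crosscorr_lag

__all__ = [
    "BundleEpisode",
    "detect_bundle_episodes",
    "width_alignment_lag",
    "width_alignment_corr_curve",
    "summarize_run",
]


@dataclass(frozen=True)
class BundleEpisode:
    t_start: float
    t_end: float
    peak_alignment: float

    def __post_init__(self):
        if not self.t_start < self.t_end:
            raise ValueError("t_start must precede t_end")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def detect_bundle_episodes(
    times: np.ndarray,
    nx2: np.ndarray,
    counts: np.ndarray,
    threshold: float = 0.65,
    min_duration: float = 60.0,
    merge_gap: float = 10.0,
) -> list[BundleEpisode]:
    """Maximal intervals where N_x^2/S exceeds ``threshold`` for at least
    ``min_duration`` seconds.

    The criterion is on the normalised alignment (0.5 = isotropic, 1 =
    fully circumferential) so it is independent of segment counts.
    Supra-threshold intervals separated by less than ``merge_gap``
    seconds are merged before the duration filter.
    """
    times = np.asarray(times, float)
    nx2 = np.asarray(nx2, float)
    counts = np.asarray(counts, float)
    if times.size == 0:
        return []
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(counts > 0, nx2 / counts, 0.0)
    above = norm > threshold
    # maximal runs of True
    intervals = []
    i = 0
    n = times.size
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            intervals.append([i, j])
            i = j + 1
        else:
            i += 1
    # merge across short gaps
    merged = []
    for iv in intervals:
        if merged and times[iv[0]] - times[merged[-1][1]] < merge_gap:
            merged[-1][1] = iv[1]
        else:
            merged.append(iv)
    episodes = []
    for i0, i1 in merged:
        t0, t1 = times[i0], times[i1]
        if t1 - t0 >= min_duration:
            episodes.append(
                BundleEpisode(t_start=float(t0), t_end=float(t1),
                              peak_alignment=float(norm[i0: i1 + 1].max()))
            )
    return episodes


def width_alignment_lag(
    record: TrajectoryRecord, max_lag: float = 600.0
) -> tuple[float, float]:
    """Lag (s) at which the correlation between central alignment and
    vessel width is most negative; positive lag means alignment leads
    width.  Both series are linearly detrended first (slow drift from
    turnover would otherwise bias the estimate).

    Returns (lag, correlation).
    """
    if record.params.boundary_mode != "deformable_membrane":
        raise ValueError("width-alignment lag requires a deformable-membrane run")
    t = record.times
    if t.size < 8:
        raise ValueError("insufficient samples")
    align = record.alignment_central
    width = record.width
    good = np.isfinite(align) & np.isfinite(width)
    a = detrend(align[good])
    w = detrend(width[good])
    frame = float(np.median(np.diff(t)))
    # the correlation needs overlap: never scan beyond ~45% of the record
    max_lag = min(max_lag, 0.45 * (t[-1] - t[0]))
    return crosscorr_lag(a, w, frame, max_lag, mode="negative")


def width_alignment_corr_curve(record: TrajectoryRecord, max_lag: float = 600.0):
    """Full normalized cross-correlation curve between detrended central
    alignment and width; positive lag means alignment leads.  Curves from
    replicate runs can be averaged before locating the extremum, which
    suppresses the single-run noise in the lag estimate."""
    if record.params.boundary_mode != "deformable_membrane":
        raise ValueError("width-alignment lag requires a deformable-membrane run")
    t = record.times
    if t.size < 8:
        raise ValueError("insufficient samples")
    align = record.alignment_central
    width = record.width
    good = np.isfinite(align) & np.isfinite(width)
    a = detrend(align[good])
    w = detrend(width[good])
    frame = float(np.median(np.diff(t)))
    max_lag = min(max_lag, 0.45 * (t[-1] - t[0]))
    return crosscorr_curve(a, w, frame, max_lag)


def summarize_run(record: TrajectoryRecord, threshold: float = 0.65,
                  min_duration: float = 60.0,
                  max_lag: float = 600.0) -> dict:
    """Deterministic per-run summary: bundle-episode statistics, stress
    anisotropy inside vs outside episodes, minimum width, and (for
    deformable runs) the width-alignment lag."""
    episodes = detect_bundle_episodes(record.times, record.nx2_central,
                                      record.s_central, threshold,
                                      min_duration)
    sxx, syy, _ = record.smoothed_stress()
    aniso = sxx - syy
    in_ep = np.zeros(record.times.size, dtype=bool)
    for ep in episodes:
        in_ep |= (record.times >= ep.t_start) & (record.times <= ep.t_end)
    out = dict(
        n_episodes=len(episodes),
        episode_total_duration=float(sum(ep.duration for ep in episodes)),
        mean_anisotropy_in_episodes=float(np.mean(aniso[in_ep])) if in_ep.any()
        else np.nan,
        mean_anisotropy_outside=float(np.mean(aniso[~in_ep])) if (~in_ep).any()
        else np.nan,
        mean_sigma_xx=float(np.mean(sxx)),
        mean_sigma_yy=float(np.mean(syy)),
        min_width=float(np.nanmin(record.width)),
        initial_width=float(record.width[0]),
        lag=np.nan,
        lag_correlation=np.nan,
    )
    if record.params.boundary_mode == "deformable_membrane" and record.times.size >= 8:
        lag, corr = width_alignment_lag(record, max_lag)
        out["lag"] = lag
        out["lag_correlation"] = corr
    return out
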