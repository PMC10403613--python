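"""Peak-ROI time courses and the normalization schemes of the study.

The response ROI is a circle of radius 5 pixels centered at the peak of the
evoked map at t = 20 ms (the first frame after the laser artifact, which is
also where all conditions peak).  Time courses (TCs) are mask-aware means
over ROI pixels; SEM is computed over trials (within a session) or over
sessions (grand averages).  Three normalizations are supported:

* ``norm_to_10ms`` — each session's TCs divided by that session's 10 ms
  condition value at t = 20 ms (accounts for staining/expression variance
  across sessions; forces the 10 ms condition to exactly 1 +/- 0).
* ``norm_to_own_peak`` — each TC divided by its own t = 20 ms value
  (compares decay dynamics across conditions of unequal amplitude).
* ``norm_to_t20`` — alias of the same anchor applied to a single TC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import uniform_filter

from .core import AcquisitionSpec, DffMovie, nanmean_quiet

T_PEAK_MS = 20.0


@dataclass(frozen=True)
class CircleROI:
    """Circular pixel ROI; membership by pixel-center Euclidean distance."""

    center_px: tuple[int, int]
    radius_px: float = 5.0

    def member_mask(self, shape: tuple[int, int]) -> np.ndarray:
        rows = np.arange(shape[0])[:, None] - self.center_px[0]
        cols = np.arange(shape[1])[None, :] - self.center_px[1]
        return rows ** 2 + cols ** 2 <= self.radius_px ** 2

    def validate_inside(self, acq: AcquisitionSpec) -> None:
        r, c = self.center_px
        if (r - self.radius_px < 0 or r + self.radius_px > acq.height_px - 1
                or c - self.radius_px < 0 or c + self.radius_px > acq.width_px - 1):
            raise ValueError("ROI not fully inside frame")


@dataclass
class TimeCourse:
    """ROI-averaged dF/f per frame with its SEM and provenance tags."""

    values: np.ndarray
    time_ms: np.ndarray
    sem: Optional[np.ndarray] = None
    n_trials: int = 1
    condition: str = ""
    normalization: str = "raw"

    def at(self, t_ms: float) -> float:
        idx = np.flatnonzero(np.isclose(self.time_ms, t_ms))
        if idx.size != 1:
            raise ValueError(f"no unique frame at t = {t_ms} ms")
        return float(self.values[idx[0]])


def _nan_boxcar(frame: np.ndarray, size: int) -> np.ndarray:
    """Boxcar smoothing that ignores NaN entries."""
    valid = np.isfinite(frame)
    filled = np.where(valid, frame, 0.0)
    num = uniform_filter(filled, size=size, mode="constant")
    den = uniform_filter(valid.astype(float), size=size, mode="constant")
    with np.errstate(invalid="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def find_peak_center(movie: DffMovie, t_peak_ms: float = T_PEAK_MS,
                     smooth_px: int = 3) -> tuple[int, int]:
    """Argmax pixel of the boxcar-smoothed valid map at the peak frame.

    Ties break to the smallest (row, col) in lexicographic order.  Invariant
    under any positive global rescaling of the movie.
    """
    k = movie.acq.frame_at(t_peak_ms)
    if not movie.valid_frames[k]:
        raise ValueError(f"frame at t = {t_peak_ms} ms is invalid")
    frame = movie.masked_data()[k]
    if smooth_px and smooth_px > 1:
        frame = _nan_boxcar(frame, smooth_px)
    frame = np.where(movie.valid_pixels, frame, np.nan)
    if not np.isfinite(frame).any():
        raise ValueError("all pixels invalid at the peak frame")
    flat = np.where(np.isfinite(frame), frame, -np.inf)
    idx = int(np.argmax(flat))
    return (idx // movie.acq.width_px, idx % movie.acq.width_px)


def extract_tc(movie: DffMovie, roi: CircleROI) -> TimeCourse:
    """Mask-aware per-frame mean over ROI pixels; SEM over trials.

    The SEM is the standard error over trials of the per-trial ROI means,
    available when the movie retains its per-trial corrected stacks.
    """
    roi.validate_inside(movie.acq)
    mask = roi.member_mask(movie.data.shape[1:]) & movie.valid_pixels
    if not mask.any():
        raise ValueError("ROI contains no valid pixels")
    data = movie.masked_data()
    values = nanmean_quiet(data[:, mask], axis=1)
    values[~movie.valid_frames] = np.nan
    sem = None
    if movie.trial_data is not None and movie.n_trials >= 2:
        per_trial = movie.trial_data[:, :, mask].mean(axis=2)
        sem = per_trial.std(axis=0, ddof=1) / np.sqrt(movie.n_trials)
        sem = np.where(movie.valid_frames, sem, np.nan)
    return TimeCourse(values=values, time_ms=movie.time_ms, sem=sem,
                      n_trials=movie.n_trials, condition=movie.condition)


def normalize_to_10ms(tcs: dict[float, TimeCourse],
                      t_peak_ms: float = T_PEAK_MS) -> dict[float, TimeCourse]:
    """Divide every pulse-duration TC by the 10 ms TC's value at t = 20 ms."""
    if 10.0 not in tcs:
        raise ValueError("10 ms condition required for normalization")
    norm = tcs[10.0].at(t_peak_ms)
    if not norm > 0:
        raise ValueError(f"non-positive normalizer {norm}")
    out = {}
    for pulse, tc in tcs.items():
        out[pulse] = TimeCourse(
            values=tc.values / norm,
            time_ms=tc.time_ms,
            sem=None if tc.sem is None else tc.sem / norm,
            n_trials=tc.n_trials,
            condition=tc.condition,
            normalization="norm_to_10ms",
        )
    return out


def normalize_to_own_peak(tc: TimeCourse, t_peak_ms: float = T_PEAK_MS,
                          mode: str = "t20") -> TimeCourse:
    """Divide a TC by its own peak (value at t = 20 ms, or global max).

    The t = 20 ms anchor is the default because the true maximum is hidden
    by the laser artifact; ``mode='max'`` uses the valid-frame maximum
    instead (the two coincide on well-behaved data).
    """
    if mode == "t20":
        peak = tc.at(t_peak_ms)
    elif mode == "max":
        peak = float(np.nanmax(tc.values))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not peak > 0:
        raise ValueError(f"non-positive peak {peak}")
    return TimeCourse(values=tc.values / peak, time_ms=tc.time_ms,
                      sem=None if tc.sem is None else tc.sem / peak,
                      n_trials=tc.n_trials, condition=tc.condition,
                      normalization="norm_to_own_peak")


def grand_average(tcs: Sequence[TimeCourse]) -> TimeCourse:
    """Frame-wise mean +/- SEM across sessions (mask-aware)."""
    if len(tcs) < 2:
        raise ValueError("need at least two sessions for a grand average")
    t0 = tcs[0].time_ms
    for tc in tcs[1:]:
        if tc.time_ms.shape != t0.shape or not np.allclose(tc.time_ms, t0):
            raise ValueError("mismatched time axes")
    stack = np.vstack([tc.values for tc in tcs])
    mean = nanmean_quiet(stack, axis=0)
    n = np.isfinite(stack).sum(axis=0)
    with np.errstate(invalid="ignore"):
        sd = np.where(n >= 2, np.sqrt(nanmean_quiet(
            (stack - mean) ** 2, axis=0) * n / np.maximum(n - 1, 1)), np.nan)
    sem = np.where(n >= 2, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return TimeCourse(values=mean, time_ms=t0, sem=sem, n_trials=len(tcs),
                      condition=tcs[0].condition,
                      normalization=tcs[0].normalization)
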