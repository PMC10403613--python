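"""Annulus (ring-ROI) space-time analysis of lateral response spread.

Forty concentric non-overlapping annuli of 50 um width tile the disk of
radius 2 mm around the response peak: ring k holds pixels whose center
distance d satisfies (k-1)*50 < d <= k*50 um.  Averaging dF/f per ring per
frame yields a space-time map; the "center" row is the mean of rings 1-5
(>= a minimal pixel count), or alternatively all pixels within 150 um.
Derived summaries: summed activation over space (to 2 mm) and time
(20-100 ms), spatial profiles at the peak frame, and distance-band time
courses (ring1 150-350 um, ring2 700-900 um, ring3 1250-1450 um).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AcquisitionSpec, DffMovie, nanmean_quiet
from .timecourse import T_PEAK_MS, TimeCourse

#: Distance bands (um) of the three reporting rings.
RING_BANDS_UM = {
    "ring1": (150.0, 350.0),
    "ring2": (700.0, 900.0),
    "ring3": (1250.0, 1450.0),
}


@dataclass
class RingSet:
    """Concentric annuli around ``center_px``.

    ``labels`` assigns ring index 1..n_rings to each pixel (0 = outside all
    rings, i.e. the center pixel itself or beyond ``max_radius_um``).
    """

    center_px: tuple[int, int]
    step_um: float
    n_rings: int
    labels: np.ndarray
    central_rings: tuple[int, ...] = (1, 2, 3, 4, 5)

    def members(self, k: int) -> np.ndarray:
        """Boolean pixel mask of ring k (1-based)."""
        if not 1 <= k <= self.n_rings:
            raise ValueError(f"ring index {k} out of range")
        return self.labels == k

    @property
    def outer_edges_um(self) -> np.ndarray:
        """Outer-edge distance of each ring, 50..2000 um."""
        return self.step_um * np.arange(1, self.n_rings + 1)

    def band_indices(self, band: str) -> np.ndarray:
        """1-based indices of elementary rings lying within a named band."""
        if band not in RING_BANDS_UM:
            raise ValueError(f"unknown band {band!r}")
        lo, hi = RING_BANDS_UM[band]
        k = np.arange(1, self.n_rings + 1)
        inner = (k - 1) * self.step_um
        outer = k * self.step_um
        return k[(inner >= lo) & (outer <= hi)]


def build_rings(center_px: tuple[int, int], acq: AcquisitionSpec,
                step_um: float = 50.0, max_radius_um: float = 2000.0) -> RingSet:
    """Build the ring set; defaults give exactly 40 disjoint rings to 2 mm."""
    if not acq.contains(center_px):
        raise ValueError(f"center {center_px} outside frame")
    n_rings = int(round(max_radius_um / step_um))
    d = acq.distance_um(center_px)
    # ring k <-> (k-1)*step < d <= k*step; the small epsilon keeps exact
    # multiples of the step on the inner ring despite float sqrt rounding.
    q = d / step_um
    labels = np.ceil(q - 1e-9).astype(int)
    labels[(d <= 0) | (labels > n_rings)] = 0
    return RingSet(center_px=center_px, step_um=step_um,
                   n_rings=n_rings, labels=labels)


@dataclass
class SpaceTimeMap:
    """Ring x frame matrix of mean dF/f, plus the center-row time course."""

    values: np.ndarray  # (n_rings, n_frames); NaN where ring/frame invalid
    center: np.ndarray  # (n_frames,)
    time_ms: np.ndarray
    distance_um: np.ndarray  # outer edge per ring
    normalization: str = "raw"

    def frame_index(self, t_ms: float) -> int:
        idx = np.flatnonzero(np.isclose(self.time_ms, t_ms))
        if idx.size != 1:
            raise ValueError(f"no unique frame at t = {t_ms} ms")
        return int(idx[0])


def spacetime_map(movie: DffMovie, rings: RingSet,
                  center_mode: str = "rings1_5") -> SpaceTimeMap:
    """Mask-aware mean dF/f per ring per frame.

    ``center_mode='rings1_5'`` (default) defines the center activation as
    the mean of the ring means of rings 1-5; ``'r150'`` averages all valid
    pixels within 150 um instead.
    """
    if rings.labels.shape != movie.data.shape[1:]:
        raise ValueError("ring set geometry does not match movie")
    data = movie.masked_data()
    n_frames = data.shape[0]
    flat_labels = rings.labels.ravel()
    flat = data.reshape(n_frames, -1)
    finite = np.isfinite(flat)
    vals = np.where(finite, flat, 0.0)
    nbins = rings.n_rings + 1
    sums = np.vstack([np.bincount(flat_labels, weights=vals[f], minlength=nbins)
                      for f in range(n_frames)])
    counts = np.vstack([np.bincount(flat_labels, weights=finite[f], minlength=nbins)
                        for f in range(n_frames)])
    with np.errstate(invalid="ignore"):
        means = sums / counts
    means[counts == 0] = np.nan
    values = means[:, 1:].T  # (n_rings, n_frames)

    if center_mode == "rings1_5":
        idx = [k - 1 for k in rings.central_rings]
        center = nanmean_quiet(values[idx, :], axis=0)
    elif center_mode == "r150":
        disk = (movie.acq.distance_um(rings.center_px) <= 150.0)
        center = nanmean_quiet(np.where(finite, flat, np.nan)[:, disk.ravel()], axis=1)
    else:
        raise ValueError(f"unknown center_mode {center_mode!r}")
    center = np.where(movie.valid_frames, center, np.nan)
    values[:, ~movie.valid_frames] = np.nan
    return SpaceTimeMap(values=values, center=center, time_ms=movie.time_ms,
                        distance_um=rings.outer_edges_um)


def normalize_to_center(stm: SpaceTimeMap, t_peak_ms: float = T_PEAK_MS) -> SpaceTimeMap:
    """Divide the whole map by the center-row value at t = 20 ms."""
    norm = stm.center[stm.frame_index(t_peak_ms)]
    if not norm > 0:
        raise ValueError(f"non-positive normalizer {norm}")
    return SpaceTimeMap(values=stm.values / norm, center=stm.center / norm,
                        time_ms=stm.time_ms, distance_um=stm.distance_um,
                        normalization="norm_to_center_t20")


def summed_activation(stm: SpaceTimeMap, t_from_ms: float = 20.0,
                      t_to_ms: float = 100.0, r_to_um: float = 2000.0) -> float:
    """Sum of ring means over space (to ``r_to_um``) and time (inclusive)."""
    rings_sel = stm.distance_um <= r_to_um
    frames_sel = (stm.time_ms >= t_from_ms) & (stm.time_ms <= t_to_ms)
    if not rings_sel.any() or not frames_sel.any():
        raise ValueError("empty summation window")
    block = stm.values[np.ix_(rings_sel, frames_sel)]
    return float(np.nansum(block))


def spatial_profile(stm: SpaceTimeMap, t_ms: float = 20.0) -> tuple[np.ndarray, np.ndarray]:
    """Ring-mean values vs distance at one frame: (distance_um, values)."""
    col = stm.values[:, stm.frame_index(t_ms)]
    if not np.isfinite(col).any():
        raise ValueError(f"frame at t = {t_ms} ms is invalid")
    return stm.distance_um.copy(), col.copy()


def ring_tc(stm: SpaceTimeMap, band: str, rings: RingSet) -> TimeCourse:
    """Time course of one distance band (mean over its elementary rings)."""
    idx = rings.band_indices(band) - 1
    values = nanmean_quiet(stm.values[idx, :], axis=0)
    return TimeCourse(values=values, time_ms=stm.time_ms, condition=band,
                      normalization=stm.normalization)
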