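"""Per-pixel decay-time-to-threshold maps and their spatial distributions.

The VSD signal decays back to baseline in two phases — an early fast decay
and a slower decline.  Each phase is characterized by the per-pixel time at
which the descending transient first falls below a fraction of that pixel's
peak response (70% for the fast phase, 30% for the slow one), with
sub-frame precision by linear interpolation between the last sample at or
above threshold and the first below it (t > 20 ms from stimulation onset).
The peak reference is the t = 20 ms frame (the true maximum is hidden by
the laser artifact).  Pixels already below threshold at 20 ms get exactly
20 ms; pixels that never cross within the analysis window, or with a
non-positive peak, are missing and excluded from the summaries.

Distributions pool per-pixel decay times over a central band (150-350 um
from the peak) and a distal band (1250-1450 um), across sessions, and are
summarized as median +/- MAD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import DffMovie
from .rings import RingSet

CENTRAL_BAND = "ring1"
DISTAL_BAND = "ring3"


@dataclass
class DecayMap:
    """Per-pixel time (ms) to fall below a threshold fraction of peak."""

    times_ms: np.ndarray  # (rows, cols); NaN where missing
    threshold_fraction: float
    peak: np.ndarray  # per-pixel peak reference (t = 20 ms value)
    valid: np.ndarray  # pixels with a defined decay time
    t_start_ms: float = 20.0
    n_not_crossed: int = 0


def decay_time_map(movie: DffMovie, threshold_fraction: float,
                   t_start_ms: float = 20.0,
                   t_end_ms: Optional[float] = None,
                   peak: Optional[np.ndarray] = None) -> DecayMap:
    """Map of first sub-frame-interpolated threshold crossings.

    Scale-invariant (thresholds are fractions of the per-pixel peak) and
    exact on signals that are piecewise linear between frames.  ``peak``
    optionally supplies an external per-pixel peak reference; by default
    the value at ``t_start_ms`` is used, in which case a pixel is never
    already below threshold at the start.  With an external reference,
    pixels already below threshold at ``t_start_ms`` get exactly that time.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in (0, 1)")
    acq = movie.acq
    k0 = acq.frame_at(t_start_ms)
    if not movie.valid_frames[k0]:
        raise ValueError(f"frame at t = {t_start_ms} ms is invalid")
    t = movie.time_ms
    sel = (t >= t_start_ms) & movie.valid_frames
    if t_end_ms is not None:
        sel &= t <= t_end_ms
    times = t[sel]
    vals = movie.masked_data()[sel]  # (m, rows, cols)

    peak = vals[0] if peak is None else np.asarray(peak, dtype=float)
    ok = movie.valid_pixels & np.isfinite(peak) & (peak > 0)
    thr = threshold_fraction * peak

    below = vals < thr[None, :, :]  # NaN compares False
    any_below = below.any(axis=0) & ok
    first = np.argmax(below, axis=0)

    out = np.full(peak.shape, np.nan)
    # already below at t_start -> floor at t_start
    floor = any_below & (first == 0)
    out[floor] = times[0]

    interp = any_below & (first > 0)
    if interp.any():
        j = first[interp]
        rows, cols = np.nonzero(interp)
        v_hi = vals[j - 1, rows, cols]
        v_lo = vals[j, rows, cols]
        th = thr[rows, cols]
        t_hi = times[j - 1]
        t_lo = times[j]
        out[interp] = t_hi + (t_lo - t_hi) * (v_hi - th) / (v_hi - v_lo)

    n_not_crossed = int((ok & ~any_below).sum())
    return DecayMap(times_ms=out, threshold_fraction=threshold_fraction,
                    peak=peak, valid=np.isfinite(out), t_start_ms=times[0],
                    n_not_crossed=n_not_crossed)


def median_mad(samples: np.ndarray) -> tuple[float, float]:
    """Median and (unscaled) median absolute deviation."""
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("empty sample")
    med = float(np.median(x))
    return med, float(np.median(np.abs(x - med)))


def band_samples(dmap: DecayMap, rings: RingSet, band: str) -> np.ndarray:
    """Defined decay times of all pixels in a named distance band."""
    idx = rings.band_indices(band)
    mask = np.isin(rings.labels, idx) & dmap.valid
    return dmap.times_ms[mask]


def decay_distributions(maps: Sequence[DecayMap], ring_sets: Sequence[RingSet],
                        bands: tuple[str, str] = (CENTRAL_BAND, DISTAL_BAND),
                        ) -> dict[str, dict]:
    """Pool per-pixel decay times per band across sessions; median +/- MAD.

    ``maps`` and ``ring_sets`` are parallel per-session sequences (each
    session's rings are centered on its own response peak).
    """
    if len(maps) != len(ring_sets):
        raise ValueError("need one ring set per decay map")
    out: dict[str, dict] = {}
    for band in bands:
        pooled = np.concatenate(
            [band_samples(m, r, band) for m, r in zip(maps, ring_sets)]
        ) if maps else np.array([])
        if pooled.size == 0:
            raise ValueError(f"empty band {band!r}")
        med, mad = median_mad(pooled)
        out[band] = {"samples": pooled, "median_ms": med, "mad_ms": mad,
                     "n_pixels": int(pooled.size)}
    return out
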