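"""Raw trial stacks -> trial-averaged, artifact-cleaned dF/f movies.

The chain follows the standard VSDI preprocessing order: frame-zero
division (per-trial, per-pixel division by the mean pre-onset
fluorescence), subtraction of the mean blank (no-stimulation) trial to
remove heartbeat and slow bleaching shared with stimulated trials, trial
averaging, and removal of the optostimulation artifacts — the frames at
t = 0 and t = 10 ms (laser light artifact) and any pixels near the fiber
tip showing large negative values right after laser offset (dye bleaching).
All removed entries become NaN and are excluded from every downstream mean.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .core import ICMS, OPTO, AcquisitionSpec, DffMovie, StimulusSpec, TrialStack

#: Optostimulation frames removed from analysis (laser light artifact).
OPTO_ARTIFACT_TIMES_MS = (0.0, 10.0)


def frame_zero_divide(stack: TrialStack) -> np.ndarray:
    """Per-trial dF/f: raw / mean pre-onset fluorescence - 1.

    The "-1" centers the pre-stimulus signal near zero; blank subtraction
    re-centers regardless.  Raises if any pixel's baseline mean is not
    strictly positive, naming the first offending (trial, row, col).
    """
    acq = stack.acq
    if acq.baseline_frames < 1:
        raise ValueError("need at least one pre-onset frame")
    baseline = stack.data[:, : acq.onset_frame].mean(axis=1)
    bad = baseline <= 0
    if bad.any():
        trial, row, col = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive baseline at trial {trial}, pixel ({row}, {col})"
        )
    return stack.data / baseline[:, None, :, :] - 1.0


def blank_subtract(dff_stim: np.ndarray, dff_blank: np.ndarray) -> np.ndarray:
    """Subtract the frame-wise mean over blank trials from each trial."""
    if dff_blank.ndim != 4 or dff_blank.shape[0] < 1:
        raise ValueError("need at least one blank trial")
    if dff_stim.shape[1:] != dff_blank.shape[1:]:
        raise ValueError(
            f"shape mismatch: stimulated {dff_stim.shape[1:]} vs "
            f"blank {dff_blank.shape[1:]}"
        )
    return dff_stim - dff_blank.mean(axis=0)


def average_trials(corrected: np.ndarray, acq: AcquisitionSpec,
                   stim: Optional[StimulusSpec] = None,
                   session_id: str = "", condition: str = "",
                   keep_trials: bool = True) -> DffMovie:
    """Frame-wise mean over trials, retaining per-trial data for SEMs."""
    if corrected.ndim != 4 or corrected.shape[0] < 1:
        raise ValueError("need at least one trial")
    return DffMovie(
        data=corrected.mean(axis=0),
        acq=acq,
        n_trials=corrected.shape[0],
        stim=stim,
        session_id=session_id,
        condition=condition,
        trial_data=corrected if keep_trials else None,
    )


def mask_stimulation_frames(movie: DffMovie, modality: Optional[str] = None) -> DffMovie:
    """Invalidate the laser-artifact frames (t = 0 and t = 10 ms) for opto.

    For ICMS no frames are removed (there is no optical artifact); instead
    every cross-modality comparison downstream starts at t = 20 ms.
    Idempotent.
    """
    if modality is None:
        modality = movie.stim.modality if movie.stim is not None else ICMS
    out = movie.copy()
    if modality == OPTO:
        for t in OPTO_ARTIFACT_TIMES_MS:
            k = movie.acq.frame_at(t)
            out.valid_frames[k] = False
            out.data[k] = np.nan
    return out


def mask_bleached_pixels(movie: DffMovie, site_px: tuple[int, int],
                         search_radius_um: float = 500.0,
                         neg_threshold: float = -0.002,
                         window_ms: tuple[float, float] = (10.0, 40.0)) -> DffMovie:
    """Invalidate bleached pixels near the fiber tip.

    A pixel within ``search_radius_um`` of ``site_px`` is flagged invalid
    (for all frames) if its trial-averaged dF/f falls below ``neg_threshold``
    on any valid frame in the window immediately following laser offset.
    """
    if neg_threshold >= 0:
        raise ValueError("neg_threshold must be negative")
    if not movie.acq.contains(site_px):
        raise ValueError(f"site {site_px} outside frame")
    out = movie.copy()
    t = movie.time_ms
    frames = (t >= window_ms[0]) & (t <= window_ms[1]) & movie.valid_frames
    if not frames.any():
        return out
    near = movie.acq.distance_um(site_px) <= search_radius_um
    window = movie.data[frames]
    with np.errstate(invalid="ignore"):
        dips = np.nanmin(window, axis=0) < neg_threshold
    bleached = near & dips
    out.valid_pixels[bleached] = False
    out.data[:, bleached] = np.nan
    return out


def preprocess_session(stim_stack: TrialStack, blank_stack: TrialStack,
                       search_radius_um: float = 500.0,
                       neg_threshold: float = -0.002,
                       window_ms: tuple[float, float] = (10.0, 40.0)) -> DffMovie:
    """Full chain: frame-zero divide, blank subtract, average, mask artifacts."""
    dff_stim = frame_zero_divide(stim_stack)
    dff_blank = frame_zero_divide(blank_stack)
    corrected = blank_subtract(dff_stim, dff_blank)
    movie = average_trials(corrected, stim_stack.acq, stim=stim_stack.stim,
                           session_id=stim_stack.session_id,
                           condition=stim_stack.condition)
    movie = mask_stimulation_frames(movie)
    if movie.stim is not None and movie.stim.modality == OPTO:
        movie = mask_bleached_pixels(movie, movie.stim.site_px,
                                     search_radius_um=search_radius_um,
                                     neg_threshold=neg_threshold,
                                     window_ms=window_ms)
    return movie
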