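"""Shared containers for VSD imaging data.

The pipeline operates on mesoscale voltage-sensitive dye (VSD) recordings:
multi-trial fluorescence stacks acquired at 100 Hz over a 100 x 100 pixel
field of view covering 5 x 5 mm of cortex (50 um per pixel).  Frames are
indexed so that stimulation onset falls at t = 0 ms, with a pre-onset
baseline window used for frame-zero normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

OPTO = "opto"
ICMS = "icms"


def nanmean_quiet(arr: np.ndarray, axis: int) -> np.ndarray:
    """nanmean that returns NaN for all-NaN slices without warning."""
    arr = np.asarray(arr, dtype=float)
    finite = np.isfinite(arr)
    cnt = finite.sum(axis=axis)
    total = np.where(finite, arr, 0.0).sum(axis=axis)
    with np.errstate(invalid="ignore"):
        out = total / cnt
    return np.where(cnt > 0, out, np.nan)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Camera and timing geometry of one VSDI session.

    Parameters
    ----------
    height_px, width_px : int
        Frame size in pixels (100 x 100 covers 5 x 5 mm of cortex).
    pixel_um : float
        Pixel pitch in micrometres (50 um/pixel at mesoscale).
    frame_ms : float
        Frame interval in milliseconds (10 ms, i.e. 100 Hz).
    n_frames : int
        Frames per trial.
    onset_frame : int
        Index of the frame at t = 0 ms (stimulation onset).  All earlier
        frames form the baseline used for frame-zero division, so at least
        one pre-onset frame is required.
    """

    height_px: int = 100
    width_px: int = 100
    pixel_um: float = 50.0
    frame_ms: float = 10.0
    n_frames: int = 40
    onset_frame: int = 10

    def __post_init__(self) -> None:
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")
        if self.frame_ms <= 0:
            raise ValueError("frame_ms must be positive")
        if not (1 <= self.onset_frame < self.n_frames):
            raise ValueError(
                "onset_frame must leave at least one pre-stimulus frame "
                "and lie inside the recording"
            )

    @property
    def baseline_frames(self) -> int:
        """Number of pre-onset frames available for frame-zero division."""
        return self.onset_frame

    @property
    def time_ms(self) -> np.ndarray:
        """Per-frame time relative to stimulation onset, in ms."""
        return (np.arange(self.n_frames) - self.onset_frame) * self.frame_ms

    def frame_at(self, t_ms: float) -> int:
        """Index of the single frame with timestamp ``t_ms`` (no binning)."""
        idx = self.onset_frame + t_ms / self.frame_ms
        k = int(round(idx))
        if abs(idx - k) > 1e-9 or not (0 <= k < self.n_frames):
            raise ValueError(f"no frame at t = {t_ms} ms")
        return k

    def distance_um(self, center_px: tuple[int, int]) -> np.ndarray:
        """Euclidean distance (um) of every pixel center to ``center_px``."""
        rows = np.arange(self.height_px)[:, None] - center_px[0]
        cols = np.arange(self.width_px)[None, :] - center_px[1]
        return np.hypot(rows, cols) * self.pixel_um

    def contains(self, site_px: tuple[int, int]) -> bool:
        r, c = site_px
        return 0 <= r < self.height_px and 0 <= c < self.width_px


@dataclass(frozen=True)
class StimulusSpec:
    """Stimulation parameters for one condition.

    Optostimulation: a single square laser pulse (2, 5 or 10 ms; 15 mW)
    delivered through a fiber above the cortex.  ICMS: a 10-pulse 500 Hz
    biphasic train at 80 uA, 20 ms total duration, through a tungsten
    microelectrode.  ``site_px`` is the fiber tip / electrode position.
    """

    modality: str
    pulse_ms: float
    site_px: tuple[int, int] = (50, 50)
    power_mw: Optional[float] = None
    current_ua: Optional[float] = None
    train: Optional[tuple[int, float]] = None  # (n_pulses, rate_hz)

    def __post_init__(self) -> None:
        if self.modality not in (OPTO, ICMS):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.pulse_ms <= 0:
            raise ValueError("pulse_ms must be positive")


@dataclass
class TrialStack:
    """Raw fluorescence trials for one condition of one session.

    ``data`` has shape (trials, frames, rows, cols) in arbitrary camera
    units.  ``stim`` is ``None`` for blank (no-stimulation) trials.
    """

    data: np.ndarray
    acq: AcquisitionSpec
    stim: Optional[StimulusSpec] = None
    session_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("TrialStack.data must be 4-D (trials, frames, rows, cols)")
        t, f, h, w = self.data.shape
        if (f, h, w) != (self.acq.n_frames, self.acq.height_px, self.acq.width_px):
            raise ValueError("TrialStack shape does not match AcquisitionSpec")
        if self.stim is not None and not self.acq.contains(self.stim.site_px):
            raise ValueError(f"stimulation site {self.stim.site_px} outside frame")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class DffMovie:
    """Trial-averaged dF/f movie with validity masks.

    Invalid frames/pixels carry NaN in ``data`` (never silent zeros) and are
    tracked by ``valid_frames`` / ``valid_pixels``; every downstream mean is
    mask-aware.  ``trial_data`` optionally retains the per-trial corrected
    stacks so per-ROI SEM over trials can be computed downstream.
    """

    data: np.ndarray
    acq: AcquisitionSpec
    valid_frames: np.ndarray = field(default=None)  # type: ignore[assignment]
    valid_pixels: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_trials: int = 1
    stim: Optional[StimulusSpec] = None
    condition: str = ""
    session_id: str = ""
    trial_data: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.data.shape != (self.acq.n_frames, self.acq.height_px, self.acq.width_px):
            raise ValueError("DffMovie shape does not match AcquisitionSpec")
        if self.valid_frames is None:
            self.valid_frames = np.ones(self.acq.n_frames, dtype=bool)
        if self.valid_pixels is None:
            self.valid_pixels = np.ones(
                (self.acq.height_px, self.acq.width_px), dtype=bool
            )

    @property
    def time_ms(self) -> np.ndarray:
        return self.acq.time_ms

    def masked_data(self) -> np.ndarray:
        """Movie with NaN at every invalid frame or pixel."""
        out = self.data.astype(float, copy=True)
        out[~self.valid_frames, :, :] = np.nan
        out[:, ~self.valid_pixels] = np.nan
        return out

    def copy(self) -> "DffMovie":
        return DffMovie(
            data=self.data.copy(),
            acq=self.acq,
            valid_frames=self.valid_frames.copy(),
            valid_pixels=self.valid_pixels.copy(),
            n_trials=self.n_trials,
            stim=self.stim,
            condition=self.condition,
            session_id=self.session_id,
            trial_data=None if self.trial_data is None else self.trial_data.copy(),
        )
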