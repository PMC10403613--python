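"""Synthetic VSDI session generator with known ground truth.

Emulates mesoscale voltage-sensitive dye recordings of population responses
evoked by optostimulation (ChR2, single 2/5/10 ms laser pulse) or
intracortical microstimulation (ICMS, 20 ms train): a stimulus-locked
activation spreading laterally from the stimulation site, riding on shared
slow drift and heartbeat components, with an optical laser artifact, a
photo-bleach spot near the fiber tip, and per-pixel camera noise.

Signal model
------------
Raw fluorescence per trial is

    F(x, y, t) = F0(x, y) * (1 + drift(t) + heartbeat(t) + R(x, y, t) + A) + eps

with ``R = 0`` on blank trials and camera noise ``eps ~ N(0, noise_sd)`` on
raw counts.  The response field is a separable space-time product

    R(x, y, t) = amplitude * T(t) * exp(-d(x, y)^2 / (2 sigma(t)^2)),
    sigma(t)   = sigma0 + speed * max(t - t_peak, 0),

where T rises as the square stimulation pulse convolved with the channel
opening/closing kinetics (opening tau ~1.92 ms, closing tau ~17.9 ms for
ChR2(H134R)), normalized and clipped so T(t_peak) = 1 is the maximum, and
decays bi-exponentially after the peak:

    T(t > t_peak) = w_fast * exp(-(t - t_peak)/tau_fast)
                  + w_slow * exp(-(t - t_peak)/tau_slow).

The temporal peak is pinned at t_peak = 20 ms: all downstream analyses
anchor at the first frame after the laser artifact, and the rise shape
before 20 ms is hidden by that artifact anyway (for opto the t = 0 and
t = 10 ms frames are dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .core import ICMS, OPTO, AcquisitionSpec, StimulusSpec, TrialStack

PRESET_NAMES = ("short_exp", "long_exp", "icms")

# Mean peak dF/f per condition and pulse duration (study conditions; the
# grand-average peaks for short/long expression at 2/5/10 ms and for the
# 20 ms ICMS train).
PEAK_DFF = {
    "short_exp": {2.0: 0.5e-3, 5.0: 1.03e-3, 10.0: 1.4e-3},
    "long_exp": {2.0: 2.3e-3, 5.0: 3.05e-3, 10.0: 3.6e-3},
    "icms": {20.0: 5.1e-3},
}


@dataclass(frozen=True)
class ResponseModel:
    """Parameters of the evoked-response field.

    ``amplitude`` is the peak dF/f at the response center (t = t_peak);
    ``sigma0_um`` the spatial Gaussian width at the peak; ``speed_um_ms``
    the lateral spread speed after the peak.  The decay mixes a fast and a
    slow exponential with weights summing to one.
    """

    amplitude: float = 3.6e-3
    sigma0_um: float = 500.0
    speed_um_ms: float = 3.0
    tau_open_ms: float = 1.92
    tau_close_ms: float = 17.9
    w_fast: float = 0.55
    w_slow: float = 0.45
    tau_fast_ms: float = 9.0
    tau_slow_ms: float = 75.0
    t_peak_ms: float = 20.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.w_fast < 0 or self.w_slow < 0:
            raise ValueError("decay weights must be non-negative")
        if abs(self.w_fast + self.w_slow - 1.0) > 1e-9:
            raise ValueError("w_fast + w_slow must equal 1")
        for name in ("tau_open_ms", "tau_close_ms", "tau_fast_ms", "tau_slow_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma0_um <= 0:
            raise ValueError("sigma0_um must be positive")


@dataclass(frozen=True)
class ArtifactModel:
    """Nuisance components added on top of the evoked response.

    The laser artifact is a large frame-wide additive offset during the
    stimulation frames (opto only; those frames are dropped downstream, so
    only its presence matters).  The bleach spot is a persistent negative
    dF/f offset within ``bleach_radius_um`` of the fiber tip after laser
    offset.  Drift and heartbeat are deterministic waveforms shared between
    stimulated and blank trials, re-centered to zero mean over the baseline
    window so blank subtraction removes them exactly.
    """

    laser_artifact_gain: float = 0.05
    bleach_radius_um: float = 150.0
    bleach_depth: float = -0.005
    drift_slope: float = -2e-4
    heartbeat_hz: float = 6.0
    heartbeat_amp: float = 1e-3
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.bleach_depth > 0:
            raise ValueError("bleach_depth must be <= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Everything needed to verify the pipeline against the generator."""

    resp: ResponseModel
    art: ArtifactModel
    stim: StimulusSpec
    center_px: tuple[int, int]
    dff: np.ndarray  # noiseless response-only dF/f movie (frames, rows, cols)
    seed: int


def _kinetics_drive(t_ms: np.ndarray, pulse_ms: float, tau_open: float,
                    tau_close: float) -> np.ndarray:
    """Square pulse of length ``pulse_ms`` convolved with the opening/closing
    kernel ``exp(-u/tau_close) - exp(-u/tau_open)`` (closed form)."""
    t = np.asarray(t_ms, dtype=float)

    def K(u: np.ndarray) -> np.ndarray:
        return -tau_close * np.exp(-u / tau_close) + tau_open * np.exp(-u / tau_open)

    tt = np.clip(t, 0.0, None)
    g = K(tt) - K(np.clip(tt - pulse_ms, 0.0, None))
    return np.where(t > 0, g, 0.0)


def temporal_profile(t_ms: np.ndarray, stim: StimulusSpec,
                     resp: ResponseModel) -> np.ndarray:
    """Unit-peak temporal waveform T(t); T(t_peak) = 1 is the maximum."""
    t = np.asarray(t_ms, dtype=float)
    tp = resp.t_peak_ms
    g = _kinetics_drive(t, stim.pulse_ms, resp.tau_open_ms, resp.tau_close_ms)
    g_peak = _kinetics_drive(np.array([tp]), stim.pulse_ms,
                             resp.tau_open_ms, resp.tau_close_ms)[0]
    rise = np.clip(g / g_peak, 0.0, 1.0)
    dt = t - tp
    decay = resp.w_fast * np.exp(-np.clip(dt, 0, None) / resp.tau_fast_ms) + \
        resp.w_slow * np.exp(-np.clip(dt, 0, None) / resp.tau_slow_ms)
    return np.where(t <= tp, rise, decay)


def response_field(acq: AcquisitionSpec, stim: StimulusSpec,
                   resp: ResponseModel) -> np.ndarray:
    """Noiseless response-only dF/f movie R(x, y, t)."""
    t = acq.time_ms
    T = temporal_profile(t, stim, resp)
    d = acq.distance_um(stim.site_px)
    sigma = resp.sigma0_um + resp.speed_um_ms * np.clip(t - resp.t_peak_ms, 0, None)
    spatial = np.exp(-d[None, :, :] ** 2 / (2.0 * sigma[:, None, None] ** 2))
    return resp.amplitude * T[:, None, None] * spatial


def _baseline_centered(wave: np.ndarray, acq: AcquisitionSpec) -> np.ndarray:
    return wave - wave[: acq.onset_frame].mean()


def shared_components(acq: AcquisitionSpec, art: ArtifactModel) -> np.ndarray:
    """Per-frame drift + heartbeat waveform, zero-mean over the baseline."""
    k = np.arange(acq.n_frames, dtype=float)
    drift = _baseline_centered(art.drift_slope * k, acq)
    phase = 2.0 * np.pi * art.heartbeat_hz * (k * acq.frame_ms) / 1000.0
    heartbeat = _baseline_centered(art.heartbeat_amp * np.sin(phase), acq)
    return drift + heartbeat


def flatfield(acq: AcquisitionSpec, level: float = 1000.0,
              vignette: float = 0.15) -> np.ndarray:
    """Resting fluorescence F0: constant level with mild radial vignetting."""
    center = ((acq.height_px - 1) / 2.0, (acq.width_px - 1) / 2.0)
    rows = np.arange(acq.height_px)[:, None] - center[0]
    cols = np.arange(acq.width_px)[None, :] - center[1]
    r2 = (rows ** 2 + cols ** 2) / max(center[0], center[1]) ** 2 / 2.0
    return level * (1.0 - vignette * r2)


def _artifact_field(acq: AcquisitionSpec, stim: StimulusSpec,
                    art: ArtifactModel) -> np.ndarray:
    """Additive relative-fluorescence artifacts (opto only): laser offset on
    frames overlapping the pulse, bleach spot after pulse offset."""
    A = np.zeros((acq.n_frames, acq.height_px, acq.width_px))
    if stim.modality != OPTO:
        return A
    t = acq.time_ms
    laser_frames = (t >= 0) & (t <= stim.pulse_ms)
    A[laser_frames, :, :] += art.laser_artifact_gain
    if art.bleach_depth < 0 and art.bleach_radius_um > 0:
        spot = acq.distance_um(stim.site_px) <= art.bleach_radius_um
        post = t >= stim.pulse_ms
        A[post[:, None, None] & spot[None, :, :]] += art.bleach_depth
    return A


def simulate_session(acq: AcquisitionSpec, stim: StimulusSpec,
                     resp: ResponseModel, art: ArtifactModel,
                     n_stim_trials: int = 12, n_blank_trials: int = 10,
                     seed: int = 0, session_id: str = "",
                     condition: str = "") -> tuple[TrialStack, TrialStack, GroundTruth]:
    """Generate one synthetic session: stimulated + blank stacks + truth.

    Identical inputs and seed give bitwise-identical stacks.
    """
    if n_stim_trials < 1 or n_blank_trials < 1:
        raise ValueError("trial counts must be >= 1")
    if not acq.contains(stim.site_px):
        raise ValueError(f"stimulation site {stim.site_px} outside frame")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    F0 = flatfield(acq)
    common = 1.0 + shared_components(acq, art)[:, None, None]
    R = response_field(acq, stim, resp)
    A = _artifact_field(acq, stim, art)

    shape = (acq.n_frames, acq.height_px, acq.width_px)
    stim_data = np.empty((n_stim_trials,) + shape)
    blank_data = np.empty((n_blank_trials,) + shape)
    clean_stim = F0[None, :, :] * (common + R + A)
    clean_blank = F0[None, :, :] * common
    for i in range(n_stim_trials):
        stim_data[i] = clean_stim + rng.normal(0.0, art.noise_sd, shape) \
            if art.noise_sd > 0 else clean_stim
    for i in range(n_blank_trials):
        blank_data[i] = clean_blank + rng.normal(0.0, art.noise_sd, shape) \
            if art.noise_sd > 0 else clean_blank

    stim_stack = TrialStack(stim_data, acq, stim=stim,
                            session_id=session_id, condition=condition)
    blank_stack = TrialStack(blank_data, acq, stim=None,
                             session_id=session_id, condition="blank")
    truth = GroundTruth(resp=resp, art=art, stim=stim,
                        center_px=stim.site_px, dff=R, seed=seed)
    return stim_stack, blank_stack, truth


def simulate_yfp_image(acq: AcquisitionSpec, center_px: tuple[int, int],
                       extent_um: float, level: float = 1.0,
                       background_sd: float = 0.0, background_level: float = 0.0,
                       seed: int = 0) -> np.ndarray:
    """Single-frame YFP expression image: a bright top-hat patch of radius
    ``extent_um`` around ``center_px`` on a noisy background."""
    if extent_um <= 0:
        raise ValueError("extent_um must be positive")
    half = min(acq.height_px, acq.width_px) * acq.pixel_um / 2.0
    if extent_um > half:
        raise ValueError("extent larger than frame")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    img = np.full((acq.height_px, acq.width_px), background_level, dtype=float)
    img[acq.distance_um(center_px) <= extent_um] += level
    if background_sd > 0:
        img += rng.normal(0.0, background_sd, img.shape)
    return img


def preset(name: str, pulse_ms: Optional[float] = None,
           amplitude: Optional[float] = None,
           ) -> tuple[StimulusSpec, ResponseModel, ArtifactModel]:
    """Study-condition presets for the three stimulation types.

    ``short_exp`` / ``long_exp`` are 3-4 vs 8 weeks of viral ChR2 expression
    (optostimulation, default 10 ms pulse at 15 mW); ``icms`` is the 20 ms /
    500 Hz / 80 uA electrical train.  Peak amplitudes follow the printed
    per-pulse grand means, so amplitude, spatial extent and slow-decay
    weight all increase short_exp < long_exp < icms.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}")
    if name == "icms":
        p = 20.0 if pulse_ms is None else pulse_ms
        stim = StimulusSpec(modality=ICMS, pulse_ms=p, current_ua=80.0,
                            train=(10, 500.0))
        resp = ResponseModel(
            amplitude=PEAK_DFF["icms"].get(p, 5.1e-3), sigma0_um=700.0,
            speed_um_ms=5.0, w_fast=0.45, w_slow=0.55,
            tau_fast_ms=9.0, tau_slow_ms=110.0)
        art = ArtifactModel(laser_artifact_gain=0.0, bleach_radius_um=0.0,
                            bleach_depth=0.0)
    else:
        p = 10.0 if pulse_ms is None else pulse_ms
        stim = StimulusSpec(modality=OPTO, pulse_ms=p, power_mw=15.0)
        if name == "short_exp":
            resp = ResponseModel(
                amplitude=PEAK_DFF["short_exp"].get(p, 1.4e-3), sigma0_um=300.0,
                speed_um_ms=1.0, w_fast=1.0, w_slow=0.0,
                tau_fast_ms=8.0, tau_slow_ms=75.0)
        else:
            resp = ResponseModel(
                amplitude=PEAK_DFF["long_exp"].get(p, 3.6e-3), sigma0_um=550.0,
                speed_um_ms=4.0, w_fast=0.55, w_slow=0.45,
                tau_fast_ms=9.0, tau_slow_ms=75.0)
        art = ArtifactModel()
    if amplitude is not None:
        resp = replace(resp, amplitude=amplitude)
    return stim, resp, art


def _biexp(dt: np.ndarray, w: float, tau_fast: float, tau_slow: float) -> np.ndarray:
    return w * np.exp(-dt / tau_fast) + (1.0 - w) * np.exp(-dt / tau_slow)


def fit_biexp_decay(time_ms: np.ndarray, values: np.ndarray,
                    t_peak_ms: float = 20.0) -> tuple[float, float, float]:
    """Fit a unit-peak bi-exponential to a decaying time course.

    Returns ``(w_fast, tau_fast_ms, tau_slow_ms)``.  The sample at
    ``t_peak_ms`` normalizes the trace; the fast/slow components are
    identified by bounding tau_fast below 40 ms and tau_slow above it.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    values = np.asarray(values, dtype=float)
    sel = (time_ms >= t_peak_ms) & np.isfinite(values)
    t = time_ms[sel] - t_peak_ms
    peak = values[sel][np.argmin(t)]
    if peak <= 0:
        raise ValueError("non-positive peak value")
    y = values[sel] / peak
    popt, _ = curve_fit(_biexp, t, y, p0=(0.5, 10.0, 80.0),
                        bounds=([0.0, 1.0, 40.0], [1.0, 40.0, 1000.0]),
                        maxfev=20000)
    return float(popt[0]), float(popt[1]), float(popt[2])
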