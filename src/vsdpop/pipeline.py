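"""End-to-end study runner: simulate -> preprocess -> analyze -> report.

Reproduces the full analysis battery on synthetic sessions: per-session
peak-ROI time courses with the three normalization schemes, ring space-time
maps with summed activation, decay-time-to-threshold maps with central and
distal distributions, YFP expression-area quantification with the shuffle
control, and the nonparametric group comparisons.  Every random choice
derives from one seed; rerunning a config reproduces identical tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import decay as dcy
from . import preprocess as pp
from . import rings as rg
from . import stats as st
from . import synth
from . import timecourse as tcm
from . import yfp as yq
from .config import PipelineConfig
from .core import AcquisitionSpec, DffMovie

log = logging.getLogger("vsdpop")

GROUPS = ("short_exp", "long_exp", "icms")


@dataclass
class SessionAnalysis:
    """All derived quantities of one condition of one session."""

    group: str
    pulse_ms: float
    session_id: str
    center_px: tuple[int, int]
    tc_raw: tcm.TimeCourse
    peak_raw: float
    summed_raw: float
    summed_norm: float
    stm_raw: rg.SpaceTimeMap
    stm_norm: rg.SpaceTimeMap
    decay_maps: dict[float, dcy.DecayMap]
    rings: rg.RingSet
    trial_tcs: Optional[np.ndarray] = None  # (trials, frames) ROI means
    n_bleached_px: int = 0


@dataclass
class StudyResult:
    sessions: list[SessionAnalysis]
    norm_peaks: pd.DataFrame
    summed: pd.DataFrame
    decay_summary: pd.DataFrame
    yfp_counts: pd.DataFrame
    yfp_shuffle: yq.ShuffleResult
    comparisons: pd.DataFrame
    first_last: tuple[st.ComparisonResult, st.ComparisonResult]

    def by_group(self, group: str, pulse_ms: Optional[float] = None
                 ) -> list[SessionAnalysis]:
        out = [s for s in self.sessions if s.group == group]
        if pulse_ms is not None:
            out = [s for s in out if s.pulse_ms == pulse_ms]
        return out


def _condition_amplitude(rng: np.random.Generator, base: float,
                         gain: float, jitter_sd: float) -> float:
    jitter = np.exp(rng.normal(-jitter_sd ** 2 / 2.0, jitter_sd))
    return base * gain * jitter


def simulate_condition(group: str, pulse_ms: float, seed: int,
                       acq: Optional[AcquisitionSpec] = None,
                       n_stim_trials: int = 12, n_blank_trials: int = 10,
                       amplitude: Optional[float] = None,
                       session_id: str = "", noise_sd: Optional[float] = None,
                       ):
    """One condition of one synthetic session (stimulated, blank, truth)."""
    acq = acq or AcquisitionSpec()
    stim, resp, art = synth.preset(group, pulse_ms=pulse_ms, amplitude=amplitude)
    if noise_sd is not None:
        from dataclasses import replace
        art = replace(art, noise_sd=noise_sd)
    return synth.simulate_session(
        acq, stim, resp, art, n_stim_trials=n_stim_trials,
        n_blank_trials=n_blank_trials, seed=seed, session_id=session_id,
        condition=f"{group}_{pulse_ms:g}ms")


def analyze_movie(movie: DffMovie, config: PipelineConfig,
                  group: str, pulse_ms: float,
                  center: Optional[tuple[int, int]] = None) -> SessionAnalysis:
    """Run the full per-session analysis chain on a preprocessed movie.

    ``center`` overrides peak detection; a session's ROI is located on its
    strongest (longest-pulse) condition and shared by the weaker pulses,
    which have too little signal to localize the peak reliably on their own.
    """
    if center is None:
        center = tcm.find_peak_center(movie, smooth_px=config.smooth_px)
    roi = tcm.CircleROI(center, radius_px=config.roi_radius_px)
    tc = tcm.extract_tc(movie, roi)

    ring_set = rg.build_rings(center, movie.acq, step_um=config.ring_step_um,
                              max_radius_um=config.ring_max_radius_um)
    stm = rg.spacetime_map(movie, ring_set, center_mode=config.ring_center_mode)
    stm_norm = rg.normalize_to_center(stm)
    summed_raw = rg.summed_activation(stm)
    summed_norm = rg.summed_activation(stm_norm)

    maps = {thr: dcy.decay_time_map(movie, thr) for thr in config.decay_thresholds}

    trial_tcs = None
    if movie.trial_data is not None:
        mask = roi.member_mask(movie.data.shape[1:]) & movie.valid_pixels
        trial_tcs = movie.trial_data[:, :, mask].mean(axis=2)

    return SessionAnalysis(
        group=group, pulse_ms=pulse_ms, session_id=movie.session_id,
        center_px=center, tc_raw=tc, peak_raw=tc.at(tcm.T_PEAK_MS),
        summed_raw=summed_raw, summed_norm=summed_norm,
        stm_raw=stm, stm_norm=stm_norm, decay_maps=maps, rings=ring_set,
        trial_tcs=trial_tcs,
        n_bleached_px=int((~movie.valid_pixels).sum()),
    )


def run_all(config: PipelineConfig, write: bool = True) -> StudyResult:
    """Execute the whole study and (optionally) write its tables.

    Opto sessions contain all pulse durations of their group (sharing one
    session gain, which the 10 ms normalization is designed to cancel);
    ICMS sessions hold the single 20 ms train condition.
    """
    acq = AcquisitionSpec()
    master = np.random.default_rng(np.random.SeedSequence(config.seed))
    sessions: list[SessionAnalysis] = []

    for group in GROUPS:
        pulses = (20.0,) if group == "icms" else config.opto_pulses_ms
        # strongest condition first: it defines the session's ROI center
        pulses = tuple(sorted(pulses, reverse=True))
        for s in range(config.n_sessions):
            sid = f"{group}_s{s:02d}"
            gain = float(np.exp(master.normal(-config.session_gain_sd ** 2 / 2.0,
                                              config.session_gain_sd)))
            session_center = None
            for pulse in pulses:
                base = synth.PEAK_DFF[group][pulse]
                amp = _condition_amplitude(master, base, gain,
                                           config.condition_jitter_sd)
                seed = int(master.integers(0, 2 ** 31 - 1))
                stim_stack, blank_stack, _ = simulate_condition(
                    group, pulse, seed, acq=acq,
                    n_stim_trials=config.n_stim_trials,
                    n_blank_trials=config.n_blank_trials,
                    amplitude=amp, session_id=sid)
                movie = pp.preprocess_session(
                    stim_stack, blank_stack,
                    search_radius_um=config.bleach_search_radius_um,
                    neg_threshold=config.bleach_neg_threshold,
                    window_ms=config.bleach_window_ms)
                sa = analyze_movie(movie, config, group, pulse,
                                   center=session_center)
                session_center = sa.center_px
                log.info("%s pulse=%gms: center=%s, %d frames masked, "
                         "%d pixels bleached", sid, pulse, sa.center_px,
                         int((~movie.valid_frames).sum()), sa.n_bleached_px)
                sessions.append(sa)

    norm_peaks = _normalized_peaks(sessions, config)
    summed = pd.DataFrame(
        [{"session": s.session_id, "group": s.group, "pulse_ms": s.pulse_ms,
          "summed_raw": s.summed_raw, "summed_norm": s.summed_norm}
         for s in sessions])
    decay_summary = _decay_summary(sessions, config)
    yfp_counts, yfp_shuffle = _yfp_analysis(config, acq, master)
    comparisons = _group_comparisons(sessions, norm_peaks)
    first_last = _first_last(sessions)

    result = StudyResult(sessions=sessions, norm_peaks=norm_peaks,
                         summed=summed, decay_summary=decay_summary,
                         yfp_counts=yfp_counts, yfp_shuffle=yfp_shuffle,
                         comparisons=comparisons, first_last=first_last)
    if write:
        _write_tables(result, config)
    return result


def _normalized_peaks(sessions: list[SessionAnalysis],
                      config: PipelineConfig) -> pd.DataFrame:
    """Per-session peaks raw and normalized to the 10 ms condition."""
    rows = []
    for group in ("short_exp", "long_exp"):
        ids = sorted({s.session_id for s in sessions if s.group == group})
        for sid in ids:
            tcs = {s.pulse_ms: s.tc_raw for s in sessions
                   if s.session_id == sid}
            normed = tcm.normalize_to_10ms(tcs)
            for pulse, tc in normed.items():
                raw = tcs[pulse].at(tcm.T_PEAK_MS)
                rows.append({"session": sid, "group": group, "pulse_ms": pulse,
                             "peak_raw": raw,
                             "peak_norm10": tc.at(tcm.T_PEAK_MS)})
    for s in sessions:
        if s.group == "icms":
            rows.append({"session": s.session_id, "group": "icms",
                         "pulse_ms": s.pulse_ms, "peak_raw": s.peak_raw,
                         "peak_norm10": np.nan})
    return pd.DataFrame(rows)


def _decay_summary(sessions: list[SessionAnalysis],
                   config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for group in GROUPS:
        pulse = 20.0 if group == "icms" else 10.0
        sel = [s for s in sessions if s.group == group and s.pulse_ms == pulse
               and s.session_id not in config.excluded_sessions]
        for thr in config.decay_thresholds:
            dists = dcy.decay_distributions([s.decay_maps[thr] for s in sel],
                                            [s.rings for s in sel])
            for band, label in ((dcy.CENTRAL_BAND, "central"),
                                (dcy.DISTAL_BAND, "distal")):
                d = dists[band]
                rows.append({"group": group, "threshold": thr, "band": label,
                             "median_ms": d["median_ms"], "mad_ms": d["mad_ms"],
                             "n_pixels": d["n_pixels"]})
    return pd.DataFrame(rows)


def _yfp_analysis(config: PipelineConfig, acq: AcquisitionSpec,
                  master: np.random.Generator
                  ) -> tuple[pd.DataFrame, yq.ShuffleResult]:
    rows = []
    for group in ("short_exp", "long_exp"):
        for a in range(config.yfp_animals_per_group):
            extent = config.yfp_extent_um[group] * float(
                np.exp(master.normal(0.0, 0.1)))
            seed = int(master.integers(0, 2 ** 31 - 1))
            img = synth.simulate_yfp_image(
                acq, center_px=(50, 50), extent_um=extent, level=1.0,
                background_sd=config.yfp_background_sd,
                background_level=0.1, seed=seed)
            yimg = yq.normalize_yfp(yq.YFPImage(img, animal_id=f"{group}_a{a}",
                                                group=group))
            rows.append({"animal": f"{group}_a{a}", "group": group,
                         "extent_um": extent,
                         "n_pixels": yq.count_expressing_pixels(yimg)})
    df = pd.DataFrame(rows)
    shuffle_seed = int(master.integers(0, 2 ** 31 - 1))
    shuffle = yq.group_difference_shuffle(
        df["n_pixels"].to_numpy(float), df["group"].to_numpy(),
        n_perm=config.yfp_n_perm, seed=shuffle_seed)
    return df, shuffle


def _group_comparisons(sessions: list[SessionAnalysis],
                       norm_peaks: pd.DataFrame) -> pd.DataFrame:
    """The reported rank-sum panels with Bonferroni correction."""
    rows = []

    def peaks(group: str, pulse: float) -> np.ndarray:
        sel = norm_peaks[(norm_peaks.group == group)
                         & (norm_peaks.pulse_ms == pulse)]
        return sel["peak_raw"].to_numpy(float)

    # short vs long raw peak, per pulse duration (family of 3)
    for pulse in (2.0, 5.0, 10.0):
        r = st.rank_sum(peaks("short_exp", pulse), peaks("long_exp", pulse),
                        label=f"peak short vs long, {pulse:g} ms")
        r.p_adjusted = st.bonferroni(r.p_value, 3)
        rows.append(r)
    # cross-modality peaks at matched durations (family of 3)
    trio = {"short_exp": peaks("short_exp", 10.0),
            "long_exp": peaks("long_exp", 10.0),
            "icms": peaks("icms", 20.0)}
    pairs = [("short_exp", "long_exp"), ("short_exp", "icms"),
             ("long_exp", "icms")]
    for a, b in pairs:
        r = st.rank_sum(trio[a], trio[b], label=f"peak {a} vs {b}")
        r.p_adjusted = st.bonferroni(r.p_value, 3)
        rows.append(r)
    # summed activation, normalized maps (family of 3)
    summed = {g: [s.summed_norm for s in sessions if s.group == g
                  and s.pulse_ms in (10.0, 20.0)] for g in GROUPS}
    for a, b in pairs:
        r = st.rank_sum(summed[a], summed[b],
                        label=f"summed activation {a} vs {b}")
        r.p_adjusted = st.bonferroni(r.p_value, 3)
        rows.append(r)
    return pd.DataFrame([vars(r) for r in rows])


def _first_last(sessions: list[SessionAnalysis]
                ) -> tuple[st.ComparisonResult, st.ComparisonResult]:
    icms = [s for s in sessions if s.group == "icms" and s.trial_tcs is not None]
    time_ms = icms[0].tc_raw.time_ms
    return st.first_last_trial_check([s.trial_tcs for s in icms], time_ms)


def _write_tables(result: StudyResult, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    tc_rows = []
    for s in result.sessions:
        tc = s.tc_raw
        for t, v, e in zip(tc.time_ms, tc.values,
                           tc.sem if tc.sem is not None else np.full_like(tc.values, np.nan)):
            tc_rows.append({"session": s.session_id, "group": s.group,
                            "pulse_ms": s.pulse_ms, "normalization": "raw",
                            "time_ms": t, "value": v, "sem": e,
                            "n": tc.n_trials})
    pd.DataFrame(tc_rows).to_csv(out / "timecourses.csv", index=False)
    result.norm_peaks.to_csv(out / "peaks.csv", index=False)
    result.summed.to_csv(out / "summed_activation.csv", index=False)
    result.decay_summary.to_csv(out / "decay_summary.csv", index=False)
    result.yfp_counts.to_csv(out / "yfp_counts.csv", index=False)
    pd.DataFrame([{
        "observed": result.yfp_shuffle.observed,
        "shuffle_mean": result.yfp_shuffle.shuffle_mean,
        "shuffle_std": result.yfp_shuffle.shuffle_std,
        "z_score": result.yfp_shuffle.z_score,
        "n_permutations": result.yfp_shuffle.n_permutations,
    }]).to_csv(out / "yfp_shuffle.csv", index=False)
    fl_peak, fl_slow = result.first_last
    rows = result.comparisons.to_dict("records") + [vars(fl_peak), vars(fl_slow)]
    pd.DataFrame(rows).to_csv(out / "stats.csv", index=False)
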