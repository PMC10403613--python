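"""Run configuration: one plain-YAML document drives a full pipeline run.

A run's config snapshot is written next to its outputs so every table is
reproducible from the snapshot alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All tunables of a full simulate -> analyze run."""

    out_dir: str = "results/run"
    seed: int = 0

    # study design
    n_sessions: int = 6
    n_stim_trials: int = 12
    n_blank_trials: int = 10
    opto_pulses_ms: tuple[float, ...] = (2.0, 5.0, 10.0)
    # across-session amplitude variability: one multiplicative gain per
    # session (staining/expression quality) plus per-condition jitter
    session_gain_sd: float = 0.2
    condition_jitter_sd: float = 0.08

    # preprocessing
    bleach_search_radius_um: float = 500.0
    bleach_neg_threshold: float = -0.002
    bleach_window_ms: tuple[float, float] = (10.0, 40.0)

    # ROI / rings / decay
    roi_radius_px: float = 5.0
    smooth_px: int = 3
    ring_step_um: float = 50.0
    ring_max_radius_um: float = 2000.0
    ring_center_mode: str = "rings1_5"
    decay_thresholds: tuple[float, float] = (0.7, 0.3)
    slow_phase_ms: tuple[float, float] = (60.0, 100.0)

    # YFP quantification
    yfp_animals_per_group: int = 3
    yfp_extent_um: dict = field(default_factory=lambda: {
        "short_exp": 430.0, "long_exp": 590.0})
    yfp_background_sd: float = 0.05
    yfp_n_perm: int = 10000

    # statistics
    excluded_sessions: tuple[str, ...] = ()

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for f in dataclasses.fields(cls):
            if f.name in d and isinstance(getattr(cls(), f.name), tuple):
                d[f.name] = tuple(d[f.name])
        return cls(**d)
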