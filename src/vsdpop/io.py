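"""TIFF + YAML-sidecar readers/writers for sessions and derived movies.

Layout of one simulated session directory::

    <dir>/
      stim.tif        4-D stimulated stack (trials, frames, rows, cols)
      blank.tif       4-D blank stack
      truth_dff.tif   noiseless response-only dF/f movie (ground truth)
      meta.yaml       acquisition, stimulus, generator parameters, seed

Derived dF/f movies are written as float32 TIFF with NaN for invalid
entries plus mask TIFFs and their own sidecar.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
import yaml

from .core import AcquisitionSpec, DffMovie, StimulusSpec, TrialStack
from .synth import ArtifactModel, GroundTruth, ResponseModel


def _spec_to_dict(obj) -> dict:
    d = dataclasses.asdict(obj)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def _stim_from_dict(d: Optional[dict]) -> Optional[StimulusSpec]:
    if d is None:
        return None
    d = dict(d)
    d["site_px"] = tuple(d["site_px"])
    if d.get("train") is not None:
        d["train"] = tuple(d["train"])
    return StimulusSpec(**d)


def save_session(directory: str | Path, stim_stack: TrialStack,
                 blank_stack: TrialStack, truth: Optional[GroundTruth] = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "stim.tif", stim_stack.data.astype(np.float32))
    tifffile.imwrite(directory / "blank.tif", blank_stack.data.astype(np.float32))
    meta = {
        "acq": _spec_to_dict(stim_stack.acq),
        "stim": _spec_to_dict(stim_stack.stim) if stim_stack.stim else None,
        "session_id": stim_stack.session_id,
        "condition": stim_stack.condition,
    }
    if truth is not None:
        tifffile.imwrite(directory / "truth_dff.tif", truth.dff.astype(np.float32))
        meta["truth"] = {
            "resp": _spec_to_dict(truth.resp),
            "art": _spec_to_dict(truth.art),
            "center_px": list(truth.center_px),
            "seed": truth.seed,
        }
    with open(directory / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return directory


def load_session(directory: str | Path
                 ) -> tuple[TrialStack, TrialStack, Optional[GroundTruth]]:
    directory = Path(directory)
    with open(directory / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    acq = AcquisitionSpec(**meta["acq"])
    stim = _stim_from_dict(meta.get("stim"))
    stim_data = tifffile.imread(directory / "stim.tif").astype(float)
    blank_data = tifffile.imread(directory / "blank.tif").astype(float)
    stim_stack = TrialStack(stim_data, acq, stim=stim,
                            session_id=meta.get("session_id", ""),
                            condition=meta.get("condition", ""))
    blank_stack = TrialStack(blank_data, acq, stim=None,
                             session_id=meta.get("session_id", ""),
                             condition="blank")
    truth = None
    tmeta = meta.get("truth")
    if tmeta is not None and (directory / "truth_dff.tif").exists():
        truth = GroundTruth(
            resp=ResponseModel(**tmeta["resp"]),
            art=ArtifactModel(**tmeta["art"]),
            stim=stim,
            center_px=tuple(tmeta["center_px"]),
            dff=tifffile.imread(directory / "truth_dff.tif").astype(float),
            seed=tmeta["seed"],
        )
    return stim_stack, blank_stack, truth


def save_dff(directory: str | Path, movie: DffMovie) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "dff.tif", movie.data.astype(np.float32))
    tifffile.imwrite(directory / "valid_pixels.tif",
                     movie.valid_pixels.astype(np.uint8))
    meta = {
        "acq": _spec_to_dict(movie.acq),
        "stim": _spec_to_dict(movie.stim) if movie.stim else None,
        "valid_frames": movie.valid_frames.astype(int).tolist(),
        "n_trials": movie.n_trials,
        "condition": movie.condition,
        "session_id": movie.session_id,
    }
    with open(directory / "dff_meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return directory


def load_dff(directory: str | Path) -> DffMovie:
    directory = Path(directory)
    with open(directory / "dff_meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    acq = AcquisitionSpec(**meta["acq"])
    return DffMovie(
        data=tifffile.imread(directory / "dff.tif").astype(float),
        acq=acq,
        valid_frames=np.asarray(meta["valid_frames"], dtype=bool),
        valid_pixels=tifffile.imread(directory / "valid_pixels.tif").astype(bool),
        n_trials=meta["n_trials"],
        stim=_stim_from_dict(meta.get("stim")),
        condition=meta.get("condition", ""),
        session_id=meta.get("session_id", ""),
    )


def save_yfp(path: str | Path, image: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, image.astype(np.float32))
    return path


def load_yfp(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(float)
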