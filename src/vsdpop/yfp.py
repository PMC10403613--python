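"""YFP expression-area quantification and the label-shuffle group control.

Opsin expression is visualized in vivo as YFP fluorescence through the
imaging window; brighter areas mark higher ChR2 expression.  Each animal's
image is first normalized between 0 and 1 (min-max within the imaging
chamber, to account for differences in imaging conditions), then the
expressing area is the count of pixels exceeding 2 standard deviations
above the image mean.  Group differences (short vs long expression time)
are assessed against a label-shuffle null: the observed mean difference is
compared with its distribution under permuted group labels.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass
class YFPImage:
    """Single-frame YFP fluorescence image of one animal."""

    data: np.ndarray
    chamber_mask: Optional[np.ndarray] = None
    normalized: bool = False
    animal_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        if self.chamber_mask is None:
            self.chamber_mask = np.ones(self.data.shape, dtype=bool)
        if self.chamber_mask.shape != self.data.shape:
            raise ValueError("chamber mask shape mismatch")


def normalize_yfp(img: YFPImage, clip_percentiles: Optional[tuple[float, float]] = None
                  ) -> YFPImage:
    """Min-max scale to [0, 1] within the chamber mask.

    ``clip_percentiles`` (e.g. ``(1, 99)``) optionally replaces the min/max
    by robust percentiles, with the result clipped to [0, 1].  Idempotent on
    already-normalized images.
    """
    vals = img.data[img.chamber_mask]
    if clip_percentiles is None:
        lo, hi = float(vals.min()), float(vals.max())
    else:
        lo, hi = np.percentile(vals, clip_percentiles)
    if hi <= lo:
        raise ValueError("constant image: cannot normalize")
    out = np.clip((img.data - lo) / (hi - lo), 0.0, 1.0)
    return YFPImage(data=out, chamber_mask=img.chamber_mask.copy(),
                    normalized=True, animal_id=img.animal_id, group=img.group)


def count_expressing_pixels(img: YFPImage) -> int:
    """Chamber pixels strictly above mean + 2 STD of the chamber pixels."""
    if not img.normalized:
        raise ValueError("image must be normalized first")
    vals = img.data[img.chamber_mask]
    thr = vals.mean() + 2.0 * vals.std()
    return int((vals > thr).sum())


@dataclass
class ShuffleResult:
    """Observed group difference vs the permuted-label null."""

    observed: float
    shuffle_mean: float
    shuffle_std: float
    z_score: float
    n_permutations: int
    exhaustive: bool
    shuffled: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def group_difference_shuffle(counts: Sequence[float], groups: Sequence[str],
                             group_a: str = "long_exp", group_b: str = "short_exp",
                             n_perm: int = 10000, seed: int = 0) -> ShuffleResult:
    """Observed mean(group_a) - mean(group_b) against the shuffled null.

    All distinct label assignments are enumerated when there are at most
    ``n_perm`` of them; otherwise ``n_perm`` random permutations are drawn
    with the given seed.
    """
    counts = np.asarray(counts, dtype=float)
    groups = np.asarray(groups)
    a = counts[groups == group_a]
    b = counts[groups == group_b]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two animals per group")
    observed = float(a.mean() - b.mean())

    n = counts.size
    n_a = a.size
    n_comb = math.comb(n, n_a)
    if n_comb <= n_perm:
        diffs = np.empty(n_comb)
        total = counts.sum()
        for i, idx in enumerate(itertools.combinations(range(n), n_a)):
            sa = counts[list(idx)].sum()
            diffs[i] = sa / n_a - (total - sa) / (n - n_a)
        exhaustive = True
    else:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        diffs = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(n)
            sa = counts[perm[:n_a]].sum()
            diffs[i] = sa / n_a - (counts.sum() - sa) / (n - n_a)
        exhaustive = False
    mean = float(diffs.mean())
    std = float(diffs.std(ddof=1))
    z = (observed - mean) / std if std > 0 else float("nan")
    return ShuffleResult(observed=observed, shuffle_mean=mean, shuffle_std=std,
                         z_score=float(z), n_permutations=diffs.size,
                         exhaustive=exhaustive, shuffled=diffs)
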