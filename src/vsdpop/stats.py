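"""Nonparametric group comparisons and summaries used across the pipeline.

Comparisons across sessions and conditions use the two-sided Wilcoxon
rank-sum (Mann-Whitney) test for independent samples and the Wilcoxon
signed-rank test for paired samples, with Bonferroni correction for
multiple comparisons.  Small samples get exact null distributions computed
by dynamic programming over midrank subset sums (valid under ties); larger
samples fall back to the tie-corrected normal approximation.  Summaries
are mean +/- SEM or median +/- MAD.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

EXACT_RANKSUM_MAX_N = 20  # combined sample size for the exact rank-sum null
EXACT_SIGNRANK_MAX_N = 15

#: Window (ms) defining the slow decay phase of the response time course.
SLOW_PHASE_MS = (60.0, 100.0)


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    test: str
    label: str = ""
    p_adjusted: Optional[float] = None


def bonferroni(p: float, n_comparisons: int) -> float:
    """Bonferroni-adjusted p: min(1, p * m); monotone, capped at 1."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return min(1.0, p * n_comparisons)


@lru_cache(maxsize=128)
def _subset_sum_counts(ranks2: tuple[int, ...], k: int) -> np.ndarray:
    """Number of k-subsets of ``ranks2`` (doubled midranks) per sum.

    dp[j, s] = number of j-subsets summing to s; returns dp[k, :].
    """
    total = sum(ranks2)
    dp = np.zeros((k + 1, total + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        for j in range(min(k, len(ranks2)), 0, -1):
            dp[j, r:] += dp[j - 1, : total + 1 - r]
    return dp[k]


def _two_sided_exact_p(counts: np.ndarray, stat2: int, mu4: int) -> float:
    """P(|S - mu| >= |stat - mu|) for the integer-valued null in ``counts``.

    ``counts`` is indexed by the statistic on the doubled-midrank scale;
    ``stat2`` is the observed value on that scale and ``mu4`` is twice the
    null mean on it, so all deviation arithmetic stays integral.
    """
    s = np.arange(counts.size)
    dev = np.abs(2 * s - mu4)
    obs = abs(2 * stat2 - mu4)
    return float(counts[dev >= obs].sum() / counts.sum())


def rank_sum(sample_a: Sequence[float], sample_b: Sequence[float],
             label: str = "") -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum test with mid-rank tie handling.

    Exact null distribution (DP over rank subsets) for combined n <= 20;
    tie-corrected normal approximation (scipy Mann-Whitney U) otherwise.
    The reported statistic is the rank sum of ``sample_a``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = float(ranks[: a.size].sum())
    n1, n2 = a.size, b.size
    n = n1 + n2
    if n <= EXACT_RANKSUM_MAX_N:
        ranks2 = tuple(int(round(2 * r)) for r in np.sort(ranks))
        counts = _subset_sum_counts(ranks2, n1)
        # null mean of W is n1*(n+1)/2; twice that on the doubled scale
        p = _two_sided_exact_p(counts, int(round(2 * w)), 2 * n1 * (n + 1))
        test = "rank-sum (exact)"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        test = "rank-sum (normal approx.)"
    return ComparisonResult(statistic=w, p_value=p, n1=n1, n2=n2,
                            test=test, label=label)


def sign_rank(paired_a: Sequence[float], paired_b: Sequence[float],
              label: str = "") -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; an all-zero difference vector leaves the
    test undefined and raises.  Exact (DP over sign patterns) for n <= 15,
    normal approximation otherwise.  Statistic: sum of positive-difference
    ranks W+.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.size < 1:
        raise ValueError("paired samples must have equal non-zero length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero: signed-rank test undefined")
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_SIGNRANK_MAX_N:
        ranks2 = tuple(int(round(2 * r)) for r in np.sort(ranks))
        total2 = sum(ranks2)
        # null: each rank enters W+ independently with probability 1/2
        counts = np.zeros(total2 + 1)
        counts[0] = 1.0
        for r in ranks2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: total2 + 1 - r]
            counts = counts + shifted
        p = _two_sided_exact_p(counts, int(round(2 * w_plus)), total2)
        test = "sign-rank (exact)"
    else:
        res = sps.wilcoxon(d, zero_method="wilcox", correction=True,
                           alternative="two-sided", method="approx")
        p = float(res.pvalue)
        test = "sign-rank (normal approx.)"
    return ComparisonResult(statistic=w_plus, p_value=p, n1=n, n2=n,
                            test=test, label=label)


def summarize(sample: Sequence[float], mode: str = "mean_sem") -> tuple[float, float]:
    """(center, spread): mean +/- SEM or median +/- MAD (unscaled).

    Spread is NaN for a single observation in mean_sem mode.
    """
    x = np.asarray(sample, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("empty sample")
    if mode == "mean_sem":
        center = float(x.mean())
        spread = float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")
    elif mode == "median_mad":
        center = float(np.median(x))
        spread = float(np.median(np.abs(x - center)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return center, spread


def first_last_trial_check(session_trial_tcs: Sequence[np.ndarray],
                           time_ms: np.ndarray,
                           t_peak_ms: float = 20.0,
                           slow_window_ms: tuple[float, float] = SLOW_PHASE_MS,
                           ) -> tuple[ComparisonResult, ComparisonResult]:
    """Electrode-integrity check: first vs last trials across sessions.

    ``session_trial_tcs`` holds, per session, a (trials x frames) matrix of
    ROI time courses.  Compares across sessions the first-trial vs
    last-trial peak response (value at t = 20 ms) and the slow-decay-phase
    amplitude (mean over the slow window) with rank-sum tests.  A stable
    electrode predicts no significant difference in either.
    """
    if len(session_trial_tcs) < 2:
        raise ValueError("need at least two sessions")
    time_ms = np.asarray(time_ms, dtype=float)
    kp = np.flatnonzero(np.isclose(time_ms, t_peak_ms))
    if kp.size != 1:
        raise ValueError(f"no unique frame at t = {t_peak_ms} ms")
    slow = (time_ms >= slow_window_ms[0]) & (time_ms <= slow_window_ms[1])
    firsts_peak, lasts_peak, firsts_slow, lasts_slow = [], [], [], []
    for tcs in session_trial_tcs:
        tcs = np.asarray(tcs, dtype=float)
        if tcs.ndim != 2 or tcs.shape[0] < 2:
            raise ValueError("each session needs at least two trials")
        firsts_peak.append(tcs[0, kp[0]])
        lasts_peak.append(tcs[-1, kp[0]])
        firsts_slow.append(tcs[0, slow].mean())
        lasts_slow.append(tcs[-1, slow].mean())
    peak_cmp = rank_sum(firsts_peak, lasts_peak, label="first vs last trial: peak")
    slow_cmp = rank_sum(firsts_slow, lasts_slow,
                        label="first vs last trial: slow-phase amplitude")
    return peak_cmp, slow_cmp
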