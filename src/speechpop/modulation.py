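"""Cross-validated neural population distances and modulation statistics.

The core statistic is an unbiased, cross-validated estimate of the squared
Euclidean distance between two conditions' mean firing-rate vectors:

    D = (1/N1)(1/N2) sum_i sum_j (y1_i - y2_j)^T (mean(y1 \\ i) - mean(y2 \\ j))

where the leave-one-out means exclude the trial in the left factor, so the
dot product pairs fully non-overlapping trial sets.  D is unbiased for
||mu1 - mu2||^2 and can be negative; the signed distance reported is
d = sign(D) * sqrt(|D|), in Hz.  An algebraically equivalent closed form,

    D = ||ybar1 - ybar2||^2 - tr(S1)/N1 - tr(S2)/N2

(S_k the unbiased sample covariance), is used for speed; tests verify it
against the literal double sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .preprocess import EpochRates, single_trial_rates
from .synthetic import Dataset

__all__ = [
    "ConditionRates",
    "DistanceResult",
    "cv_distance",
    "cv_squared_distance_timecourse",
    "distance_timecourse",
    "epoch_mean",
    "epoch_comparison",
    "modulation_ratio",
    "electrode_significance",
    "within_condition_distance",
]


@dataclass
class ConditionRates:
    """Two trials x units rate matrices to be compared."""

    A: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        if self.A.shape[1] != self.B.shape[1]:
            raise ValueError("unit counts differ")
        if self.A.shape[0] < 2 or self.B.shape[0] < 2:
            raise ValueError("need >= 2 trials per condition "
                             "(leave-one-out means undefined otherwise)")


@dataclass
class DistanceResult:
    D: float          # squared-distance estimate, Hz^2 (may be negative)
    d: float          # signed distance, Hz: sign(D) * sqrt(|D|)
    n1: int
    n2: int
    n_units: int


def _cv_D(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Closed form of the cross-validated squared distance.

    ``a``/``b`` have trials on axis 0 and may carry trailing axes (units, or
    units x time); the result is reduced over the unit axis (axis 1) only.
    """
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    var_a = a.var(axis=0, ddof=1)
    var_b = b.var(axis=0, ddof=1)
    diff = mu_a - mu_b
    return (diff * diff).sum(axis=0) - var_a.sum(axis=0) / a.shape[0] \
        - var_b.sum(axis=0) / b.shape[0]


def _signed_sqrt(D):
    return np.sign(D) * np.sqrt(np.abs(D))


def cv_distance(pair: ConditionRates | None = None, *,
                A: np.ndarray | None = None,
                B: np.ndarray | None = None) -> DistanceResult:
    """Cross-validated signed neural distance between two conditions."""
    if pair is None:
        pair = ConditionRates(A, B)
    D = float(_cv_D(pair.A, pair.B))
    return DistanceResult(D=D, d=float(_signed_sqrt(D)),
                          n1=pair.A.shape[0], n2=pair.B.shape[0],
                          n_units=pair.A.shape[1])


def cv_squared_distance_timecourse(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized D(t) for single-trial rate stacks (trials, units, time)."""
    if a.ndim != 3 or b.ndim != 3:
        raise ValueError("expected (trials, units, time) arrays")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >= 2 trials per condition")
    return _cv_D(a, b)


def distance_timecourse(dataset: Dataset, cond: str, ref_cond: str,
                        alignment: str, window: tuple[float, float],
                        kernel_sd: float = 0.025, bin: float = 0.02,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Signed neural distance between two conditions at each time point.

    Single-trial rates are kernel-smoothed, then the cross-validated distance
    is evaluated independently per time bin.  Typical use compares each spoken
    condition against the silent condition, aligned to the prompt or go cue.
    Returns ``(bin centers, d(t))``.
    """
    ra, _, centers = single_trial_rates(dataset, [cond], alignment, window,
                                        kernel_sd, bin)
    rb, _, _ = single_trial_rates(dataset, [ref_cond], alignment, window,
                                  kernel_sd, bin)
    D = cv_squared_distance_timecourse(ra, rb)
    return centers, _signed_sqrt(D)


def epoch_mean(times: np.ndarray, values: np.ndarray,
               epoch: tuple[float, float]) -> float:
    """Time-average of a series over a half-open epoch."""
    mask = (times >= epoch[0]) & (times < epoch[1])
    if not np.any(mask):
        raise ValueError("epoch contains no time points")
    return float(values[mask].mean())


def epoch_comparison(prompt_means: Sequence[float] | Mapping[str, float],
                     speak_means: Sequence[float] | Mapping[str, float],
                     alternative: str = "two-sided",
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Paired Wilcoxon signed-rank comparison of per-condition epoch means.

    One (prompt, speak) pair per condition; exact p-value for n <= 25 when
    there are no zero differences or ties.
    """
    if isinstance(prompt_means, Mapping):
        if set(prompt_means) != set(speak_means):
            raise ValueError("condition sets differ between epochs")
        keys = sorted(prompt_means)
        prompt = np.array([prompt_means[k] for k in keys], dtype=float)
        speak = np.array([speak_means[k] for k in keys], dtype=float)
    else:
        prompt = np.asarray(prompt_means, dtype=float)
        speak = np.asarray(speak_means, dtype=float)
        if prompt.shape != speak.shape:
            raise ValueError("condition sets differ between epochs")
    if prompt.size < 6:
        raise ValueError("need >= 6 conditions for a meaningful paired test")
    diffs = speak - prompt
    if np.all(diffs == 0):
        return prompt, speak, 1.0
    method = "exact" if prompt.size <= 25 and np.all(diffs != 0) else "auto"
    res = stats.wilcoxon(speak, prompt, alternative=alternative,
                         zero_method="zsplit", method=method)
    return prompt, speak, float(res.pvalue)


def modulation_ratio(prompt_means: Sequence[float],
                     speak_means: Sequence[float]) -> float:
    """Ratio of across-condition mean modulation, speaking epoch / prompt epoch."""
    p = float(np.mean(np.asarray(prompt_means, dtype=float)))
    s = float(np.mean(np.asarray(speak_means, dtype=float)))
    if p <= 0:
        warnings.warn("prompt-epoch mean modulation <= 0; ratio undefined",
                      RuntimeWarning)
        return float("nan")
    return s / p


def electrode_significance(epoch_rates: EpochRates, baseline_cond: str,
                           alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray,
                                                         list[str]]:
    """Per-electrode rank tests of each condition against a baseline condition.

    Two-sided Mann-Whitney (rank-sum) test per electrode x condition,
    Bonferroni-corrected over the number of non-baseline conditions.  Returns
    ``(significant (U, C) bool, pvalues (U, C), condition order)``; the
    per-electrode count of significant conditions is ``significant.sum(1)``.
    """
    labels = epoch_rates.labels
    if baseline_cond not in labels:
        raise ValueError("baseline condition absent")
    conds = [c for c in dict.fromkeys(labels) if c != baseline_cond]
    base = epoch_rates.rates[labels == baseline_cond]
    n_u = epoch_rates.rates.shape[1]
    pvals = np.ones((n_u, len(conds)))
    for j, cond in enumerate(conds):
        x = epoch_rates.rates[labels == cond]
        for u in range(n_u):
            if np.all(x[:, u] == x[0, u]) and np.all(base[:, u] == x[0, u]):
                pvals[u, j] = 1.0       # all samples tied
                continue
            pvals[u, j] = stats.mannwhitneyu(x[:, u], base[:, u],
                                             alternative="two-sided",
                                             method="auto").pvalue
    significant = pvals < alpha / max(len(conds), 1)
    return significant, pvals, conds


def within_condition_distance(A: np.ndarray, n_splits: int = 20,
                              seed: int | np.random.Generator = 0) -> float:
    """Mean signed distance between random half-splits of one condition.

    With an odd trial count the halves have floor/ceil sizes.  This is the
    within-condition ('diagonal') analogue of the between-condition distance
    and is near zero for i.i.d. trials.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    n = A.shape[0]
    if n < 4:
        raise ValueError("need >= 4 trials for half-splits")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    half = n // 2
    ds = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        ds.append(cv_distance(A=A[perm[:half]], B=A[perm[half:]]).d)
    return float(np.mean(ds))
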