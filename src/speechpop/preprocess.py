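"""Alignment, smoothing and normalization of trial-structured spike data.

Conventions: all times are seconds; the alignment event sits at t = 0 of a
window; windows are half-open ``[start, end)``.  Spike trains are binned at
1 ms before convolution with a Gaussian kernel truncated at +/- 4 s.d. and
renormalized at the window edges, which conserves spike count (an isolated
spike integrates to one spike) without edge droop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .synthetic import Dataset

__all__ = [
    "RateTensor",
    "EpochRates",
    "bin_and_smooth",
    "single_trial_rates",
    "trial_average",
    "soft_normalize",
    "undo_soft_normalize",
    "center_across_conditions",
    "uncenter",
    "assign_faux_AO",
    "epoch_mean_rates",
]

_INTERNAL_DT = 0.001


@dataclass
class RateTensor:
    """Trial-averaged firing rates, units x conditions x time.

    ``rates`` is in Hz until soft normalization, dimensionless after.
    ``time`` holds bin centers in seconds relative to the alignment event.
    """

    rates: np.ndarray                 # (U, C, T)
    time: np.ndarray                  # (T,)
    conditions: tuple[str, ...]
    alignment: str
    bin: float
    kernel_sd: float
    normalization: dict | None = None     # {"offset": Hz, "ranges": (U,)}
    centered: bool = False
    condition_mean: np.ndarray | None = None   # (U, T) stored when centered
    trial_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        dt = np.diff(self.time)
        if self.time.size > 1 and (np.any(dt <= 0) or
                                   not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError("time axis must be strictly increasing and uniform")

    @property
    def n_units(self) -> int:
        return self.rates.shape[0]

    def copy(self) -> "RateTensor":
        return replace(self, rates=self.rates.copy(), time=self.time.copy())


@dataclass
class EpochRates:
    """Trials x units mean rates over one window (no smoothing)."""

    rates: np.ndarray                 # (n_trials, U), Hz
    labels: np.ndarray                # condition per trial
    window: tuple[float, float]
    alignment: str


# ------------------------------------------------------------- smoothing

def bin_and_smooth(spike_times: Sequence[np.ndarray], align_time: float,
                   window: tuple[float, float], bin: float, kernel_sd: float,
                   trial_length: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Kernel-smoothed firing rates for one trial.

    ``spike_times`` is one array of event times per unit.  Rates (Hz) are
    computed on an internal 1 ms grid over ``[align_time+start,
    align_time+end)`` then block-averaged to ``bin``.  Returns
    ``(rates (U, T), bin centers relative to align_time)``.
    """
    start, end = window
    if end <= start:
        raise ValueError("empty window")
    if bin > kernel_sd + 1e-12:
        raise ValueError("bin must not exceed kernel_sd")
    if align_time + start < -1e-9:
        raise ValueError("window starts before the trial")
    if trial_length is not None and align_time + end > trial_length + 1e-9:
        raise ValueError("window ends after the trial")

    factor = max(1, int(round(bin / _INTERNAL_DT)))
    n_fine = int(round((end - start) / _INTERNAL_DT))
    n_fine -= n_fine % factor
    n_out = n_fine // factor

    counts = np.zeros((len(spike_times), n_fine))
    t0 = align_time + start
    for u, st in enumerate(spike_times):
        if len(st) == 0:
            continue
        idx = np.floor((np.asarray(st) - t0) / _INTERNAL_DT).astype(np.intp)
        idx = idx[(idx >= 0) & (idx < n_fine)]
        np.add.at(counts[u], idx, 1.0)

    sigma = kernel_sd / _INTERNAL_DT
    sm = gaussian_filter1d(counts, sigma=sigma, axis=1, mode="constant",
                           truncate=4.0)
    norm = gaussian_filter1d(np.ones(n_fine), sigma=sigma, mode="constant",
                             truncate=4.0)
    rates = sm / norm[None, :] / _INTERNAL_DT
    rates = rates.reshape(len(spike_times), n_out, factor).mean(axis=2)
    centers = start + (np.arange(n_out) + 0.5) * factor * _INTERNAL_DT
    return rates, centers


def single_trial_rates(dataset: Dataset, conditions: Sequence[str],
                       alignment: str, window: tuple[float, float],
                       kernel_sd: float, bin: float,
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smoothed rates for every (non-excluded) trial of ``conditions``.

    Returns ``(rates (n_trials, U, T), labels, bin centers)``.
    """
    mats, labels = [], []
    centers = None
    for cond in conditions:
        for tr in dataset.trials_of(cond):
            align_time = tr.events.get(alignment)
            if align_time is None:
                raise ValueError(
                    f"trial of condition {cond!r} lacks event {alignment!r}")
            r, centers = bin_and_smooth(tr.spike_times, align_time, window,
                                        bin, kernel_sd, dataset.trial_length)
            mats.append(r)
            labels.append(cond)
    if not mats:
        raise ValueError("no trials matched")
    return np.stack(mats), np.asarray(labels), centers


def trial_average(dataset: Dataset, alignment: str, window: tuple[float, float],
                  kernel_sd: float, bin: float,
                  conditions: Sequence[str] | None = None) -> RateTensor:
    """Condition-averaged smoothed rates as a units x conditions x time tensor.

    Conditions with zero usable trials are dropped with a warning.
    """
    conditions = tuple(conditions if conditions is not None else dataset.conditions)
    per_cond, kept, counts = [], [], {}
    centers = None
    for cond in conditions:
        trials = dataset.trials_of(cond)
        trials = [tr for tr in trials if tr.events.get(alignment) is not None]
        if not trials:
            warnings.warn(f"condition {cond!r} has no usable trials; dropped",
                          RuntimeWarning)
            continue
        acc = None
        for tr in trials:
            r, centers = bin_and_smooth(tr.spike_times, tr.events[alignment],
                                        window, bin, kernel_sd,
                                        dataset.trial_length)
            acc = r if acc is None else acc + r
        per_cond.append(acc / len(trials))
        kept.append(cond)
        counts[cond] = len(trials)
    if not per_cond:
        raise ValueError("no conditions with usable trials")
    rates = np.stack(per_cond, axis=1)     # (U, C, T)
    return RateTensor(rates=rates, time=centers, conditions=tuple(kept),
                      alignment=alignment, bin=bin, kernel_sd=kernel_sd,
                      trial_counts=counts)


# --------------------------------------------------------- normalization

def soft_normalize(tensor: RateTensor, offset: float) -> RateTensor:
    """Divide each unit by (its rate range across conditions and times + offset).

    The offset ('soft' normalization) keeps weakly modulated units from being
    amplified to the same scale as strongly modulated ones; 5 Hz and 10 Hz
    offsets reproduce the two standard population-dynamics conventions.
    Ranges are stored so the transform can be inverted.
    """
    if tensor.normalization is not None:
        raise ValueError("tensor is already soft-normalized")
    if offset < 0:
        raise ValueError("offset must be nonnegative")
    ranges = tensor.rates.max(axis=(1, 2)) - tensor.rates.min(axis=(1, 2))
    denom = ranges + offset
    rates = np.zeros_like(tensor.rates)
    ok = denom > 0
    if not np.all(ok):
        warnings.warn("constant unit(s) with zero range and zero offset "
                      "mapped to 0", RuntimeWarning)
    rates[ok] = tensor.rates[ok] / denom[ok, None, None]
    out = tensor.copy()
    out.rates = rates
    out.normalization = {"offset": float(offset), "ranges": ranges}
    return out


def undo_soft_normalize(tensor: RateTensor) -> RateTensor:
    if tensor.normalization is None:
        raise ValueError("tensor is not normalized")
    denom = tensor.normalization["ranges"] + tensor.normalization["offset"]
    out = tensor.copy()
    out.rates = tensor.rates * denom[:, None, None]
    out.normalization = None
    return out


def center_across_conditions(tensor: RateTensor) -> RateTensor:
    """Subtract each unit's across-condition mean rate at every time point."""
    if len(tensor.conditions) < 2:
        raise ValueError("need at least 2 conditions to center")
    mean = tensor.rates.mean(axis=1)          # (U, T)
    out = tensor.copy()
    out.rates = tensor.rates - mean[:, None, :]
    out.centered = True
    out.condition_mean = mean
    return out


def uncenter(tensor: RateTensor) -> RateTensor:
    if not tensor.centered or tensor.condition_mean is None:
        raise ValueError("tensor is not centered")
    out = tensor.copy()
    out.rates = tensor.rates + tensor.condition_mean[:, None, :]
    out.centered = False
    out.condition_mean = None
    return out


# ------------------------------------------------------------ event logic

def assign_faux_AO(dataset: Dataset) -> Dataset:
    """Give silent trials a surrogate acoustic onset.

    Each silent trial's AO is set to its go cue plus the mean go-to-AO latency
    of the spoken trials in the same block; blocks without spoken trials fall
    back to the dataset-wide mean with a warning.  Returns a new Dataset;
    spoken trials are untouched.
    """
    latencies: dict[int, list[float]] = {}
    all_lat: list[float] = []
    for tr in dataset.trials:
        if tr.condition != dataset.silent_condition and not tr.excluded \
                and tr.events.get("AO") is not None:
            lat = tr.events["AO"] - tr.events["go"]
            latencies.setdefault(tr.block, []).append(lat)
            all_lat.append(lat)
    new_trials = []
    for tr in dataset.trials:
        if tr.condition == dataset.silent_condition:
            if tr.block in latencies:
                mean_lat = float(np.mean(latencies[tr.block]))
            elif all_lat:
                warnings.warn(f"block {tr.block} has no spoken trials; "
                              "using dataset-wide mean latency", RuntimeWarning)
                mean_lat = float(np.mean(all_lat))
            else:
                new_trials.append(tr)
                continue
            events = dict(tr.events)
            events["AO"] = tr.events["go"] + mean_lat
            tr = replace(tr, events=events)
        new_trials.append(tr)
    return replace(dataset, trials=new_trials)


def epoch_mean_rates(dataset: Dataset, alignment: str,
                     window: tuple[float, float],
                     conditions: Sequence[str] | None = None) -> EpochRates:
    """Spike count / duration per trial and electrode over one window."""
    start, end = window
    if end <= start:
        raise ValueError("empty window")
    conditions = tuple(conditions if conditions is not None else dataset.conditions)
    rows, labels = [], []
    for cond in conditions:
        for tr in dataset.trials_of(cond):
            align_time = tr.events.get(alignment)
            if align_time is None:
                raise ValueError(f"trial lacks event {alignment!r}")
            lo, hi = align_time + start, align_time + end
            if lo < -1e-9 or hi > dataset.trial_length + 1e-9:
                raise ValueError("window outside the recorded span")
            counts = [np.count_nonzero((st >= lo) & (st < hi))
                      for st in tr.spike_times]
            rows.append(np.asarray(counts, dtype=float) / (end - start))
            labels.append(cond)
    return EpochRates(rates=np.vstack(rows), labels=np.asarray(labels),
                      window=window, alignment=alignment)
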