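"""Trial-structured synthetic datasets with planted population latents.

The generator emulates a prompted speaking task recorded with a ~100-electrode
intracortical array: on each trial an audio prompt is played, a go cue follows
about two seconds later, and the participant speaks (acoustic onset, AO) a few
hundred milliseconds after the go cue.  One condition is silent: the prompt is
ambient noise and nothing is spoken.

Each electrode's instantaneous rate is a baseline plus three planted
population-level latents, rectified at zero:

    lambda_e(t) = baseline_e
                + prompt_gain * prompt_loading_e * p(t)      (prompt response)
                + cis_gain    * cis_loading_e    * c(t)      (condition-invariant kick)
                + rot_gain    * [rot_plane @ z_cond(t)]_e    (rotatory latent)
                + tuning_gain * tuning_{e,cond}  * h(t)      (condition tuning)

c(t) is a logistic ramp (150 ms rise, centered 200 ms after go); z_cond obeys
z' = 2*pi*omega*S*z with S the 2x2 unit skew matrix, i.e. a pure rotation at
``rot_freq`` Hz, started shortly before AO with a condition-specific phase;
h(t) gates condition tuning around articulation.  Silent trials carry no
latent drive at all.  Spikes are drawn as an inhomogeneous Poisson process by
thinning; the high-frequency LFP power channel is a smoothed copy of the rate
plus Gaussian noise, rectified.

All gains are population norms in Hz (the loading vectors are unit norm), so
``cis_gain=30`` means the condition-invariant latent displaces the population
firing-rate vector by 30 Hz (Euclidean norm over electrodes) at its plateau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.special import expit

__all__ = [
    "SimConfig",
    "GroundTruth",
    "Trial",
    "Dataset",
    "simulate_speech_task",
    "simulate_phoneme_instances",
    "simulate_condition_pair",
    "make_ci_cd_tensor",
    "make_rotation_tensor",
]

_INTERNAL_DT = 0.001  # rate grid for thinning, seconds

DEFAULT_CONDITIONS = (
    "beet", "bat", "bot", "boot", "dot",
    "got", "shot", "keep", "seal", "more", "silent",
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated prompted-speaking session.

    Durations are seconds, rates Hz.  ``trials_per_condition`` may be a single
    integer or a mapping from condition name to count.  Exactly one condition
    must equal ``silent_condition``.
    """

    n_electrodes: int = 100
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    silent_condition: str = "silent"
    trials_per_condition: int | Mapping[str, int] = 30
    baseline_shape: float = 3.0   # gamma shape of per-electrode baseline rates
    baseline_scale: float = 5.0   # gamma scale (shape*scale = 15 Hz mean)
    prompt_gain: float = 15.0
    cis_gain: float = 30.0
    rot_freq: float = 2.0
    rot_gain: float = 20.0
    rot_lead: float = 0.15        # rotation latent starts this long before AO
    tuning_gain: float = 15.0
    prompt_time: float = 1.0
    prompt_to_go: float = 2.0
    go_to_AO_mean: float = 0.6
    go_to_AO_sd: float = 0.1
    trial_length: float = 5.0
    hlfp_noise_sd: float = 1.0
    hlfp_dt: float = 0.01
    n_blocks: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prompt_gain", "cis_gain", "rot_gain", "tuning_gain",
                     "prompt_time", "prompt_to_go", "go_to_AO_mean",
                     "go_to_AO_sd", "trial_length", "hlfp_noise_sd",
                     "baseline_shape", "baseline_scale", "rot_lead"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_electrodes < 1:
            raise ValueError("n_electrodes must be positive")
        if list(self.conditions).count(self.silent_condition) != 1:
            raise ValueError("exactly one condition must be the silent condition")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("duplicate condition names")
        if not 0 < self.rot_freq < 50:
            raise ValueError("rot_freq must lie in (0, 50) Hz (Nyquist of 10 ms bins)")
        if self.prompt_time + self.prompt_to_go + self.go_to_AO_mean >= self.trial_length:
            raise ValueError("trial_length too short for the event sequence")
        counts = self.trial_counts()
        if any(c < 1 for c in counts.values()):
            raise ValueError("trials_per_condition must be positive")

    def trial_counts(self) -> dict[str, int]:
        if isinstance(self.trials_per_condition, Mapping):
            missing = set(self.conditions) - set(self.trials_per_condition)
            if missing:
                raise ValueError(f"missing trial counts for {sorted(missing)}")
            return {c: int(self.trials_per_condition[c]) for c in self.conditions}
        return {c: int(self.trials_per_condition) for c in self.conditions}

    @property
    def spoken_conditions(self) -> tuple[str, ...]:
        return tuple(c for c in self.conditions if c != self.silent_condition)


@dataclass
class GroundTruth:
    """Planted latents of a simulated session, for parameter-recovery tests."""

    cis_loading: np.ndarray          # (n_electrodes,) unit vector
    rot_plane: np.ndarray            # (n_electrodes, 2) orthonormal columns
    prompt_loading: np.ndarray       # (n_electrodes,) unit vector
    tuning_loadings: np.ndarray      # (n_electrodes, n_conditions); silent col = 0
    baseline: np.ndarray             # (n_electrodes,)
    rot_freq: float
    rot_phase: dict[str, float]      # per-condition initial phase (radians)
    rot_amplitude: float
    rot_onset_before_AO: float
    conditions: tuple[str, ...]
    silent_condition: str
    cis_timecourse: Callable[[np.ndarray], np.ndarray] = field(repr=False, default=None)

    def lambda_timecourse(self, config: SimConfig, condition: str,
                          go: float, ao: float | None,
                          t: np.ndarray) -> np.ndarray:
        """Noiseless per-electrode rate (Hz) for one trial at times ``t``."""
        lam = np.repeat(self.baseline[:, None], t.size, axis=1)
        if condition == self.silent_condition:
            return lam
        prompt = go - config.prompt_to_go
        lam = lam + config.prompt_gain * self.prompt_loading[:, None] * \
            _prompt_timecourse(t - prompt)[None, :]
        lam = lam + config.cis_gain * self.cis_loading[:, None] * \
            _cis_timecourse(t - go)[None, :]
        if ao is not None:
            z = _rotation_latent(t - (ao - self.rot_onset_before_AO),
                                 self.rot_freq, self.rot_phase[condition],
                                 self.rot_amplitude)
            lam = lam + config.rot_gain * (self.rot_plane @ z)
            k = self.conditions.index(condition)
            lam = lam + config.tuning_gain * self.tuning_loadings[:, k:k + 1] * \
                _tuning_gate(t - ao)[None, :]
        return np.clip(lam, 0.0, None)


@dataclass
class Trial:
    condition: str
    spike_times: list[np.ndarray]    # per electrode, sorted seconds
    hlfp_power: np.ndarray | None    # (n_electrodes, n_samples), >= 0
    hlfp_times: np.ndarray | None
    events: dict[str, float | None]  # prompt / go / AO (AO None on silent trials)
    block: int = 0
    excluded: bool = False


@dataclass
class Dataset:
    trials: list[Trial]
    electrode_ids: list[int]
    conditions: tuple[str, ...]
    silent_condition: str
    trial_length: float
    meta: dict = field(default_factory=dict)

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_ids)

    def trials_of(self, condition: str, include_excluded: bool = False) -> list[Trial]:
        return [tr for tr in self.trials
                if tr.condition == condition and (include_excluded or not tr.excluded)]

    @property
    def spoken_conditions(self) -> tuple[str, ...]:
        return tuple(c for c in self.conditions if c != self.silent_condition)


# ----------------------------------------------------------------- latents

def _cis_timecourse(tau: np.ndarray) -> np.ndarray:
    """Condition-invariant kick: 0 before go, logistic ramp after.

    10-90% rise of 150 ms centered 200 ms after the go cue.  The logistic is
    hard-gated at the go cue; its value there (expit(-5.86) ~ 0.003) makes the
    gating step negligible.
    """
    s = 0.150 / (2.0 * np.log(9.0))
    out = expit((tau - 0.200) / s)
    return np.where(tau >= 0.0, out, 0.0)


def _prompt_timecourse(tau: np.ndarray) -> np.ndarray:
    """Auditory-prompt response: smooth plateau over ~[0.1, 0.9] s after prompt."""
    return np.where(tau >= 0.0,
                    expit((tau - 0.10) / 0.03) * expit((0.90 - tau) / 0.08), 0.0)


def _tuning_gate(tau: np.ndarray) -> np.ndarray:
    """Articulation gate relative to AO: on through ~0.75 s of speaking."""
    return np.where(tau >= -0.2,
                    expit((tau - 0.05) / 0.03) * expit((0.75 - tau) / 0.05), 0.0)


def _rotation_latent(tau: np.ndarray, freq: float, phase: float,
                     amplitude: float) -> np.ndarray:
    """2-D rotation z(tau), zero before onset; solves z' = 2 pi f S z."""
    ang = 2.0 * np.pi * freq * tau + phase
    z = amplitude * np.stack([np.cos(ang), np.sin(ang)])
    return np.where(tau[None, :] >= 0.0, z, 0.0)


# ---------------------------------------------------------------- main sim

def simulate_speech_task(config: SimConfig | None = None,
                         seed: int | None = None) -> tuple[Dataset, GroundTruth]:
    """Simulate one prompted-speaking session.

    Returns the trial-structured dataset (spike times, HLFP power, events)
    together with the planted ground truth.  Identical ``(config, seed)``
    yield bit-identical output.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    n_e = config.n_electrodes
    baseline = rng.gamma(config.baseline_shape, config.baseline_scale, size=n_e)
    # cis_loading, rot_plane and prompt_loading drawn jointly orthonormal
    q, _ = np.linalg.qr(rng.standard_normal((n_e, 4)))
    cis_loading, rot_plane, prompt_loading = q[:, 0], q[:, 1:3], q[:, 3]
    tuning = rng.standard_normal((n_e, len(config.conditions)))
    tuning /= np.linalg.norm(tuning, axis=0, keepdims=True)
    silent_idx = config.conditions.index(config.silent_condition)
    tuning[:, silent_idx] = 0.0

    spoken = config.spoken_conditions
    phases = {c: 2.0 * np.pi * i / len(spoken) for i, c in enumerate(spoken)}
    truth = GroundTruth(
        cis_loading=cis_loading, rot_plane=rot_plane,
        prompt_loading=prompt_loading, tuning_loadings=tuning,
        baseline=baseline, rot_freq=config.rot_freq, rot_phase=phases,
        rot_amplitude=1.0, rot_onset_before_AO=config.rot_lead,
        conditions=config.conditions, silent_condition=config.silent_condition,
        cis_timecourse=_cis_timecourse,
    )

    counts = config.trial_counts()
    order: list[str] = []
    for c in config.conditions:
        order.extend([c] * counts[c])
    order = [order[i] for i in rng.permutation(len(order))]

    t_grid = np.arange(0.0, config.trial_length + _INTERNAL_DT / 2, _INTERNAL_DT)
    hlfp_t = np.arange(0.0, config.trial_length, config.hlfp_dt) + config.hlfp_dt / 2

    n_total = len(order)
    block_size = int(np.ceil(n_total / config.n_blocks))
    trials: list[Trial] = []
    clipped_mass = 0.0
    total_mass = 0.0
    for i, cond in enumerate(order):
        go = config.prompt_time + config.prompt_to_go
        if cond == config.silent_condition:
            ao = None
        else:
            ao = go + max(0.1, rng.normal(config.go_to_AO_mean, config.go_to_AO_sd))
            ao = min(ao, config.trial_length - 0.05)
        lam_raw = _raw_lambda(config, truth, cond, go, ao, t_grid)
        clipped_mass += float(np.sum(np.clip(-lam_raw, 0.0, None)))
        total_mass += float(np.sum(np.abs(lam_raw)))
        lam = np.clip(lam_raw, 0.0, None)
        spikes = _thin_poisson(lam, t_grid, rng)
        hlfp = _hlfp_from_rate(lam, t_grid, hlfp_t, config.hlfp_noise_sd, rng)
        trials.append(Trial(
            condition=cond, spike_times=spikes,
            hlfp_power=hlfp, hlfp_times=hlfp_t.copy(),
            events={"prompt": go - config.prompt_to_go, "go": go, "AO": ao},
            block=i // block_size,
        ))

    if total_mass > 0 and clipped_mass / total_mass > 0.20:
        warnings.warn(
            f"rate rectification clipped {100 * clipped_mass / total_mass:.1f}% "
            "of intensity mass; planted latents are distorted", RuntimeWarning)

    dataset = Dataset(
        trials=trials, electrode_ids=list(range(n_e)),
        conditions=config.conditions, silent_condition=config.silent_condition,
        trial_length=config.trial_length,
        meta={"seed": config.seed if seed is None else seed,
              "clip_fraction": clipped_mass / total_mass if total_mass else 0.0},
    )
    return dataset, truth


def _raw_lambda(config: SimConfig, truth: GroundTruth, cond: str,
                go: float, ao: float | None, t: np.ndarray) -> np.ndarray:
    lam = np.repeat(truth.baseline[:, None], t.size, axis=1)
    if cond == truth.silent_condition:
        return lam
    prompt = go - config.prompt_to_go
    lam += config.prompt_gain * truth.prompt_loading[:, None] * \
        _prompt_timecourse(t - prompt)[None, :]
    lam += config.cis_gain * truth.cis_loading[:, None] * \
        _cis_timecourse(t - go)[None, :]
    if ao is not None:
        z = _rotation_latent(t - (ao - truth.rot_onset_before_AO),
                             truth.rot_freq, truth.rot_phase[cond],
                             truth.rot_amplitude)
        lam += config.rot_gain * (truth.rot_plane @ z)
        k = truth.conditions.index(cond)
        lam += config.tuning_gain * truth.tuning_loadings[:, k:k + 1] * \
            _tuning_gate(t - ao)[None, :]
    return lam


def _thin_poisson(lam: np.ndarray, t_grid: np.ndarray,
                  rng: np.random.Generator) -> list[np.ndarray]:
    """Exact inhomogeneous Poisson sampling by thinning against each
    electrode's maximum rate (intensity linearly interpolated on the grid)."""
    n_e, _ = lam.shape
    duration = t_grid[-1]
    lam_max = lam.max(axis=1)
    counts = rng.poisson(lam_max * duration)
    total = int(counts.sum())
    times = rng.uniform(0.0, duration, size=total)
    accept_u = rng.uniform(size=total)
    e_idx = np.repeat(np.arange(n_e), counts)
    # linear interpolation of lambda at candidate times, vectorized over electrodes
    pos = times / _INTERNAL_DT
    i0 = np.minimum(pos.astype(np.intp), lam.shape[1] - 2)
    frac = pos - i0
    lam_at = lam[e_idx, i0] * (1 - frac) + lam[e_idx, i0 + 1] * frac
    with np.errstate(divide="ignore", invalid="ignore"):
        keep = accept_u * lam_max[e_idx] < lam_at
    spikes: list[np.ndarray] = []
    for e in range(n_e):
        sel = (e_idx == e) & keep
        spikes.append(np.sort(times[sel]))
    return spikes


def _hlfp_from_rate(lam: np.ndarray, t_grid: np.ndarray, hlfp_t: np.ndarray,
                    noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    sm = gaussian_filter1d(lam, sigma=0.020 / _INTERNAL_DT, axis=1, mode="nearest")
    idx = np.clip((hlfp_t / _INTERNAL_DT).astype(np.intp), 0, t_grid.size - 1)
    power = sm[:, idx] + noise_sd * rng.standard_normal((lam.shape[0], hlfp_t.size))
    return np.clip(power, 0.0, None).astype(np.float32)


# ----------------------------------------------------- auxiliary generators

def simulate_phoneme_instances(n_groups: int, instances_per_phoneme: int,
                               within_sd: float, between_sd: float,
                               n_electrodes: int, seed: int,
                               phonemes_per_group: int = 4,
                               group_sd: float | None = None,
                               base_rate: float = 10.0,
                               ) -> tuple[np.ndarray, np.ndarray, dict[str, str]]:
    """Instance-by-electrode rates with hierarchical phoneme/group geometry.

    Group centroids are spread with s.d. ``group_sd`` (default ``3*between_sd``),
    phoneme centroids around their group centroid with s.d. ``between_sd``, and
    individual instances around their phoneme centroid with s.d. ``within_sd``.
    Returns ``(X, phoneme_labels, phoneme_to_group)``.
    """
    if within_sd < 0 or between_sd < 0:
        raise ValueError("standard deviations must be nonnegative")
    if instances_per_phoneme < 4:
        raise ValueError("need at least 4 instances per phoneme "
                         "(cross-validated distance needs >= 2 per split)")
    rng = np.random.default_rng(seed)
    if group_sd is None:
        group_sd = 3.0 * between_sd
    rows, labels = [], []
    phoneme_to_group: dict[str, str] = {}
    for g in range(n_groups):
        g_centroid = base_rate + group_sd * rng.standard_normal(n_electrodes)
        for p in range(phonemes_per_group):
            name = f"g{g}p{p}"
            phoneme_to_group[name] = f"group{g}"
            centroid = g_centroid + between_sd * rng.standard_normal(n_electrodes)
            rows.append(centroid[None, :] +
                        within_sd * rng.standard_normal((instances_per_phoneme,
                                                         n_electrodes)))
            labels.extend([name] * instances_per_phoneme)
    return np.vstack(rows), np.asarray(labels), phoneme_to_group


def simulate_condition_pair(n_units: int, n_trials: int,
                            mean_offset: np.ndarray | float,
                            rate_sd: float, seed: int,
                            base_rate: float = 10.0,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Two trial-by-unit rate matrices whose means differ by ``mean_offset``."""
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    rng = np.random.default_rng(seed)
    offset = np.broadcast_to(np.asarray(mean_offset, dtype=float), (n_units,))
    a = base_rate + rate_sd * rng.standard_normal((n_trials, n_units))
    b = base_rate + offset + rate_sd * rng.standard_normal((n_trials, n_units))
    return a, b


def make_ci_cd_tensor(n_units: int, n_conditions: int, n_time: int,
                      ci_fraction: float, noise_fraction: float = 0.05,
                      seed: int = 0) -> np.ndarray:
    """Units x conditions x time tensor with a planted condition-invariant
    variance fraction.

    The condition-invariant part is a rank-1 ramp shared by all conditions and
    carries ``ci_fraction`` of the planted sum of squares; the
    condition-dependent part (zero mean across conditions at every time) makes
    up the rest; isotropic noise with ``noise_fraction`` of the total sum of
    squares is added on top.
    """
    if not 0.0 <= ci_fraction <= 1.0:
        raise ValueError("ci_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(n_units)
    u /= np.linalg.norm(u)
    ramp = expit(np.linspace(-4, 4, n_time))
    ramp = ramp - ramp.mean()
    ci = u[:, None, None] * np.ones(n_conditions)[None, :, None] * ramp[None, None, :]
    cd = rng.standard_normal((n_units, n_conditions, n_time))
    cd -= cd.mean(axis=1, keepdims=True)          # zero condition mean
    cd = gaussian_filter1d(cd, sigma=max(n_time / 12, 1), axis=2, mode="nearest")
    cd -= cd.mean(axis=1, keepdims=True)
    ci *= np.sqrt(ci_fraction) / np.linalg.norm(ci)
    if np.linalg.norm(cd) > 0:
        cd *= np.sqrt(1.0 - ci_fraction) / np.linalg.norm(cd)
    x = ci + cd
    noise = rng.standard_normal(x.shape)
    noise *= np.sqrt(noise_fraction) * np.linalg.norm(x) / np.linalg.norm(noise)
    return x + noise


def make_rotation_tensor(n_units: int, n_conditions: int, n_time: int,
                         freq_hz: float, dt: float, snr: float = 20.0,
                         amplitude: float = 1.0, seed: int = 0,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Units x conditions x time tensor carrying a pure planted rotation.

    Conditions start at phases uniformly spaced around the circle, all
    rotating at ``freq_hz`` in a common 2-D orthonormal electrode-space plane.
    The additive noise is Gaussian smoothed along time with a 30 ms kernel
    (mimicking kernel-smoothed firing rates, whose noise is temporally
    correlated) and scaled so signal power / noise power equals ``snr``.
    Returns ``(tensor, plane)``.
    """
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((n_units, 2)))
    t = np.arange(n_time) * dt
    x = np.empty((n_units, n_conditions, n_time))
    for c in range(n_conditions):
        phase = 2.0 * np.pi * c / n_conditions
        z = amplitude * np.stack([np.cos(2 * np.pi * freq_hz * t + phase),
                                  np.sin(2 * np.pi * freq_hz * t + phase)])
        x[:, c, :] = q @ z
    noise = gaussian_filter1d(rng.standard_normal(x.shape),
                              sigma=0.030 / dt, axis=2, mode="nearest")
    noise *= np.linalg.norm(x) / (np.linalg.norm(noise) * np.sqrt(snr))
    return x + noise, q
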