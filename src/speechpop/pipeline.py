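"""End-to-end analysis of one (synthetic or loaded) prompted-speaking session.

Chains the full tool set in the order the analyses build on one another:
faux-AO assignment, population modulation time courses and epoch statistics,
per-electrode rank tests, single-trial decoding, demixed PCA
(condition-invariant signal), jPCA (rotatory dynamics), and
tensor-maximum-entropy significance of the rotatory fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import modulation as mod
from .decoding import build_features, loo_classify, shuffle_chance
from .dpca import DPCAConfig, fit_dpca, subspace_angle
from .jpca import JPCAResult, fit_skew_dynamics, prepare_states
from .preprocess import (assign_faux_AO, center_across_conditions,
                         epoch_mean_rates, single_trial_rates, soft_normalize,
                         trial_average)
from .surrogates import SignificanceResult, rotation_significance
from .synthetic import Dataset, SimConfig, simulate_speech_task

__all__ = ["PipelineResult", "run_pipeline"]

PROMPT_EPOCH = (0.0, 1.0)        # relative to the audio prompt
SPEAK_EPOCH = (0.0, 1.75)        # relative to the go cue
DPCA_EPOCH = (-0.2, 0.4)         # relative to the go cue
JPCA_EPOCH = (-0.15, 0.10)       # relative to acoustic onset


@dataclass
class PipelineResult:
    modulation: dict
    electrode_counts: np.ndarray
    decoding: object
    dpca: object
    jpca: JPCAResult
    cis_jpc_angle_deg: float
    significance: SignificanceResult | None
    meta: dict = field(default_factory=dict)


def run_pipeline(dataset: Dataset | None = None,
                 config: SimConfig | None = None, seed: int = 0,
                 n_surrogates: int = 200, n_shuffles: int = 0,
                 run_decoding: bool = True) -> PipelineResult:
    """Run every analysis stage on a dataset (simulated if not given)."""
    if dataset is None:
        dataset, _ = simulate_speech_task(config or SimConfig(), seed)
    dataset = assign_faux_AO(dataset)
    silent = dataset.silent_condition
    spoken = list(dataset.spoken_conditions)

    # --- population modulation: distance to silent, per epoch -------------
    prompt_rates, prompt_labels, prompt_t = single_trial_rates(
        dataset, spoken + [silent], "prompt", (-1.0, 1.0),
        kernel_sd=0.025, bin=0.02)
    go_rates, go_labels, go_t = single_trial_rates(
        dataset, spoken + [silent], "go", (-0.5, 1.75),
        kernel_sd=0.025, bin=0.02)
    prompt_means, speak_means, timecourses = {}, {}, {}
    ref_p = prompt_rates[prompt_labels == silent]
    ref_g = go_rates[go_labels == silent]
    for cond in spoken:
        d_p = np.sign(Dp := mod.cv_squared_distance_timecourse(
            prompt_rates[prompt_labels == cond], ref_p)) * np.sqrt(np.abs(Dp))
        d_g = np.sign(Dg := mod.cv_squared_distance_timecourse(
            go_rates[go_labels == cond], ref_g)) * np.sqrt(np.abs(Dg))
        timecourses[cond] = {"prompt": (prompt_t, d_p), "go": (go_t, d_g)}
        prompt_means[cond] = mod.epoch_mean(prompt_t, d_p, PROMPT_EPOCH)
        speak_means[cond] = mod.epoch_mean(go_t, d_g, SPEAK_EPOCH)
    _, _, wilcoxon_p = mod.epoch_comparison(prompt_means, speak_means)
    ratio = mod.modulation_ratio(list(prompt_means.values()),
                                 list(speak_means.values()))
    modulation = {"prompt_means": prompt_means, "speak_means": speak_means,
                  "wilcoxon_p": wilcoxon_p, "ratio": ratio,
                  "timecourses": timecourses}

    # --- per-electrode task modulation ------------------------------------
    epoch = epoch_mean_rates(dataset, "AO", (-0.5, 0.5))
    sig, _, _ = mod.electrode_significance(epoch, silent)
    electrode_counts = sig.sum(axis=1)

    # --- single-trial decoding --------------------------------------------
    decoding = None
    if run_decoding:
        features = build_features(dataset)
        decoding = loo_classify(features)
        if n_shuffles > 0:
            decoding.chance = shuffle_chance(features, n_shuffles, seed=seed)
            decoding.n_shuffles = n_shuffles

    # --- condition-invariant signal (dPCA) --------------------------------
    dcfg = DPCAConfig()
    tensor = trial_average(dataset, "go", DPCA_EPOCH, kernel_sd=dcfg.kernel_sd,
                           bin=0.001, conditions=spoken)
    tensor = soft_normalize(tensor, dcfg.soft_offset)
    dpca_res = fit_dpca(tensor, dcfg)
    cis_axis = dpca_res.encoder[:, dpca_res.leading_ci_component()]

    # --- rotatory dynamics (jPCA) -----------------------------------------
    jtensor = trial_average(dataset, "AO", JPCA_EPOCH, kernel_sd=0.030,
                            bin=0.010, conditions=spoken)
    jtensor = soft_normalize(jtensor, 10.0)
    jres = fit_skew_dynamics(prepare_states(
        center_across_conditions(jtensor), k=6, dt=0.010))
    angle = subspace_angle(cis_axis, jres.plane_in_unit_space(0))

    # --- surrogate significance -------------------------------------------
    significance = None
    if n_surrogates > 0:
        significance = rotation_significance(jtensor, n_surrogates, seed=seed)

    return PipelineResult(
        modulation=modulation, electrode_counts=electrode_counts,
        decoding=decoding, dpca=dpca_res, jpca=jres,
        cis_jpc_angle_deg=angle, significance=significance,
        meta={"seed": seed, "n_trials": len(dataset.trials),
              "n_electrodes": dataset.n_electrodes})
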