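import numpy as np
import pytest

import speechpop as sp


def test_identical_config_and_seed_give_bit_identical_datasets():
    cfg = sp.SimConfig(n_electrodes=8, conditions=("a", "silent"),
                       trials_per_condition=3)
    ds1, gt1 = sp.simulate_speech_task(cfg, seed=5)
    ds2, gt2 = sp.simulate_speech_task(cfg, seed=5)
    assert np.array_equal(gt1.cis_loading, gt2.cis_loading)
    for t1, t2 in zip(ds1.trials, ds2.trials):
        assert t1.condition == t2.condition
        assert t1.events == t2.events
        for s1, s2 in zip(t1.spike_times, t2.spike_times):
            assert np.array_equal(s1, s2)
        assert np.array_equal(t1.hlfp_power, t2.hlfp_power)


def test_all_latents_off_yields_homogeneous_poisson_at_baseline():
    """With every gain zero, each electrode is homogeneous Poisson: pooled
    spike counts land within 3 SE of baseline * duration (rare excursions
    tolerated at the binomial rate of a 3-sigma test)."""
    cfg = sp.SimConfig(n_electrodes=30, conditions=("a", "silent"),
                       trials_per_condition=15, prompt_gain=0, cis_gain=0,
                       rot_gain=0, tuning_gain=0)
    ds, gt = sp.simulate_speech_task(cfg, seed=2)
    n_trials = len(ds.trials)
    dur = cfg.trial_length
    counts = np.zeros(cfg.n_electrodes)
    for tr in ds.trials:
        counts += [len(s) for s in tr.spike_times]
    expected = gt.baseline * dur * n_trials
    z = np.abs(counts - expected) / np.sqrt(expected)
    assert np.sum(z > 3) <= 2


def test_default_trial_count_is_thirty_per_condition():
    assert sp.SimConfig().trials_per_condition == 30
    cfg = sp.SimConfig(n_electrodes=4, conditions=("a", "silent"))
    ds, _ = sp.simulate_speech_task(cfg, seed=0)
    assert len(ds.trials_of("a")) == 30
    assert len(ds.trials_of("silent")) == 30


def test_planted_loadings_are_orthonormal():
    _, _, truth = _tiny_truth()
    assert abs(truth.cis_loading @ truth.rot_plane).max() < 1e-10
    assert np.abs(truth.rot_plane.T @ truth.rot_plane - np.eye(2)).max() < 1e-10
    assert abs(np.linalg.norm(truth.cis_loading) - 1) < 1e-10


def _tiny_truth():
    cfg = sp.SimConfig(n_electrodes=12, conditions=("a", "silent"),
                       trials_per_condition=1)
    ds, truth = sp.simulate_speech_task(cfg, seed=3)
    return cfg, ds, truth


def test_psth_projected_on_rotation_plane_recovers_frequency(two_condition_sim):
    """The AO-aligned PSTH of 200 trials, projected onto the planted plane,
    is a sinusoid whose zero-padded FFT peak sits within 5% of the planted
    rotation frequency."""
    cfg, ds, truth = two_condition_sim
    tensor = sp.trial_average(ds, "AO", (0.0, 1.2), kernel_sd=0.02, bin=0.01,
                              conditions=("ga",))
    proj = np.einsum("u,ut->t", truth.rot_plane[:, 0],
                     tensor.rates[:, 0, :]) + 1j * np.einsum(
        "u,ut->t", truth.rot_plane[:, 1], tensor.rates[:, 0, :])
    proj = proj - proj.mean()
    n_pad = 1 << 15
    spec = np.abs(np.fft.fft(proj, n_pad))
    freqs = np.fft.fftfreq(n_pad, d=0.01)
    pos = freqs > 0.3
    peak = freqs[pos][np.argmax(spec[pos])]
    assert abs(peak - truth.rot_freq) / truth.rot_freq < 0.05


def test_psth_error_shrinks_with_trial_count(two_condition_sim):
    """RMSE of the PSTH against the planted rate profile scales ~1/sqrt(n):
    the 200-trial error over the 50-trial error should sit near 0.5."""
    cfg, ds, truth = two_condition_sim
    trials = ds.trials_of("ga")
    t_eval = None
    rates_all = []
    for tr in trials:
        r, t_eval = sp.bin_and_smooth(tr.spike_times, tr.events["go"],
                                      (-0.5, 1.0), bin=0.02, kernel_sd=0.025,
                                      trial_length=ds.trial_length)
        rates_all.append(r)
    rates_all = np.stack(rates_all)

    def rmse(n):
        psth = rates_all[:n].mean(axis=0)
        lam = np.stack([
            truth.lambda_timecourse(cfg, "ga", tr.events["go"],
                                    tr.events["AO"],
                                    tr.events["go"] + t_eval)
            for tr in trials[:n]]).mean(axis=0)
        return float(np.sqrt(np.mean((psth - lam) ** 2)))

    ratio = rmse(200) / rmse(50)
    assert 0.3 < ratio < 0.8


def test_rate_rectification_warns_when_clipping_is_heavy():
    cfg = sp.SimConfig(n_electrodes=10, conditions=("a", "silent"),
                       trials_per_condition=2, baseline_shape=1.0,
                       baseline_scale=1.0, cis_gain=300.0, rot_gain=200.0)
    with pytest.warns(RuntimeWarning, match="rectification"):
        sp.simulate_speech_task(cfg, seed=0)


@pytest.mark.parametrize("kwargs", [
    dict(prompt_to_go=-1.0),
    dict(conditions=("a", "b")),                      # no silent condition
    dict(conditions=("silent", "x", "silent")),       # two silent conditions
    dict(rot_freq=60.0),
    dict(trials_per_condition=0),
])
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ValueError):
        sp.SimConfig(n_electrodes=4, **kwargs)


def test_phoneme_instances_shapes_and_degenerate_geometry():
    X, labels, groups = sp.simulate_phoneme_instances(
        3, 6, within_sd=1.0, between_sd=0.5, n_electrodes=10, seed=0)
    assert X.shape == (3 * 4 * 6, 10)
    assert len(labels) == X.shape[0]
    assert set(groups.values()) == {"group0", "group1", "group2"}
    # all centroids identical and no within noise -> all distances ~ 0
    X0, labels0, _ = sp.simulate_phoneme_instances(
        2, 8, within_sd=0.0, between_sd=0.0, group_sd=0.0,
        n_electrodes=6, seed=1)
    labs = np.unique(labels0)
    d = sp.cv_distance(A=X0[labels0 == labs[0]], B=X0[labels0 == labs[1]])
    assert abs(d.D) < 1e-18
    with pytest.raises(ValueError):
        sp.simulate_phoneme_instances(2, 3, 1.0, 1.0, 5, 0)


def test_condition_pair_offset_is_planted():
    a, b = sp.simulate_condition_pair(5, 2000, mean_offset=1.5, rate_sd=1.0,
                                      seed=4)
    assert a.shape == b.shape == (2000, 5)
    assert np.abs((b.mean(axis=0) - a.mean(axis=0)) - 1.5).max() < 0.15
    with pytest.raises(ValueError):
        sp.simulate_condition_pair(5, 1, 0.0, 1.0, 0)


def test_silent_trials_have_no_latent_drive_and_no_AO(small_sim):
    cfg, ds, truth = small_sim
    for tr in ds.trials_of("silent"):
        assert tr.events["AO"] is None
        assert tr.events["prompt"] < tr.events["go"]
    assert np.all(truth.tuning_loadings[:, list(truth.conditions).index("silent")] == 0)
    lam = truth.lambda_timecourse(cfg, "silent", 3.0, None,
                                  np.linspace(0, 5, 50))
    assert np.allclose(lam, truth.baseline[:, None])
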