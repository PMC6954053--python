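import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import speechpop as sp
from speechpop.synthetic import Trial


@pytest.mark.parametrize("sd", [0.025, 0.028, 0.030])
def test_single_spike_kernel_identity(sd):
    """An isolated spike smooths to a Gaussian bump with peak
    1/(sqrt(2 pi) sd) Hz whose integral is one spike."""
    rates, t = sp.bin_and_smooth([np.array([1.0])], align_time=1.0,
                                 window=(-0.8, 0.8), bin=0.001, kernel_sd=sd)
    peak = rates[0].max()
    assert abs(peak - 1.0 / (np.sqrt(2 * np.pi) * sd)) / peak < 0.01
    assert abs(np.trapezoid(rates[0], dx=0.001) - 1.0) < 0.01
    assert abs(t[np.argmax(rates[0])]) < 0.002


def test_smoothing_is_linear_in_spike_trains():
    rng = np.random.default_rng(0)
    a = np.sort(rng.uniform(0.1, 1.9, 40))
    b = np.sort(rng.uniform(0.1, 1.9, 25))
    ra, _ = sp.bin_and_smooth([a], 1.0, (-0.9, 0.9), 0.01, 0.025)
    rb, _ = sp.bin_and_smooth([b], 1.0, (-0.9, 0.9), 0.01, 0.025)
    rab, _ = sp.bin_and_smooth([np.sort(np.concatenate([a, b]))], 1.0,
                               (-0.9, 0.9), 0.01, 0.025)
    assert np.allclose(ra + rb, rab, atol=1e-10)


def test_constant_rate_poisson_recovered_within_three_se():
    rng = np.random.default_rng(1)
    rate, dur, n_trials = 20.0, 2.0, 200
    means = []
    for _ in range(n_trials):
        n = rng.poisson(rate * dur)
        spikes = np.sort(rng.uniform(0, dur, n))
        r, _ = sp.bin_and_smooth([spikes], dur / 2, (-0.8, 0.8), 0.02, 0.025)
        means.append(r.mean())
    se = np.sqrt(rate / (1.6 * n_trials))   # Poisson count variance over window
    assert abs(np.mean(means) - rate) < 3 * se


def test_bin_and_smooth_rejects_bad_windows():
    with pytest.raises(ValueError):
        sp.bin_and_smooth([np.array([0.5])], 1.0, (0.5, 0.5), 0.01, 0.02)
    with pytest.raises(ValueError):
        sp.bin_and_smooth([np.array([0.5])], 0.2, (-0.5, 0.5), 0.01, 0.02)
    with pytest.raises(ValueError):   # bin coarser than the kernel
        sp.bin_and_smooth([np.array([0.5])], 1.0, (-0.5, 0.5), 0.05, 0.02)


def test_trial_average_identities(small_sim):
    _, ds, _ = small_sim
    # single-trial condition average equals that trial's smoothed rates
    one = replace(ds, trials=[ds.trials_of("a")[0]])
    tensor = sp.trial_average(one, "go", (-0.2, 0.4), 0.028, 0.01)
    direct, _ = sp.bin_and_smooth(one.trials[0].spike_times,
                                  one.trials[0].events["go"], (-0.2, 0.4),
                                  0.01, 0.028, ds.trial_length)
    assert np.allclose(tensor.rates[:, 0, :], direct)
    # averaging commutes with unit subsetting
    full = sp.trial_average(ds, "go", (-0.2, 0.4), 0.028, 0.01,
                            conditions=("a", "b"))
    sub_ds = replace(ds, trials=[
        replace(tr, spike_times=tr.spike_times[:5],
                hlfp_power=None, hlfp_times=None)
        for tr in ds.trials], electrode_ids=ds.electrode_ids[:5])
    sub = sp.trial_average(sub_ds, "go", (-0.2, 0.4), 0.028, 0.01,
                           conditions=("a", "b"))
    assert np.allclose(full.rates[:5], sub.rates)


def test_soft_normalize_arithmetic_and_inversion():
    rates = np.zeros((2, 2, 4))
    rates[0] = np.array([[0, 5, 10, 15], [2, 2, 2, 2]])   # unit 0 range 15
    rates[1] = 3.0                                         # constant unit
    t = _tensor(rates)
    out = sp.soft_normalize(t, 5.0)
    assert np.allclose(out.rates[0], rates[0] / 20.0)
    back = sp.undo_soft_normalize(out)
    assert np.abs(back.rates - rates).max() < 1e-12
    with pytest.raises(ValueError):
        sp.soft_normalize(out, 5.0)          # double normalization
    with pytest.warns(RuntimeWarning):
        z = sp.soft_normalize(t, 0.0)        # zero-range unit, zero offset
    assert np.all(z.rates[1] == 0)


def test_centering_and_its_inverse():
    rng = np.random.default_rng(2)
    rates = rng.uniform(0, 10, (3, 4, 6))
    t = _tensor(rates)
    c = sp.center_across_conditions(t)
    assert np.abs(c.rates.mean(axis=1)).max() < 1e-10
    assert np.abs(sp.uncenter(c).rates - rates).max() < 1e-12
    same = _tensor(np.repeat(rates[:, :1], 4, axis=1))
    assert np.abs(sp.center_across_conditions(same).rates).max() < 1e-12


def _tensor(rates):
    return sp.RateTensor(rates=rates, time=np.arange(rates.shape[2]) * 0.01,
                         conditions=tuple(f"c{i}" for i in range(rates.shape[1])),
                         alignment="go", bin=0.01, kernel_sd=0.02)


def _event_trial(cond, block, go, ao):
    return Trial(condition=cond, spike_times=[np.empty(0)], hlfp_power=None,
                 hlfp_times=None, events={"prompt": go - 2, "go": go, "AO": ao},
                 block=block)


def test_faux_AO_uses_per_block_mean_latency():
    trials = [
        _event_trial("a", 0, 3.0, 3.4), _event_trial("b", 0, 3.0, 3.6),
        _event_trial("a", 1, 3.0, 3.8), _event_trial("b", 1, 3.0, 3.9),
        _event_trial("silent", 0, 3.0, None),
        _event_trial("silent", 1, 3.0, None),
    ]
    ds = sp.Dataset(trials=trials, electrode_ids=[0],
                    conditions=("a", "b", "silent"), silent_condition="silent",
                    trial_length=5.0)
    out = sp.assign_faux_AO(ds)
    faux = {tr.block: tr.events["AO"] for tr in out.trials_of("silent")}
    # oracle: independent pandas group-by of the spoken latencies
    df = pd.DataFrame([(tr.block, tr.events["AO"] - tr.events["go"])
                       for tr in trials if tr.condition != "silent"],
                      columns=["block", "lat"])
    expect = df.groupby("block")["lat"].mean()
    assert faux[0] == pytest.approx(3.0 + expect[0])   # = go + 0.5
    assert faux[1] == pytest.approx(3.0 + expect[1])
    # spoken trials untouched; dataset without silent trials is a no-op
    assert [t.events["AO"] for t in out.trials[:4]] == [3.4, 3.6, 3.8, 3.9]
    spoken_only = sp.Dataset(trials=trials[:4], electrode_ids=[0],
                             conditions=("a", "b", "silent"),
                             silent_condition="silent", trial_length=5.0)
    assert sp.assign_faux_AO(spoken_only).trials == spoken_only.trials


def test_faux_AO_block_without_spoken_trials_falls_back():
    trials = [_event_trial("a", 0, 3.0, 3.4),
              _event_trial("silent", 5, 3.0, None)]
    ds = sp.Dataset(trials=trials, electrode_ids=[0],
                    conditions=("a", "silent"), silent_condition="silent",
                    trial_length=5.0)
    with pytest.warns(RuntimeWarning, match="dataset-wide"):
        out = sp.assign_faux_AO(ds)
    assert out.trials_of("silent")[0].events["AO"] == pytest.approx(3.4)


def test_epoch_mean_rates_counts_spikes():
    tr = Trial(condition="a",
               spike_times=[np.array([2.1, 2.2, 2.5, 2.9, 3.05]), np.empty(0)],
               hlfp_power=None, hlfp_times=None,
               events={"prompt": 0.5, "go": 2.5, "AO": 3.1}, block=0)
    ds = sp.Dataset(trials=[tr], electrode_ids=[0, 1],
                    conditions=("a", "silent"), silent_condition="silent",
                    trial_length=5.0)
    er = sp.epoch_mean_rates(ds, "go", (-0.5, 0.5))
    assert er.rates[0, 0] == pytest.approx(4.0)    # 4 spikes in [2.0, 3.0)
    assert er.rates[0, 1] == 0.0
    with pytest.raises(ValueError):
        sp.epoch_mean_rates(ds, "go", (-3.0, 0.5))
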