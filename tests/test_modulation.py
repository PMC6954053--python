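import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import speechpop as sp
from oracles import naive_cv_squared_distance


def test_worked_example_matches_double_sum_oracle():
    """One unit, A = {1, 3}, B = {0, 0}: the literal double sum gives
    D = mean of {1*3, 1*3, 3*1, 3*1} = 3, so d = sqrt(3)."""
    A = np.array([[1.0], [3.0]])
    B = np.array([[0.0], [0.0]])
    oracle = naive_cv_squared_distance(A, B)
    res = sp.cv_distance(A=A, B=B)
    assert oracle == pytest.approx(3.0, abs=1e-12)
    assert res.D == pytest.approx(oracle, abs=1e-10)
    assert res.d == pytest.approx(np.sqrt(3.0), abs=1e-10)


def test_identical_trials_give_zero_distance():
    A = np.tile([2.0, 5.0, 1.0], (6, 1))
    res = sp.cv_distance(A=A, B=A.copy())
    assert res.D == 0.0 and res.d == 0.0


def test_closed_form_equals_double_sum_and_is_symmetric():
    rng = np.random.default_rng(3)
    for _ in range(30):
        n1, n2, u = rng.integers(2, 9, 3)
        A = rng.normal(10, 3, (n1, u))
        B = rng.normal(10, 3, (n2, u))
        d_ab = sp.cv_distance(A=A, B=B)
        assert d_ab.D == pytest.approx(naive_cv_squared_distance(A, B),
                                       abs=1e-10)
        assert d_ab.D == pytest.approx(sp.cv_distance(A=B, B=A).D, abs=1e-12)
        assert d_ab.d ** 2 == pytest.approx(abs(d_ab.D), abs=1e-12)


def test_null_draws_produce_negative_values_and_unbiased_mean():
    """Identical distributions: D is unbiased around zero and must go
    negative on a substantial fraction of draws."""
    rng = np.random.default_rng(4)
    ds = np.array([sp.cv_distance(A=rng.normal(0, 1, (8, 10)),
                                  B=rng.normal(0, 1, (8, 10))).D
                   for _ in range(300)])
    assert np.mean(ds < 0) > 0.2
    assert abs(ds.mean()) < 2 * ds.std() / np.sqrt(ds.size)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), shift=st.floats(-20, 20),
       scale=st.floats(0.1, 5))
def test_distance_translation_invariance_and_quadratic_scaling(seed, shift,
                                                               scale):
    """Adding a common offset to every trial of both conditions leaves D
    unchanged; scaling all rates by a scales D by a^2 (d by |a|)."""
    rng = np.random.default_rng(seed)
    a = rng.normal(5, 2, (rng.integers(2, 7), 4))
    b = rng.normal(5, 2, (rng.integers(2, 7), 4))
    base = sp.cv_distance(A=a, B=b).D
    shifted = sp.cv_distance(A=a + shift, B=b + shift).D
    scaled = sp.cv_distance(A=scale * a, B=scale * b).D
    assert shifted == pytest.approx(base, abs=1e-8 * max(1, abs(base)))
    assert scaled == pytest.approx(scale ** 2 * base,
                                   rel=1e-9, abs=1e-12)


def test_cv_distance_rejects_single_trial():
    with pytest.raises(ValueError):
        sp.cv_distance(A=np.ones((1, 3)), B=np.ones((5, 3)))


def test_self_distance_timecourse_is_centered_on_zero(small_sim):
    """Splitting one condition in half, the distance time course should
    scatter around zero (sign test over time points)."""
    _, ds, _ = small_sim
    rates, labels, t = sp.single_trial_rates(ds, ["a"], "go", (-0.5, 1.0),
                                             0.025, 0.02)
    D = sp.cv_squared_distance_timecourse(rates[:4], rates[4:])
    from scipy.stats import binomtest
    n_pos = int(np.sum(D > 0))
    assert binomtest(n_pos, D.size, 0.5).pvalue > 0.01


def test_planted_modulation_profile_recovered():
    """With only the condition-invariant latent on, the spoken-vs-silent
    distance is ~0 before the go cue and rises to ~cis_gain after it."""
    cfg = sp.SimConfig(n_electrodes=25, conditions=("a", "silent"),
                       trials_per_condition=40, prompt_gain=0.0,
                       cis_gain=25.0, rot_gain=0.0, tuning_gain=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ds, _ = sp.simulate_speech_task(cfg, seed=9)
    t, d = sp.distance_timecourse(ds, "a", "silent", "go", (-0.8, 1.2))
    pre = np.abs(d[t < -0.1]).mean()
    post = d[t > 0.6].mean()
    assert post > 0.7 * cfg.cis_gain
    assert pre < 0.3 * post


def test_epoch_comparison_exact_signed_rank_p():
    prompt = np.arange(10, dtype=float)
    speak = prompt + 1.0
    _, _, p_greater = sp.epoch_comparison(prompt, speak,
                                          alternative="greater")
    assert p_greater == pytest.approx(1 / 1024)
    _, _, p_two = sp.epoch_comparison(prompt, speak)
    assert p_two == pytest.approx(2 / 1024)
    _, _, p_same = sp.epoch_comparison(prompt, prompt.copy())
    assert p_same == 1.0
    with pytest.raises(ValueError):
        sp.epoch_comparison(prompt[:4], speak[:4])
    with pytest.raises(ValueError):
        sp.epoch_comparison({"a": 1.0}, {"b": 1.0})


def test_modulation_ratio_identity_and_guard():
    assert sp.modulation_ratio([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    with pytest.warns(RuntimeWarning):
        assert np.isnan(sp.modulation_ratio([-1.0, 0.5], [2.0, 2.0]))


def test_modulation_ratio_recovers_planted_amplitude_ratio():
    """Prompt and speaking latents planted at 1:4 population amplitude; the
    measured epoch-mean ratio must match the ratio of the planted distance
    profiles (computed analytically from the ground truth) within 10%."""
    cfg = sp.SimConfig(n_electrodes=25, conditions=("a", "silent"),
                       trials_per_condition=120, prompt_gain=8.0,
                       cis_gain=32.0, rot_gain=0.0, tuning_gain=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ds, truth = sp.simulate_speech_task(cfg, seed=12)
    tp, dp = sp.distance_timecourse(ds, "a", "silent", "prompt", (-0.2, 1.2))
    tg, dg = sp.distance_timecourse(ds, "a", "silent", "go", (-0.2, 1.75))
    prompt_mean = sp.epoch_mean(tp, dp, (0.0, 1.0))
    speak_mean = sp.epoch_mean(tg, dg, (0.0, 1.75))
    measured = sp.modulation_ratio([prompt_mean], [speak_mean])

    # analytic oracle: planted ||delta lambda(t)|| averaged over each epoch
    go = cfg.prompt_time + cfg.prompt_to_go
    tr = ds.trials_of("a")[0]
    t_prompt = cfg.prompt_time + np.linspace(0, 1.0, 400)
    t_speak = go + np.linspace(0, 1.75, 400)
    lam_base = truth.baseline[:, None]
    def planted_norm(ts):
        lam = np.stack([
            truth.lambda_timecourse(cfg, "a", t.events["go"], t.events["AO"], ts)
            for t in ds.trials_of("a")]).mean(axis=0)
        return np.linalg.norm(lam - lam_base, axis=0).mean()
    expected = planted_norm(t_speak) / planted_norm(t_prompt)
    assert measured == pytest.approx(expected, rel=0.10)


def test_electrode_significance_recovers_planted_tuning():
    rng = np.random.default_rng(5)
    conds = [f"c{i}" for i in range(10)] + ["base"]
    n_per, n_u = 60, 8
    tuned = {0: [1, 4, 7]}          # electrode 0 responds to exactly these
    rows, labels = [], []
    for ci, cond in enumerate(conds):
        x = rng.normal(10, 1, (n_per, n_u))
        if cond != "base" and ci in tuned[0] if True else False:
            pass
        if cond != "base" and ci in [1, 4, 7]:
            x[:, 0] += 5.0
        rows.append(x)
        labels += [cond] * n_per
    er = sp.EpochRates(rates=np.vstack(rows), labels=np.asarray(labels),
                       window=(-0.5, 0.5), alignment="AO")
    sig, pvals, order = sp.electrode_significance(er, "base")
    flagged = {order[j] for j in np.where(sig[0])[0]}
    assert flagged == {"c1", "c4", "c7"}
    assert sig[1:].sum() <= 1       # untuned electrodes essentially silent


def test_within_condition_distance_null_and_identity():
    """Identical rows give exactly zero.  For i.i.d. rows the half-split
    squared distance D is unbiased around zero; the signed root d inherits a
    small negative offset (sign(D)*sqrt|D| of a right-skewed null is not
    mean-zero), so d is only required to be small against its own spread."""
    A = np.tile([3.0, 1.0], (10, 1))
    assert sp.within_condition_distance(A) == 0.0
    rng = np.random.default_rng(6)
    d_vals, D_vals = [], []
    for k in range(150):
        x = rng.normal(0, 1, (9, 6))
        d_vals.append(sp.within_condition_distance(x, 20, seed=k))
        perm = np.random.default_rng(k).permutation(9)
        D_vals.append(sp.cv_distance(A=x[perm[:4]], B=x[perm[4:]]).D)
    D_vals = np.asarray(D_vals)
    d_vals = np.asarray(d_vals)
    assert abs(D_vals.mean()) < 2 * D_vals.std() / np.sqrt(D_vals.size)
    assert abs(d_vals.mean()) < 0.5 * d_vals.std()
    with pytest.raises(ValueError):
        sp.within_condition_distance(A[:3])
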