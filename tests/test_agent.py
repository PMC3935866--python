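"""Unit and property tests for the TD(λ) engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from td_arousal import (AgentState, ConfigurationError, DrugCondition,
                        ModelParams, NO_DRUG, apply_break_trial,
                        arousal_update, drug_transform, features, init_agent,
                        run_trial, td_step)


# ---------------------------------------------------------------------------
# independent brute-force oracle: plain-Python, loop-unrolled recurrences
# ---------------------------------------------------------------------------

def brute_force_trials(schedule, alpha=0.08, beta=0.04, lam=0.9, gamma=1.0,
                       arousal=1.0, T=10, cs=3, rt=8, reward=1.0):
    """Straight-line recomputation of the engine recurrences.

    Kept deliberately free of the package's internals: explicit lists, the
    δ(t) = r + γV(t) − V(t−1) recursion, weight update with the trace
    accumulated through t−1, trace update e ← γλe + x(t), sign clamps on
    both weight populations (both driven by every δ).
    """
    K = T - cs + 1
    wp = [0.0] * K
    wm = [0.0] * K

    def phi(t):
        x = [0.0] * K
        if cs <= t <= T:
            x[t - cs] = 1.0
        return x

    def val(x):
        return sum((wp[i] + wm[i]) * x[i] for i in range(K))

    history = []
    for rewarded in schedule:
        e = [0.0] * K
        deltas, values = [0.0] * (T + 1), [0.0] * (T + 1)
        for t in range(1, T + 1):
            x = phi(t)
            x_prev = phi(t - 1) if t > 1 else [0.0] * K
            v_t = val(x)
            v_prev = val(x_prev)
            r = reward if (rewarded and t == rt) else 0.0
            d = r + gamma * v_t - v_prev
            for i in range(K):
                wp[i] = max(wp[i] + alpha * arousal * d * e[i], 0.0)
            for i in range(K):
                wm[i] = min(wm[i] + beta * arousal * d * e[i], 0.0)
            for i in range(K):
                e[i] = gamma * lam * e[i] + x[i]
            deltas[t], values[t] = d, v_t
        history.append((deltas, values, list(wp), list(wm)))
    return history


def test_engine_matches_brute_force_oracle(params):
    """Per-step δ/V and per-trial weights on a 3-trial hand-traceable
    schedule agree with the independent recomputation to 1e-12."""
    schedule = [True, True, False]
    expected = brute_force_trials(schedule)
    state = init_agent(params)
    for rewarded, (deltas, values, wp, wm) in zip(schedule, expected):
        rec = run_trial(state, rewarded, "acquisition", NO_DRUG, params)
        np.testing.assert_allclose(rec.delta_trace, deltas, atol=1e-12)
        np.testing.assert_allclose(rec.value_trace, values, atol=1e-12)
        np.testing.assert_allclose(state.w_plus, wp, atol=1e-12)
        np.testing.assert_allclose(state.w_minus, wm, atol=1e-12)


# ---------------------------------------------------------------------------
# initialization and stimulus representation
# ---------------------------------------------------------------------------

def test_fresh_agent_is_value_free(params):
    agent = init_agent(params)
    assert agent.arousal == 1.0
    assert agent.trial_index == 0
    assert len(agent.w_plus) == len(agent.w_minus) \
        == len(agent.eligibility) == 8
    rec = run_trial(agent, False, "extinction", NO_DRUG, params)
    assert np.all(rec.delta_trace == 0)
    assert np.all(rec.value_trace == 0)


@pytest.mark.parametrize("t, hot", [(3, 0), (8, 5), (10, 7)])
def test_features_one_hot_from_cs_onset(params, t, hot):
    x = features(t, params)
    assert x[hot] == 1.0 and x.sum() == 1.0


def test_features_zero_before_cs_and_bounded(params):
    assert features(2, params).sum() == 0.0
    with pytest.raises(ValueError):
        features(0, params)
    with pytest.raises(ValueError):
        features(11, params)


def test_first_rewarded_trial_delta_profile(params):
    """With zero weights, δ is the raw reward at reward_time and zero at
    the CS."""
    agent = init_agent(params)
    rec = run_trial(agent, True, "acquisition", NO_DRUG, params)
    assert rec.delta_trace[params.reward_time] == params.reward_magnitude
    assert rec.delta_at_cs == 0.0
    assert rec.delta_at_cs == rec.delta_trace[params.cs_time]


# ---------------------------------------------------------------------------
# drug transform
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("delta, direction, dose, expected", [
    (0.5, "none", 0.0, 0.5),
    (0.5, "reduce", 0.1, 0.45),
    (-0.5, "reduce", 0.1, -0.55),
    (0.5, "enhance", 0.1, 0.55),
    (-0.5, "enhance", 0.1, -0.45),
    (0.0, "reduce", 0.5, 0.0),
    (0.5, "enhance", 0.0, 0.5),
])
def test_drug_transform_scales_error_magnitude(delta, direction, dose,
                                               expected):
    cond = DrugCondition(direction, dose)
    assert drug_transform(delta, cond) == pytest.approx(expected, abs=1e-15)


@given(delta=st.floats(0.0, 10.0), dose=st.floats(0.0, 0.99))
@settings(derandomize=True, max_examples=50)
def test_reduce_never_flips_positive_error(delta, dose):
    assert drug_transform(delta, DrugCondition("reduce", dose)) >= 0.0


def test_drug_condition_validation():
    with pytest.raises(ConfigurationError):
        DrugCondition("reduce", -0.1)
    with pytest.raises(ConfigurationError):
        DrugCondition("reduce", 1.0)
    with pytest.raises(ConfigurationError):
        DrugCondition("stimulate", 0.1)


# ---------------------------------------------------------------------------
# arousal
# ---------------------------------------------------------------------------

def test_arousal_update_examples():
    assert arousal_update(1.0, 0.0, 0.97) == pytest.approx(0.97)
    assert arousal_update(0.4, 0.4, 0.93) == pytest.approx(0.4)  # fixed point
    assert arousal_update(0.25, -0.5, 0.97) == pytest.approx(0.2575)
    with pytest.raises(ConfigurationError):
        arousal_update(0.5, 0.1, 1.5)


@given(a=st.floats(0.0, 1.0), d=st.floats(-1.0, 1.0),
       eta=st.floats(0.01, 0.99))
@settings(derandomize=True, max_examples=100)
def test_arousal_stays_in_unit_interval(a, d, eta):
    """If A starts in [0,1] and |δ| ≤ 1, arousal never leaves [0,1]."""
    assert 0.0 <= arousal_update(a, d, eta) <= 1.0


def test_constant_surprise_drives_arousal_geometrically():
    a, eta, c = 1.0, 0.9, 0.3
    for i in range(1, 30):
        a = arousal_update(a, c, eta)
        assert a - c == pytest.approx((1.0 - c) * eta ** i)


# ---------------------------------------------------------------------------
# sign discipline, break decay, determinism
# ---------------------------------------------------------------------------

def test_sign_discipline_through_learning_and_extinction(params):
    agent = init_agent(params)
    rng = np.random.default_rng(7)
    for rewarded in rng.random(60) < 0.5:
        run_trial(agent, bool(rewarded), "acquisition", NO_DRUG, params)
        assert agent.w_plus.min() >= 0.0
        assert agent.w_minus.max() <= 0.0
    for _ in range(40):
        run_trial(agent, False, "extinction", NO_DRUG, params)
        assert agent.w_plus.min() >= 0.0
        assert agent.w_minus.max() <= 0.0
    assert agent.w_minus.min() < 0.0  # extinction actually built inhibition


def test_break_trial_decays_weights_only(params):
    agent = init_agent(params)
    agent.w_plus[:] = 0.8
    agent.w_minus[:] = -0.5
    agent.eligibility[:] = 0.3
    agent.arousal = 0.42
    rec = run_trial(agent, False, "break", NO_DRUG, params)
    assert np.allclose(agent.w_minus, -0.45)  # one ψ− step
    assert np.all(agent.eligibility == 0.0)
    assert agent.arousal == 0.42
    assert np.all(rec.delta_trace == 0.0)
    for _ in range(19):
        apply_break_trial(agent, params)
    assert agent.w_plus[0] == pytest.approx(0.8 * 0.999999 ** 20)
    assert agent.w_minus[0] == pytest.approx(-0.5 * 0.9 ** 20)


def test_zero_dose_matches_no_drug_bit_for_bit(params):
    schedule = (np.random.default_rng(3).random(30) < 0.5).tolist()
    outs = []
    for cond in (NO_DRUG, DrugCondition("enhance", 0.0),
                 DrugCondition("reduce", 0.0)):
        agent = init_agent(params)
        tr = [run_trial(agent, r, "acquisition", cond, params).delta_trace
              for r in schedule]
        outs.append((np.concatenate(tr), agent.w_plus.copy(),
                     agent.w_minus.copy()))
    for deltas, wp, wm in outs[1:]:
        assert np.array_equal(deltas, outs[0][0])
        assert np.array_equal(wp, outs[0][1])
        assert np.array_equal(wm, outs[0][2])


def test_td_step_rejects_mismatched_state(params):
    bad = AgentState(np.zeros(3), np.zeros(3), np.zeros(3))
    with pytest.raises(RuntimeError):
        td_step(bad, 5, 0.0, NO_DRUG, params)


def test_model_params_validation():
    with pytest.raises(ConfigurationError):
        ModelParams(alpha=-1.0)
    with pytest.raises(ConfigurationError):
        ModelParams(cs_time=9, reward_time=8)
    with pytest.raises(ConfigurationError):
        ModelParams(extinction_criterion=0.0)
    with pytest.raises(ConfigurationError):
        ModelParams(update_rule="other")
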