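"""The TD(λ) learning engine.

Value is represented over a complete serial compound: one feature per time
step from CS onset to the end of the trial, so ``V(t)`` is simply the sum of
the positive and negative weights of the feature active at ``t``.  The
prediction error uses the shifted-target convention

    δ(t) = r(t) + γ·V(t) − V(t−1),      V(t) = 0 for t < cs_time,

so the persistent CS-time dopamine response appears at ``t = cs_time``
(δ(cs) = γ·V(cs), since nothing before the CS can learn to predict it).
Weights are updated with the eligibility trace accumulated through ``t−1``;
the trace itself is then decayed by γλ and the current feature added.  The
CS-time δ therefore meets an empty trace and never self-reinforces.

Two weight populations share the features: positive weights (clamped ≥ 0)
are updated by δ of either sign at rate α and carry acquisition; negative
weights (clamped ≤ 0) are updated only by negative δ at rate β and carry the
inhibition learned in extinction.  Both updates are multiplied by the
current arousal level A.  During a break no prediction errors occur; the
weights simply decay (ψ⁺ for positive, ψ⁻ for negative), which — because
ψ⁻ ≪ ψ⁺ — releases the inhibition and produces spontaneous recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ConfigurationError, DrugCondition, ModelParams, NO_DRUG

__all__ = [
    "AgentState", "TrialRecord", "init_agent", "features",
    "drug_transform", "arousal_update", "td_step", "apply_break_trial",
    "run_trial",
]

PHASES = ("acquisition", "extinction", "break", "reacquisition")


@dataclass
class AgentState:
    """Mutable learner state: two weight vectors, trace, arousal."""

    w_plus: np.ndarray
    w_minus: np.ndarray
    eligibility: np.ndarray
    arousal: float = 1.0
    trial_index: int = 0

    def value(self, x: np.ndarray) -> float:
        """V = (w⁺ + w⁻)·x."""
        return float((self.w_plus + self.w_minus) @ x)

    def copy(self) -> "AgentState":
        return AgentState(self.w_plus.copy(), self.w_minus.copy(),
                          self.eligibility.copy(), self.arousal,
                          self.trial_index)


@dataclass
class TrialRecord:
    """Per-trial diagnostics.

    ``delta_trace`` and ``value_trace`` are indexed by time step (entry 0 is
    unused and zero, so ``delta_trace[cs_time]`` is δ at CS onset).
    """

    delta_trace: np.ndarray
    value_trace: np.ndarray
    delta_at_cs: float
    rewarded: bool
    arousal: float
    phase: str


def init_agent(params: ModelParams) -> AgentState:
    """Fresh agent: all weights and traces zero (V ≡ 0), arousal 1."""
    n = params.n_features
    return AgentState(w_plus=np.zeros(n), w_minus=np.zeros(n),
                      eligibility=np.zeros(n), arousal=1.0, trial_index=0)


def features(t: int, params: ModelParams) -> np.ndarray:
    """Serial-compound feature vector at time step ``t`` (1-based).

    One-hot on component ``t − cs_time`` from CS onset onward; all-zero
    before the CS.
    """
    if not 1 <= t <= params.trial_length:
        raise ValueError(
            f"time step {t} outside 1..{params.trial_length}")
    x = np.zeros(params.n_features)
    if t >= params.cs_time:
        x[t - params.cs_time] = 1.0
    return x


def drug_transform(delta: float, condition: DrugCondition) -> float:
    """Scale the prediction error by the simulated drug.

    reduce (dopamine activation):  δ′ = δ − d·|δ| — positive errors shrink,
    negative errors deepen, so reward value is underestimated.
    enhance (dopamine inactivation): δ′ = δ + d·|δ| — the opposite, so
    reward value is overestimated.  Dose 0 (or no drug) is the identity.
    """
    if condition.direction == "none" or condition.dose == 0.0:
        return delta
    if condition.direction == "reduce":
        return delta - condition.dose * abs(delta)
    return delta + condition.dose * abs(delta)


def arousal_update(arousal: float, delta: float, eta: float) -> float:
    """One per-trial arousal step: A′ = η·A + (1−η)·|δ|.

    η is the decay factor — the larger it is, the more slowly arousal tracks
    the magnitude of the prediction error.
    """
    if not 0.0 < eta < 1.0:
        raise ConfigurationError(f"eta must be in (0, 1), got {eta!r}")
    if arousal < 0:
        raise ValueError(f"arousal must be >= 0, got {arousal!r}")
    return eta * arousal + (1.0 - eta) * abs(delta)


def td_step(state: AgentState, t: int, reward: float,
            condition: DrugCondition, params: ModelParams,
            learning_enabled: bool = True) -> float:
    """Advance the learner by one within-trial time step; return δ(t).

    The returned δ is drug-transformed; it is the quantity used for the
    weight update and the one callers should record and feed to arousal.
    When ``learning_enabled`` is False (break phase) nothing happens and
    δ = 0 is returned.
    """
    if not learning_enabled:
        return 0.0
    x_t = features(t, params)
    x_prev = features(t - 1, params) if t > 1 else np.zeros(params.n_features)
    if x_t.shape != state.w_plus.shape:
        raise RuntimeError("feature/state dimension mismatch")
    v_t = state.value(x_t)
    v_prev = state.value(x_prev)
    delta = reward + params.gamma * v_t - v_prev
    delta = drug_transform(delta, condition)

    a = state.arousal
    e = state.eligibility
    rule = params.update_rule
    upd_plus = True if rule in ("shared", "plus_both") else delta > 0
    upd_minus = True if rule == "shared" else delta < 0
    if upd_plus:
        state.w_plus += params.alpha * a * delta * e
        np.maximum(state.w_plus, 0.0, out=state.w_plus)
    if upd_minus:
        state.w_minus += params.beta * a * delta * e
        np.minimum(state.w_minus, 0.0, out=state.w_minus)
    # trace decays then picks up the current feature — it lags δ by one step
    state.eligibility = params.gamma * params.lambda_trace * e + x_t
    return delta


def apply_break_trial(state: AgentState, params: ModelParams) -> AgentState:
    """One break trial: weights decay (ψ⁺/ψ⁻), trace cleared, no δ."""
    state.w_plus *= params.psi_plus
    state.w_minus *= params.psi_minus
    state.eligibility[:] = 0.0
    state.trial_index += 1
    return state


def run_trial(state: AgentState, rewarded: bool, phase: str,
              condition: DrugCondition, params: ModelParams) -> TrialRecord:
    """Run one complete trial and return its diagnostics.

    Break trials only decay the weights.  Otherwise the eligibility trace is
    reset (trials are separated by long inter-trial intervals), the drug
    transform is applied in the phases selected by ``params.drug_window``,
    and every time step runs through :func:`td_step`.  Arousal is *used*
    here but never updated — the per-trial arousal schedule belongs to the
    protocol runner.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    T = params.trial_length
    if phase == "break":
        apply_break_trial(state, params)
        z = np.zeros(T + 1)
        return TrialRecord(delta_trace=z, value_trace=z.copy(),
                           delta_at_cs=0.0, rewarded=False,
                           arousal=state.arousal, phase=phase)

    cond = condition
    if params.drug_window == "acquisition_only" and phase not in (
            "acquisition", "reacquisition"):
        cond = NO_DRUG

    # same recurrences as td_step, written with one-hot indexing instead of
    # feature vectors so sweeps stay cheap; the brute-force oracle test
    # pins the two paths together to 1e-12
    cs, rt = params.cs_time, params.reward_time
    gamma, lam = params.gamma, params.lambda_trace
    a = state.arousal
    rule = params.update_rule
    w_sum = state.w_plus + state.w_minus
    e = state.eligibility
    e[:] = 0.0
    deltas = np.zeros(T + 1)
    values = np.zeros(T + 1)
    for t in range(1, T + 1):
        v_t = w_sum[t - cs] if t >= cs else 0.0
        v_prev = w_sum[t - 1 - cs] if t - 1 >= cs else 0.0
        r = params.reward_magnitude if (rewarded and t == rt) else 0.0
        delta = drug_transform(r + gamma * v_t - v_prev, cond)
        if delta != 0.0:
            if rule in ("shared", "plus_both") or delta > 0:
                state.w_plus += params.alpha * a * delta * e
                np.maximum(state.w_plus, 0.0, out=state.w_plus)
            if rule == "shared" or delta < 0:
                state.w_minus += params.beta * a * delta * e
                np.minimum(state.w_minus, 0.0, out=state.w_minus)
            np.add(state.w_plus, state.w_minus, out=w_sum)
        e *= gamma * lam
        if t >= cs:
            e[t - cs] += 1.0
        deltas[t], values[t] = delta, v_t
    state.trial_index += 1
    return TrialRecord(delta_trace=deltas, value_trace=values,
                       delta_at_cs=float(deltas[params.cs_time]),
                       rewarded=rewarded, arousal=state.arousal, phase=phase)
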