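"""Model parameters and drug conditions.

The model is a trial-based TD(λ) learner over a complete-serial-compound
stimulus representation, with separate positive (excitatory) and negative
(inhibitory) weight populations, break-only forgetting, and a slowly decaying
arousal signal that multiplies the learning rate during extinction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

__all__ = ["ModelParams", "DrugCondition", "NO_DRUG", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Raised for out-of-range or inconsistent model/run configuration."""


@dataclass(frozen=True)
class ModelParams:
    """All scalar constants of the learning model.

    Parameters
    ----------
    alpha : float
        Learning rate of the positive (excitatory) weights.
    beta : float
        Learning rate of the negative (inhibitory) weights.  Smaller than
        ``alpha`` by default so acquisition of probabilistic rewards does not
        fluctuate wildly.
    lambda_trace : float
        Eligibility-trace decay factor λ.
    psi_plus, psi_minus : float
        Per-break-trial decay factors of the positive and negative weights.
        ``psi_plus`` is very close to 1 while ``psi_minus`` is much smaller:
        during a break the inhibition learned in extinction fades quickly
        while the excitatory association survives, which is what produces
        spontaneous recovery.
    eta : float
        Arousal decay factor η per extinction trial; larger η means arousal
        (and hence the effective learning rate) tracks the prediction error
        more slowly.
    gamma : float
        Temporal discount factor per within-trial time step.  The default of
        1 (no discounting inside the short 10-step trial) makes the
        asymptotic CS response equal the reward probability, which is what
        places the lowest probability's response far enough above the
        extinction criterion for the slow-extinction regime to exist.
    trial_length : int
        Number of time steps per trial.
    cs_time, reward_time : int
        Time steps of CS onset and reward delivery within a trial.
    reward_magnitude : float
        Size of the reward in value units.
    extinction_criterion : float
        Threshold on |δ(CS)|; the first extinction trial whose CS-time
        prediction error falls below it counts as extinction complete.
    arousal_enabled : bool
        If False, arousal stays pinned at 1 in every phase (the plain TD
        model without the associability mechanism).
    arousal_source : {"reward_time", "max_abs"}
        Which δ of an extinction trial drives the arousal update: the
        outcome-time error (default) or the largest |δ| in the trial.
    drug_window : {"both", "acquisition_only"}
        Phases in which the prediction-error drug transform is active.
    update_rule : {"shared", "split", "plus_both"}
        Which prediction errors each weight population sees.  "shared"
        (default): both populations are driven by every δ and the sign
        clamps do the gating — rewarded trials push the inhibitory weights
        back toward zero, so during acquisition the net value converges to
        the reward probability itself.  "plus_both": positive weights see
        every δ, negative weights only negative δ (inhibition then
        accumulates during probabilistic acquisition, deflating the learned
        value).  "split": each population sees only its own sign of δ
        (extinction is then carried by the slow inhibitory rate alone).
    """

    alpha: float = 0.08
    beta: float = 0.04
    lambda_trace: float = 0.9
    psi_plus: float = 0.999999
    psi_minus: float = 0.9
    eta: float = 0.97
    gamma: float = 1.0
    trial_length: int = 10
    cs_time: int = 3
    reward_time: int = 8
    reward_magnitude: float = 1.0
    extinction_criterion: float = 0.12
    arousal_enabled: bool = True
    arousal_source: str = "reward_time"
    drug_window: str = "both"
    update_rule: str = "shared"

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "lambda_trace", "psi_plus",
                     "psi_minus", "eta", "gamma"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigurationError(
                    f"{name} must be in (0, 1], got {v!r}")
        if not 1 <= self.cs_time < self.reward_time <= self.trial_length:
            raise ConfigurationError(
                "need 1 <= cs_time < reward_time <= trial_length, got "
                f"cs_time={self.cs_time}, reward_time={self.reward_time}, "
                f"trial_length={self.trial_length}")
        if self.extinction_criterion <= 0:
            raise ConfigurationError("extinction_criterion must be > 0")
        if self.reward_magnitude <= 0:
            raise ConfigurationError("reward_magnitude must be > 0")
        if self.arousal_source not in ("reward_time", "max_abs"):
            raise ConfigurationError(
                f"arousal_source must be 'reward_time' or 'max_abs', "
                f"got {self.arousal_source!r}")
        if self.drug_window not in ("both", "acquisition_only"):
            raise ConfigurationError(
                f"drug_window must be 'both' or 'acquisition_only', "
                f"got {self.drug_window!r}")
        if self.update_rule not in ("shared", "split", "plus_both"):
            raise ConfigurationError(
                f"update_rule must be 'shared', 'split' or 'plus_both', "
                f"got {self.update_rule!r}")

    @property
    def n_features(self) -> int:
        """Length of the serial-compound feature vector (one feature per
        time step from CS onset to the end of the trial)."""
        return self.trial_length - self.cs_time + 1

    def replace(self, **changes) -> "ModelParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class DrugCondition:
    """A simulated pharmacological manipulation of the prediction error.

    ``enhance`` scales up |δ| (simulated dopamine-neuron inactivation, which
    sharpens the contrast between phasic and tonic firing); ``reduce`` scales
    it down (simulated dopamine-neuron activation).  ``dose`` is the
    dimensionless drug amount d.
    """

    direction: str = "none"
    dose: float = 0.0

    def __post_init__(self) -> None:
        if self.direction not in ("none", "enhance", "reduce"):
            raise ConfigurationError(
                f"direction must be one of none/enhance/reduce, "
                f"got {self.direction!r}")
        if self.dose < 0:
            raise ConfigurationError(f"dose must be >= 0, got {self.dose!r}")
        if self.direction == "reduce" and self.dose >= 1:
            raise ConfigurationError(
                "reduce with dose >= 1 would flip the sign of the "
                f"prediction error (dose={self.dose!r})")

    @property
    def is_active(self) -> bool:
        return self.direction != "none" and self.dose > 0


NO_DRUG = DrugCondition()
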