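"""Reward schedules and multi-phase experiment protocols.

Acquisition schedules are exact-count shuffles, not i.i.d. draws: a 20-trial
session at probability p contains exactly ``20·p`` rewards in a seeded
pseudorandom order, mirroring the behavioral sessions.  Longer simulated
acquisition phases are concatenations of independently shuffled 20-trial
blocks.  Two behavioral designs are supported: *trial-constant* (20 trials,
the reward count varies with p) and *reward-constant* (20 rewards, the trial
count varies with p).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .params import ConfigurationError

__all__ = [
    "SessionSpec", "Protocol", "build_trial_constant",
    "build_reward_constant", "build_acquisition_schedule",
    "build_simulation_protocol",
]

BLOCK_SIZE = 20  # behavioral sessions combined to build simulated acquisition


@dataclass(frozen=True)
class SessionSpec:
    """One phase of a protocol: an ordered reward schedule plus its label."""

    phase: str  # acquisition | extinction | break | reacquisition
    probability: float  # programmed reward probability (0 for ext/break)
    schedule: tuple  # per-trial reward indicators
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.phase in ("extinction", "break") and any(self.schedule):
            raise ConfigurationError(
                f"{self.phase} schedules must be all-unrewarded")

    @property
    def n_trials(self) -> int:
        return len(self.schedule)

    @property
    def n_rewards(self) -> int:
        return sum(self.schedule)


@dataclass(frozen=True)
class Protocol:
    """An ordered list of sessions, e.g. acquisition → extinction → break →
    extinction (the standard spontaneous-recovery design)."""

    sessions: tuple
    label: str = ""

    def __post_init__(self) -> None:
        seen_acq = False
        for s in self.sessions:
            if s.phase in ("acquisition", "reacquisition"):
                seen_acq = True
            elif not seen_acq:
                raise ConfigurationError(
                    f"{s.phase} cannot precede the first acquisition")

    @property
    def n_trials(self) -> int:
        return sum(s.n_trials for s in self.sessions)

    def to_json(self) -> str:
        return json.dumps({
            "label": self.label,
            "sessions": [
                {"phase": s.phase, "probability": s.probability,
                 "schedule": [int(b) for b in s.schedule], "seed": s.seed}
                for s in self.sessions],
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Protocol":
        doc = json.loads(text)
        sessions = tuple(
            SessionSpec(phase=s["phase"], probability=s["probability"],
                        schedule=tuple(bool(b) for b in s["schedule"]),
                        seed=s.get("seed"))
            for s in doc["sessions"])
        return cls(sessions=sessions, label=doc.get("label", ""))


def _max_gap(sched: list) -> int:
    gap = longest = 0
    for rewarded in sched:
        gap = 0 if rewarded else gap + 1
        longest = max(longest, gap)
    return longest


def _shuffled_block(n_trials: int, n_rewards: int,
                    rng: np.random.Generator,
                    max_consecutive_omissions: int | None = None) -> list:
    """Exact-count shuffle; optionally reject orders with reward droughts
    longer than ``max_consecutive_omissions`` (the behavioral sessions kept
    gaps bounded — e.g. a pellet every few trials at low probability)."""
    if max_consecutive_omissions is not None \
            and max_consecutive_omissions * (n_rewards + 1) < \
            n_trials - n_rewards:
        raise ConfigurationError(
            "max_consecutive_omissions infeasible for this reward count")
    sched = [True] * n_rewards + [False] * (n_trials - n_rewards)
    rng.shuffle(sched)
    while max_consecutive_omissions is not None \
            and _max_gap(sched) > max_consecutive_omissions:
        rng.shuffle(sched)
    return sched


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def build_trial_constant(p: float, seed: int) -> SessionSpec:
    """Trial-constant acquisition session: 20 trials, exactly 20·p rewards."""
    if not 0 < p <= 1:
        raise ConfigurationError(f"probability must be in (0, 1], got {p!r}")
    n_rewards = BLOCK_SIZE * p
    if abs(n_rewards - round(n_rewards)) > 1e-9:
        raise ConfigurationError(
            f"{BLOCK_SIZE}*p must be integral for a trial-constant session "
            f"(p={p!r})")
    rng = np.random.default_rng(seed)
    sched = _shuffled_block(BLOCK_SIZE, round(n_rewards), rng)
    return SessionSpec("acquisition", p, tuple(sched), seed)


def build_reward_constant(p: float, seed: int) -> SessionSpec:
    """Reward-constant acquisition session: exactly 20 rewards among
    ceil(20/p) trials."""
    if not 0 < p <= 1:
        raise ConfigurationError(f"probability must be in (0, 1], got {p!r}")
    n_trials = math.ceil(BLOCK_SIZE / p)
    rng = np.random.default_rng(seed)
    sched = _shuffled_block(n_trials, BLOCK_SIZE, rng)
    return SessionSpec("acquisition", p, tuple(sched), seed)


def build_acquisition_schedule(
        p: float, n_trials: int, seed: int,
        max_consecutive_omissions: int | None = None) -> list:
    """Exact-count acquisition schedule of arbitrary length.

    Built from independently shuffled 20-trial blocks of ``round(20·p)``
    rewards each; a remainder block of r trials carries ``round(r·p)``
    rewards (half-up).
    """
    if not 0 < p <= 1:
        raise ConfigurationError(f"probability must be in (0, 1], got {p!r}")
    if n_trials * p < 1:
        raise ConfigurationError(
            f"n_trials*p = {n_trials * p} < 1: no rewards to learn from")
    ss = np.random.SeedSequence([int(seed), 0])
    rng = np.random.default_rng(ss)
    sched: list = []
    remaining = n_trials
    while remaining > 0:
        block = min(BLOCK_SIZE, remaining)
        n_rewards = _round_half_up(block * p)
        sched.extend(_shuffled_block(block, n_rewards, rng,
                                     max_consecutive_omissions))
        remaining -= block
    return sched


def build_simulation_protocol(p: float, n_acq: int, seed: int,
                              n_ext1: int = 70, n_break: int = 20,
                              n_ext2: int = 40,
                              label: str = "") -> Protocol:
    """The standard simulated design: ``n_acq`` acquisition trials at
    probability p, then 70 extinction trials, a 20-trial break, and 40 more
    extinction trials (which show spontaneous recovery)."""
    if n_acq < 1:
        raise ConfigurationError(f"n_acq must be >= 1, got {n_acq!r}")
    acq = SessionSpec("acquisition", p,
                      tuple(build_acquisition_schedule(p, n_acq, seed)), seed)
    sessions = [acq]
    for phase, n in (("extinction", n_ext1), ("break", n_break),
                     ("extinction", n_ext2)):
        if n > 0:
            sessions.append(SessionSpec(phase, 0.0, (False,) * n))
    return Protocol(tuple(sessions),
                    label=label or f"sim_p{int(round(p * 100))}_n{n_acq}")
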