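"""Protocol execution, extinction measures, sweeps and normalizations.

The central measurement is *trials to extinction*: the 1-based index of the
first extinction trial whose CS-time prediction error falls below the
criterion.  Sweeps evaluate it over grids of reward probability, arousal
decay factor η, acquisition length and drug dose, averaging over seeded
reward schedules, and classify the shape of the extinction-vs-probability
curve (decreasing = PREE, interior maximum = inverted-U, increasing = the
no-arousal pattern).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .agent import (AgentState, TrialRecord, arousal_update, init_agent,
                    run_trial)
from .params import ConfigurationError, DrugCondition, ModelParams, NO_DRUG
from .protocols import Protocol, build_simulation_protocol

__all__ = [
    "run_protocol", "ExtinctionResult", "trials_to_extinction",
    "classify_curve", "SweepResult", "sweep", "dose_response",
    "normalize_by_subject_mean", "normalize_to_reference",
]

PROBABILITY_GRID = (0.25, 0.5, 0.75, 1.0)
ETA_GRID = (0.91, 0.93, 0.95, 0.97, 0.99)


def _trial_arousal_delta(record: TrialRecord, params: ModelParams) -> float:
    if params.arousal_source == "max_abs":
        return float(np.max(np.abs(record.delta_trace)))
    return float(record.delta_trace[params.reward_time])


def run_protocol(params: ModelParams, protocol: Protocol,
                 condition: DrugCondition = NO_DRUG,
                 agent: AgentState | None = None) -> list:
    """Run every trial of ``protocol`` and return one TrialRecord per trial.

    Arousal schedule: pinned at 1 throughout acquisition; at the first
    extinction trial after an acquisition phase it is reset to the
    programmed reward probability (the learned reliability of the reward),
    then updated once per extinction trial from that trial's outcome-time
    prediction error.  Break trials leave arousal untouched.  With
    ``params.arousal_enabled`` False, arousal stays at 1 everywhere.
    """
    state = agent if agent is not None else init_agent(params)
    records: list = []
    last_acq_probability: float | None = None
    prev_phase: str | None = None
    for session in protocol.sessions:
        if session.phase in ("acquisition", "reacquisition"):
            state.arousal = 1.0
            last_acq_probability = session.probability
        elif (session.phase == "extinction"
              and prev_phase in ("acquisition", "reacquisition")
              and params.arousal_enabled):
            if last_acq_probability is None:
                raise ConfigurationError(
                    "extinction phase with no preceding acquisition")
            state.arousal = last_acq_probability
        for rewarded in session.schedule:
            rec = run_trial(state, bool(rewarded), session.phase,
                            condition, params)
            records.append(rec)
            if session.phase == "extinction" and params.arousal_enabled:
                state.arousal = arousal_update(
                    state.arousal, _trial_arousal_delta(rec, params),
                    params.eta)
        prev_phase = session.phase
    return records


class ExtinctionResult(NamedTuple):
    """Trials until the extinction criterion; ``reached`` is False when the
    criterion was never met, in which case ``trials`` is the (censored)
    phase length."""

    trials: int
    reached: bool


def trials_to_extinction(records: Sequence[TrialRecord],
                         criterion: float) -> ExtinctionResult:
    """1-based index of the first extinction trial with |δ(CS)| below the
    criterion, over a contiguous run of extinction-phase records."""
    if len(records) == 0:
        raise ValueError("empty extinction record list")
    for rec in records:
        if rec.phase != "extinction":
            raise ValueError(
                f"expected extinction-phase records, got {rec.phase!r}")
    for i, rec in enumerate(records, start=1):
        if abs(rec.delta_at_cs) < criterion:
            return ExtinctionResult(i, True)
    return ExtinctionResult(len(records), False)


def classify_curve(counts: Sequence[float],
                   tolerance: float = 0.5) -> str:
    """Label a trials-to-extinction curve ordered by increasing probability.

    ``decreasing_PREE``: strictly decreasing with every pairwise drop larger
    than the tolerance; ``increasing``: the mirror image; ``inverted_U``:
    an interior maximum exceeding both endpoints by more than the tolerance;
    otherwise ``flat_or_mixed``.
    """
    c = np.asarray(counts, dtype=float)
    if c.size < 3:
        raise ValueError("need at least 3 probability levels to classify")
    diffs = np.diff(c)
    if np.all(diffs < -tolerance):
        return "decreasing_PREE"
    if np.all(diffs > tolerance):
        return "increasing"
    k = int(np.argmax(c))
    if 0 < k < c.size - 1 and c[k] - c[0] > tolerance \
            and c[k] - c[-1] > tolerance:
        return "inverted_U"
    return "flat_or_mixed"


@dataclass
class SweepResult:
    """Tidy per-seed results of a sweep plus grid metadata.

    ``data`` has one row per (probability, eta, n_acq, direction, dose,
    seed) cell-run with columns ``trials_to_extinction``, ``end_value``
    (δ(CS) on the last acquisition trial) and ``censored``.
    """

    data: pd.DataFrame
    probabilities: tuple
    etas: tuple
    n_acqs: tuple
    doses: tuple
    seeds: tuple
    tolerance: float = 0.5

    _CELL = ["eta", "n_acq", "direction", "dose"]

    def cell_means(self) -> pd.DataFrame:
        """Mean trials-to-extinction and end-of-acquisition value per
        (probability × the other axes) cell, with a censoring flag."""
        g = self.data.groupby(self._CELL + ["probability"], sort=True)
        out = g.agg(trials_to_extinction=("trials_to_extinction", "mean"),
                    end_value=("end_value", "mean"),
                    censored=("censored", "any")).reset_index()
        return out

    def shape_labels(self) -> pd.DataFrame:
        """Curve-shape label per (eta, n_acq, direction, dose) over the
        probability axis; curves touched by censoring are flat_or_mixed."""
        means = self.cell_means()
        rows = []
        for key, grp in means.groupby(self._CELL, sort=True):
            grp = grp.sort_values("probability")
            if grp["censored"].any():
                label = "flat_or_mixed"
            else:
                label = classify_curve(
                    grp["trials_to_extinction"].to_numpy(), self.tolerance)
            rows.append(dict(zip(self._CELL, key)) | {"shape_label": label})
        return pd.DataFrame(rows)


def _run_cell(params: ModelParams, p: float, n_acq: int,
              condition: DrugCondition, seed: int) -> tuple:
    protocol = build_simulation_protocol(p, n_acq, seed)
    records = run_protocol(params, protocol, condition)
    acq = [r for r in records if r.phase == "acquisition"]
    n_ext1 = protocol.sessions[1].n_trials
    ext1 = records[n_acq:n_acq + n_ext1]
    res = trials_to_extinction(ext1, params.extinction_criterion)
    return res.trials, not res.reached, acq[-1].delta_at_cs


def sweep(params: ModelParams,
          probabilities: Sequence[float] = PROBABILITY_GRID,
          etas: Sequence[float] = ETA_GRID,
          n_acqs: Sequence[int] = (30,),
          condition: DrugCondition = NO_DRUG,
          n_seeds: int = 20,
          seeds: Sequence[int] | None = None,
          tolerance: float = 0.5) -> SweepResult:
    """Trials-to-extinction over a (probability × η × acquisition-length)
    grid, each cell averaged over the same explicit list of schedule seeds.
    """
    if seeds is None:
        seeds = list(range(n_seeds))
    if len(seeds) < 1:
        raise ConfigurationError("need at least one seed")
    rows = []
    for n_acq in n_acqs:
        for p in probabilities:
            for eta in etas:
                cell_params = params.replace(eta=eta)
                for seed in seeds:
                    tte, cens, end_v = _run_cell(
                        cell_params, p, n_acq, condition, seed)
                    rows.append({
                        "probability": p, "eta": eta, "n_acq": n_acq,
                        "direction": condition.direction,
                        "dose": condition.dose, "seed": seed,
                        "trials_to_extinction": tte, "end_value": end_v,
                        "censored": cens})
    return SweepResult(pd.DataFrame(rows), tuple(probabilities), tuple(etas),
                       tuple(n_acqs), (condition.dose,), tuple(seeds),
                       tolerance)


def dose_response(params: ModelParams,
                  probabilities: Sequence[float] = PROBABILITY_GRID,
                  direction: str = "reduce",
                  doses: Sequence[float] = (0.0, 0.05, 0.1),
                  n_acq: int = 30,
                  n_seeds: int = 20,
                  seeds: Sequence[int] | None = None,
                  tolerance: float = 0.5) -> SweepResult:
    """End-of-acquisition value and trials-to-extinction per (probability,
    dose) under one drug direction; η and n_acq default to the
    moderate-training setting (η = 0.97, 30 acquisition trials)."""
    if seeds is None:
        seeds = list(range(n_seeds))
    rows = []
    for dose in doses:
        condition = DrugCondition(direction, dose)
        for p in probabilities:
            for seed in seeds:
                tte, cens, end_v = _run_cell(params, p, n_acq, condition,
                                             seed)
                rows.append({
                    "probability": p, "eta": params.eta, "n_acq": n_acq,
                    "direction": condition.direction, "dose": dose,
                    "seed": seed, "trials_to_extinction": tte,
                    "end_value": end_v, "censored": cens})
    return SweepResult(pd.DataFrame(rows), tuple(probabilities),
                       (params.eta,), (n_acq,), tuple(doses), tuple(seeds),
                       tolerance)


def normalize_by_subject_mean(counts) -> np.ndarray | pd.DataFrame:
    """Divide each subject's per-session counts by that subject's mean.

    Removes between-subject baseline differences; every output row has mean
    exactly 1.  Accepts a 2-D array or DataFrame (rows = subjects).
    """
    is_frame = isinstance(counts, pd.DataFrame)
    a = np.asarray(counts, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a subjects x sessions matrix")
    if np.all(np.isnan(a), axis=1).any():
        raise ValueError("subject with all-missing sessions")
    row_means = np.nanmean(a, axis=1, keepdims=True)
    if np.any(row_means == 0):
        raise ValueError("subject with zero mean count")
    out = a / row_means
    if is_frame:
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


def normalize_to_reference(counts, reference) -> pd.Series:
    """Divide a per-probability curve by its value at the reference
    probability level (so the reference entry is exactly 1)."""
    s = pd.Series(counts, dtype=float) if not isinstance(counts, pd.Series) \
        else counts.astype(float)
    if reference not in s.index:
        raise ValueError(f"reference level {reference!r} not in curve")
    ref = s.loc[reference]
    if not np.isfinite(ref) or ref == 0:
        raise ValueError("reference level has no valid count")
    return s / ref
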