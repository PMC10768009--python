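"""Rescorla-Wagner value learning with explicit reinforcement efficacy.

The model separates two constructs that are usually conflated in
reinforcement-learning analyses of conditioning data:

* ``alpha`` -- the learning rate, i.e. the fraction of each reward prediction
  error (RPE) folded into the next value estimate.  It controls how fast the
  learning curve rises.
* ``lam`` (lambda) -- reinforcement efficacy, the asymptote scale of learning.
  It controls how large the elicited RPEs (and hence any RPE-coupled neural
  signal) can be.

Value updates follow

    Q[t+1] = Q[t] + alpha * RPE[t],      RPE[t] = lam * outcome[t] - Q[t]

with binary outcomes in {0, 1}.  Instrumental (two-option) agents choose via a
softmax on the current option values with inverse temperature ``theta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "RWParams",
    "SoftmaxParams",
    "AgentTrace",
    "rw_step",
    "simulate_pavlovian",
    "softmax_prob",
    "simulate_instrumental",
]


@dataclass(frozen=True)
class RWParams:
    """Generative (or analysis-side) parameters of one Rescorla-Wagner agent."""

    alpha: float
    lam: float = 1.0
    q0: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.lam <= 0.0:
            raise ValueError(f"lam must be positive, got {self.lam}")


@dataclass(frozen=True)
class SoftmaxParams:
    """Choice-rule parameters: non-negative inverse temperature theta."""

    theta: float

    def __post_init__(self) -> None:
        if self.theta < 0.0:
            raise ValueError(f"theta must be non-negative, got {self.theta}")


@dataclass
class AgentTrace:
    """Per-trial record of one agent run.

    ``qvalues`` holds the value *before* that trial's update; for instrumental
    traces it has one column per option and ``choices`` gives the chosen
    option index per trial.  ``rpes`` is always the chosen (or sole) option's
    prediction error, the quantity taken to drive phasic dopaminergic /
    BOLD responses.
    """

    outcomes: np.ndarray
    rpes: np.ndarray
    qvalues: np.ndarray
    choices: Optional[np.ndarray] = None

    @property
    def n_trials(self) -> int:
        return len(self.outcomes)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-trial table (trial, [choice,] outcome, q, rpe)."""
        data: dict = {"trial": np.arange(self.n_trials)}
        if self.choices is not None:
            data["choice"] = self.choices
            data["q"] = self.qvalues[np.arange(self.n_trials), self.choices]
        else:
            data["q"] = self.qvalues
        data["outcome"] = self.outcomes
        data["rpe"] = self.rpes
        return pd.DataFrame(data)


def rw_step(q: float, outcome: float, params: RWParams) -> tuple[float, float]:
    """One Rescorla-Wagner update; returns (next value, prediction error)."""
    rpe = params.lam * outcome - q
    return q + params.alpha * rpe, rpe


def simulate_pavlovian(outcomes, params: RWParams) -> AgentTrace:
    """Run a single-cue (classical conditioning) agent over a fixed outcome
    sequence.  Deterministic given inputs; arithmetic is identical to
    repeated :func:`rw_step`."""
    outcomes = np.asarray(outcomes, dtype=float)
    if outcomes.ndim != 1 or outcomes.size == 0:
        raise ValueError("outcomes must be a non-empty 1-D sequence")
    n = outcomes.size
    q = params.q0
    qvalues = np.empty(n)
    rpes = np.empty(n)
    for t in range(n):
        qvalues[t] = q
        q, rpes[t] = rw_step(q, outcomes[t], params)
    return AgentTrace(outcomes=outcomes, rpes=rpes, qvalues=qvalues)


def softmax_prob(qA: float, qB: float, theta: float) -> float:
    """P(choose A) = e^(theta qA) / (e^(theta qA) + e^(theta qB)).

    Computed through the logistic of the scaled value difference, so it is
    stable for arbitrarily large theta*q.
    """
    if theta < 0:
        raise ValueError("theta must be non-negative")
    return float(expit(theta * (qA - qB)))


def simulate_instrumental(
    schedule,
    params: RWParams,
    sm: SoftmaxParams,
    rng: np.random.Generator,
) -> AgentTrace:
    """Run a two-option agent on a :class:`~rlderiv.paradigms.Schedule`.

    On each trial the agent samples a choice from the softmax over current
    values, receives the chosen option's scheduled outcome, and updates only
    the chosen option's value (the unchosen value carries forward unchanged).
    The recorded RPE is the chosen option's prediction error.
    """
    outcomes_table = np.asarray(schedule.outcomes)
    if outcomes_table.ndim != 2 or outcomes_table.shape[1] != 2:
        raise ValueError("instrumental simulation requires a 2-option schedule")
    n = outcomes_table.shape[0]
    q = np.array([params.q0, params.q0], dtype=float)
    qvalues = np.empty((n, 2))
    rpes = np.empty(n)
    choices = np.empty(n, dtype=np.int64)
    outcomes = np.empty(n)
    u = rng.random(n)
    for t in range(n):
        qvalues[t] = q
        p_a = softmax_prob(q[0], q[1], sm.theta)
        c = 0 if u[t] < p_a else 1
        o = float(outcomes_table[t, c])
        q[c], rpes[t] = rw_step(q[c], o, params)
        choices[t] = c
        outcomes[t] = o
    return AgentTrace(outcomes=outcomes, rpes=rpes, qvalues=qvalues, choices=choices)
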