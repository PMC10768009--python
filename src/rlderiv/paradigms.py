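"""Reward schedules and participant-level generative parameters.

Both simulated paradigms reward a cue with probability 0.5 on the first trial;
the probability then performs a Gaussian random walk (scaled by a per-person
drift rate, clipped to [0, 1]) across trials.  The instrumental variant has two
options with independent walks.  Simulated participants draw every generative
parameter i.i.d. uniform from a configured range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Schedule",
    "ParameterRanges",
    "ParticipantSpec",
    "drifting_walk",
    "make_schedule",
    "sample_participants",
    "participant_rng",
]


@dataclass
class Schedule:
    """Per-trial reward probabilities and sampled binary outcomes.

    ``probs`` and ``outcomes`` are (n_trials, n_options) arrays; column j is
    option j.  Pavlovian schedules have a single column.
    """

    probs: np.ndarray
    outcomes: np.ndarray
    drift: float
    seed: int | None = None

    @property
    def n_trials(self) -> int:
        return self.probs.shape[0]

    @property
    def n_options(self) -> int:
        return self.probs.shape[1]


def drifting_walk(
    n_trials: int,
    drift: float,
    p0: float = 0.5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Random-walk reward probability: p[t+1] = clip(p[t] + drift * N(0,1), 0, 1)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if drift < 0:
        raise ValueError("drift must be non-negative")
    if rng is None:
        rng = np.random.default_rng()
    p = np.empty(n_trials)
    p[0] = p0
    if n_trials > 1:
        steps = drift * rng.standard_normal(n_trials - 1)
        cur = p0
        for t in range(1, n_trials):
            cur = min(1.0, max(0.0, cur + steps[t - 1]))
            p[t] = cur
    return p


def make_schedule(
    n_trials: int,
    drift: float,
    n_options: int = 1,
    rng: np.random.Generator | None = None,
) -> Schedule:
    """Independent drifting walks per option; outcomes sampled Bernoulli(p)."""
    if n_options not in (1, 2):
        raise ValueError("n_options must be 1 or 2")
    if rng is None:
        rng = np.random.default_rng()
    probs = np.column_stack(
        [drifting_walk(n_trials, drift, rng=rng) for _ in range(n_options)]
    )
    outcomes = (rng.random(probs.shape) < probs).astype(np.int64)
    return Schedule(probs=probs, outcomes=outcomes, drift=drift)


# Default ranges of the uniform per-participant parameter distributions.
_DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "alpha": (0.2, 0.7),
    "lam": (0.75, 1.25),
    "drift": (0.0, 0.4),
    "theta": (0.0, 5.0),
    "snr": (2.0, 4.0),
    "noise_exponent": (0.8, 1.2),
    "hrf_scale": (1.0, 1.0),  # fixed at 1 unless the HRF-scaling analysis is on
}


@dataclass(frozen=True)
class ParameterRanges:
    """Lower/upper bounds of each uniformly distributed generative parameter."""

    alpha: tuple[float, float] = _DEFAULT_RANGES["alpha"]
    lam: tuple[float, float] = _DEFAULT_RANGES["lam"]
    drift: tuple[float, float] = _DEFAULT_RANGES["drift"]
    theta: tuple[float, float] = _DEFAULT_RANGES["theta"]
    snr: tuple[float, float] = _DEFAULT_RANGES["snr"]
    noise_exponent: tuple[float, float] = _DEFAULT_RANGES["noise_exponent"]
    hrf_scale: tuple[float, float] = _DEFAULT_RANGES["hrf_scale"]

    def __post_init__(self) -> None:
        for name in _DEFAULT_RANGES:
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"inverted range for {name}: ({lo}, {hi})")

    def with_varying_hrf(self) -> "ParameterRanges":
        return replace(self, hrf_scale=(0.5, 1.5))


@dataclass(frozen=True)
class ParticipantSpec:
    """One simulated participant: generative parameters plus a child seed."""

    alpha: float
    lam: float
    drift: float
    theta: float
    snr: float
    noise_exponent: float
    hrf_scale: float
    n_trials: int
    seed: int


def _child_seeds(master_seed: int, n: int) -> np.ndarray:
    """Reproducible, order-independent per-participant seeds (< 2**31)."""
    children = np.random.SeedSequence(master_seed).spawn(n)
    return np.array(
        [int(c.generate_state(1, np.uint32)[0]) % (2**31) for c in children],
        dtype=np.int64,
    )


def participant_rng(spec: ParticipantSpec, stream: int = 0) -> np.random.Generator:
    """Independent named stream for one participant (0=schedule, 1=noise, ...)."""
    return np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(stream,)))


def sample_participants(
    n: int,
    ranges: ParameterRanges | None = None,
    master_seed: int = 0,
    n_trials: int = 200,
) -> list[ParticipantSpec]:
    """Draw n participants with i.i.d. uniform parameters on the given ranges.

    The master seed fully determines both the parameter draws and every child
    seed, so identical (n, ranges, master_seed) give identical spec lists.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if ranges is None:
        ranges = ParameterRanges()
    rng = np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(0xA11CE,)))
    draws = {
        name: rng.uniform(*getattr(ranges, name), size=n) for name in _DEFAULT_RANGES
    }
    seeds = _child_seeds(master_seed, n)
    return [
        ParticipantSpec(
            alpha=float(draws["alpha"][i]),
            lam=float(draws["lam"][i]),
            drift=float(draws["drift"][i]),
            theta=float(draws["theta"][i]),
            snr=float(draws["snr"][i]),
            noise_exponent=float(draws["noise_exponent"][i]),
            hrf_scale=float(draws["hrf_scale"][i]),
            n_trials=n_trials,
            seed=int(seeds[i]),
        )
        for i in range(n)
    ]
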