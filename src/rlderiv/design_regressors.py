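"""Trial-level GLM regressors and their embedding on the scan sampling grid.

An outcome event occurs once per inter-stimulus interval (default 14 s) and
the signal is sampled every ``dt`` (default 2 s); trial t's event amplitude
sits at sample t * (isi/dt) and every other sample is exactly zero.  The main
parametric modulator is a model-side RPE series (fixed analysis learning rate,
lambda fixed at 1).  Two derivative constructions capture the learning-curve
shape variance that a mis-specified learning rate leaves behind:

* gradient method -- numerical gradient of the trial-level RPE values
  (central differences, one-sided at the ends), computed on trial values and
  then embedded;
* high/low method -- mean and (orthogonalized) difference of the RPE series
  generated with a high (0.7) and a low (0.2) learning rate.

All regressors are z-normalized (population SD) before entering a GLM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rl_core import RWParams, simulate_pavlovian

__all__ = [
    "SamplingGrid",
    "embed_events",
    "model_rpe_trial_values",
    "gradient_derivative",
    "residualize",
    "highlow_regressors",
    "win_regressor",
    "znormalize",
    "perturb_alpha",
]


@dataclass(frozen=True)
class SamplingGrid:
    """Regular sampling grid: dt seconds per sample, isi seconds per trial."""

    n_trials: int
    dt: float = 2.0
    isi: float = 14.0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        ratio = self.isi / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("isi must be divisible by dt")

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.isi / self.dt))

    @property
    def n_samples(self) -> int:
        return self.n_trials * self.samples_per_trial

    @property
    def event_indices(self) -> np.ndarray:
        return np.arange(self.n_trials) * self.samples_per_trial


def embed_events(trial_values, grid: SamplingGrid) -> np.ndarray:
    """Place per-trial amplitudes at their event samples; zero elsewhere."""
    trial_values = np.asarray(trial_values, dtype=float)
    if trial_values.shape != (grid.n_trials,):
        raise ValueError(
            f"expected {grid.n_trials} trial values, got shape {trial_values.shape}"
        )
    ts = np.zeros(grid.n_samples)
    ts[grid.event_indices] = trial_values
    return ts


def model_rpe_trial_values(
    outcomes, alpha_model: float, lam_model: float = 1.0, q0: float = 0.5
) -> np.ndarray:
    """Analysis-side RPE series for a fixed (or estimated) learning rate."""
    params = RWParams(alpha=alpha_model, lam=lam_model, q0=q0)
    return simulate_pavlovian(outcomes, params).rpes


def gradient_derivative(trial_values) -> np.ndarray:
    """Numerical gradient over trials: central differences in the interior,
    one-sided at the ends (unit trial spacing)."""
    trial_values = np.asarray(trial_values, dtype=float)
    if trial_values.size < 2:
        raise ValueError("need at least 2 trial values for a gradient")
    return np.gradient(trial_values)


def residualize(target: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares residual of target on [1, reference]."""
    X = np.column_stack([np.ones_like(reference), reference])
    beta, *_ = np.linalg.lstsq(X, target, rcond=None)
    return target - X @ beta


def highlow_regressors(
    outcomes,
    grid: SamplingGrid,
    alpha_hi: float = 0.7,
    alpha_lo: float = 0.2,
    q0: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and orthogonalized-difference regressors, on the sampling grid.

    mean = (rpe(alpha_hi) + rpe(alpha_lo)) / 2 and
    diff = rpe(alpha_hi) - rpe(alpha_lo); the difference is residualized on
    the mean (with intercept) at the embedded-timeseries level, so the
    returned difference has exactly zero sample correlation with the mean.
    """
    hi = model_rpe_trial_values(outcomes, alpha_hi, q0=q0)
    lo = model_rpe_trial_values(outcomes, alpha_lo, q0=q0)
    mean_ts = embed_events((hi + lo) / 2.0, grid)
    diff_ts = embed_events(hi - lo, grid)
    if np.ptp(mean_ts) == 0:
        raise ValueError("degenerate (constant) mean series")
    return mean_ts, residualize(diff_ts, mean_ts)


def win_regressor(outcomes) -> np.ndarray:
    """Win / no-win trial values (the outcomes themselves, as floats)."""
    return np.asarray(outcomes, dtype=float).copy()


def znormalize(timeseries) -> np.ndarray:
    """Zero mean, unit population (1/N) standard deviation."""
    ts = np.asarray(timeseries, dtype=float)
    sd = ts.std()
    if sd == 0:
        raise ValueError("cannot normalize a zero-variance series")
    return (ts - ts.mean()) / sd


def perturb_alpha(
    alpha_true: float, error_halfwidth: float, rng: np.random.Generator
) -> float:
    """Individually estimated learning rate: truth plus U(-e, +e), clipped to (0, 1]."""
    est = alpha_true + rng.uniform(-error_halfwidth, error_halfwidth)
    return float(min(1.0, max(1e-6, est)))
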