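"""End-to-end simulation campaigns.

Each campaign simulates a population of agents with individually varying
generative parameters, fits a subject-level GLM per simulated participant, and
runs the group-level battery relating fitted betas to the parameters that
generated the data:

* ``basic_*`` -- noiseless, unconvolved RPE event series analyzed by OLS with
  a single (fixed- or estimated-alpha) RPE regressor: shows that the RPE beta
  tracks reinforcement efficacy (lambda) far more than learning rate (alpha).
* ``derivative_*`` -- adds the derivative regressor (gradient or high/low
  construction, optionally a win/no-win regressor): the derivative beta picks
  up alpha specifically, the RPE beta stays lambda-dominated.
* ``fmri_*`` -- HRF-convolved signal mixed with 1/f^a noise, AR(2)-error ML
  fits, correlation/effect-size/dependent-z battery across task durations,
  optionally with per-subject HRF amplitude variation and partial correlations.
* ``test_retest`` -- two independent 100-trial blocks per participant with
  identical parameters; ICC(3,1) of each beta across blocks.
* ``bic_comparison`` -- per-subject BIC for RPE-only vs RPE+derivative models
  and the logistic regression of when the fuller model wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bold_sim import canonical_hrf, convolve_hrf, simulate_bold_run
from .design_regressors import (
    SamplingGrid,
    embed_events,
    gradient_derivative,
    highlow_regressors,
    model_rpe_trial_values,
    perturb_alpha,
    win_regressor,
)
from .glm_fit import DesignMatrix, ar2_fit, compare_bic, ols_fit
from .group_stats import (
    bic_preference_logistic,
    compare_dependent_correlations,
    correlations,
    d_from_r,
    icc_3_1,
    regress_betas,
)
from .paradigms import (
    ParameterRanges,
    ParticipantSpec,
    Schedule,
    make_schedule,
    participant_rng,
    sample_participants,
)
from .rl_core import RWParams, SoftmaxParams, simulate_instrumental, simulate_pavlovian

logger = logging.getLogger(__name__)

__all__ = [
    "CampaignConfig",
    "run_basic",
    "run_derivative",
    "run_fmri",
    "run_test_retest",
    "run_bic_comparison",
    "make_fig1_fixture",
    "run_campaign",
]

CAMPAIGNS = (
    "basic_pavlovian",
    "basic_instrumental",
    "derivative_gradient",
    "derivative_highlow",
    "derivative_plus_outcome",
    "fmri_durations",
    "fmri_hrf_scaling",
    "test_retest",
    "bic_comparison",
)


@dataclass(frozen=True)
class CampaignConfig:
    """Configuration of one simulation campaign."""

    campaign: str
    n_participants: int = 5000
    n_trials: int = 200
    durations: tuple[int, ...] = (25, 50, 100, 200, 400)
    alpha_model: float = 0.45
    estimation_error: float | None = None  # None = fixed alpha_model
    master_seed: int = 0
    ranges: ParameterRanges = field(default_factory=ParameterRanges)
    dt: float = 2.0
    isi: float = 14.0

    def __post_init__(self) -> None:
        if self.campaign not in CAMPAIGNS:
            raise ValueError(f"unknown campaign {self.campaign!r}")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")


def _varying(table: pd.DataFrame, predictors: list[str]) -> list[str]:
    """Drop degenerate (zero-variance) predictors from a group regression."""
    kept = [p for p in predictors if table[p].nunique() > 1]
    for p in set(predictors) - set(kept):
        logger.info("dropping constant predictor %r from group regression", p)
    return kept


def _grid(config: CampaignConfig, n_trials: int | None = None) -> SamplingGrid:
    return SamplingGrid(
        n_trials=n_trials or config.n_trials, dt=config.dt, isi=config.isi
    )


def _spec_row(spec: ParticipantSpec) -> dict:
    return {
        "alpha": spec.alpha,
        "lam": spec.lam,
        "drift": spec.drift,
        "theta": spec.theta,
        "snr": spec.snr,
        "noise_exponent": spec.noise_exponent,
        "hrf_scale": spec.hrf_scale,
    }


def _alpha_model_for(
    spec: ParticipantSpec, config: CampaignConfig, rng: np.random.Generator
) -> float:
    if config.estimation_error is None:
        return config.alpha_model
    return perturb_alpha(spec.alpha, config.estimation_error, rng)


def _agent_outcomes(
    spec: ParticipantSpec, config: CampaignConfig, rng: np.random.Generator
):
    """Simulate the agent; return (realized outcome sequence, true RPEs)."""
    instrumental = config.campaign == "basic_instrumental"
    schedule = make_schedule(
        spec.n_trials, spec.drift, n_options=2 if instrumental else 1, rng=rng
    )
    params = RWParams(alpha=spec.alpha, lam=spec.lam)
    if instrumental:
        trace = simulate_instrumental(schedule, params, SoftmaxParams(spec.theta), rng)
    else:
        trace = simulate_pavlovian(schedule.outcomes[:, 0], params)
    return trace.outcomes, trace.rpes


def run_basic(config: CampaignConfig) -> dict:
    """Noiseless single-regressor campaign (Pavlovian or instrumental)."""
    if config.campaign not in ("basic_pavlovian", "basic_instrumental"):
        raise ValueError("run_basic requires a basic_* campaign")
    grid = _grid(config)
    specs = sample_participants(
        config.n_participants, config.ranges, config.master_seed, config.n_trials
    )
    rows = []
    for spec in specs:
        rng = participant_rng(spec, stream=0)
        outcomes, true_rpes = _agent_outcomes(spec, config, rng)
        y = embed_events(true_rpes, grid)
        a_model = _alpha_model_for(spec, config, participant_rng(spec, stream=2))
        x = embed_events(model_rpe_trial_values(outcomes, a_model), grid)
        fit = ols_fit(y, DesignMatrix.build({"rpe": x}))
        rows.append(_spec_row(spec) | {"beta_rpe": fit.beta("rpe")})
    table = pd.DataFrame(rows)
    predictors = ["lam", "alpha", "drift"]
    if config.campaign == "basic_instrumental":
        predictors.append("theta")
    predictors = _varying(table, predictors)
    return {"table": table, "group": {"rpe": regress_betas(table, "beta_rpe", predictors)}}


def _derivative_design(
    outcomes, grid: SamplingGrid, config: CampaignConfig
) -> DesignMatrix:
    if config.campaign == "derivative_highlow":
        mean_ts, diff_ts = highlow_regressors(outcomes, grid)
        return DesignMatrix.build({"rpe": mean_ts, "deriv": diff_ts})
    tv = model_rpe_trial_values(outcomes, config.alpha_model)
    cols = {
        "rpe": embed_events(tv, grid),
        "deriv": embed_events(gradient_derivative(tv), grid),
    }
    if config.campaign == "derivative_plus_outcome":
        cols["outcome"] = embed_events(win_regressor(outcomes), grid)
    return DesignMatrix.build(cols)


def run_derivative(config: CampaignConfig) -> dict:
    """Noiseless campaign with RPE + derivative (and optional outcome) regressors."""
    if config.campaign not in (
        "derivative_gradient",
        "derivative_highlow",
        "derivative_plus_outcome",
    ):
        raise ValueError("run_derivative requires a derivative_* campaign")
    grid = _grid(config)
    specs = sample_participants(
        config.n_participants, config.ranges, config.master_seed, config.n_trials
    )
    rows = []
    for spec in specs:
        rng = participant_rng(spec, stream=0)
        schedule = make_schedule(spec.n_trials, spec.drift, rng=rng)
        outcomes = schedule.outcomes[:, 0]
        trace = simulate_pavlovian(outcomes, RWParams(alpha=spec.alpha, lam=spec.lam))
        y = embed_events(trace.rpes, grid)
        design = _derivative_design(outcomes, grid, config)
        fit = ols_fit(y, design)
        row = _spec_row(spec) | {
            "beta_rpe": fit.beta("rpe"),
            "beta_deriv": fit.beta("deriv"),
        }
        if config.campaign == "derivative_plus_outcome":
            row["beta_outcome"] = fit.beta("outcome")
        rows.append(row)
    table = pd.DataFrame(rows)
    predictors = ["lam", "alpha", "drift"]
    group = {
        name: regress_betas(table, f"beta_{name}", predictors)
        for name in ("rpe", "deriv")
    }
    if config.campaign == "derivative_plus_outcome":
        group["outcome"] = regress_betas(table, "beta_outcome", predictors)
    return {"table": table, "group": group}


def fmri_design(outcomes, grid: SamplingGrid, alpha_model: float = 0.45) -> DesignMatrix:
    """RPE + gradient-derivative regressors, HRF-convolved then normalized,
    plus a standardized linear trend (analysis-side kernel at scale 1)."""
    kernel = canonical_hrf(grid.dt)
    tv = model_rpe_trial_values(outcomes, alpha_model)
    return DesignMatrix.build(
        {
            "rpe": convolve_hrf(embed_events(tv, grid), kernel),
            "deriv": convolve_hrf(embed_events(gradient_derivative(tv), grid), kernel),
        },
        add_trend=True,
    )


def _fit_fmri_participant(
    spec: ParticipantSpec,
    config: CampaignConfig,
    grid: SamplingGrid,
    reduced: bool = False,
    schedule_rng: np.random.Generator | None = None,
    noise_rng: np.random.Generator | None = None,
) -> dict:
    """One participant's noisy BOLD run and AR(2) fit(s)."""
    rng_s = schedule_rng or participant_rng(spec, stream=0)
    schedule = make_schedule(grid.n_trials, spec.drift, rng=rng_s)
    bold = simulate_bold_run(spec, schedule, grid, rng=noise_rng)
    design = fmri_design(schedule.outcomes[:, 0], grid, config.alpha_model)
    fit_full = ar2_fit(bold.values, design)
    out = {
        "beta_rpe": fit_full.beta("rpe"),
        "beta_deriv": fit_full.beta("deriv"),
        "bic_full": fit_full.bic,
        "converged": fit_full.converged,
    }
    if reduced:
        fit_red = ar2_fit(bold.values, design.drop("deriv"))
        out["beta_rpe_noderiv"] = fit_red.beta("rpe")
        out["bic_reduced"] = fit_red.bic
        out["prefers_full"] = compare_bic(fit_red, fit_full)["prefers_full"]
        out["converged"] = out["converged"] and fit_red.converged
    return out


def _drop_nonconverged(table: pd.DataFrame, context: str) -> pd.DataFrame:
    bad = int((~table["converged"]).sum())
    if bad:
        logger.info("%s: excluding %d non-converged fits", context, bad)
    return table[table["converged"]].reset_index(drop=True)


def _fmri_group_stats(table: pd.DataFrame, partial_hrf: bool) -> dict:
    """Correlation / effect-size / dependent-z battery for one duration cell."""
    r = {
        ("lam", "rpe"): correlations(table, "lam", "beta_rpe"),
        ("alpha", "rpe"): correlations(table, "alpha", "beta_rpe"),
        ("lam", "deriv"): correlations(table, "lam", "beta_deriv"),
        ("alpha", "deriv"): correlations(table, "alpha", "beta_deriv"),
    }
    r_param = correlations(table, "lam", "alpha")
    n = len(table)
    z_rpe, _ = compare_dependent_correlations(
        r[("lam", "rpe")], r[("alpha", "rpe")], r_param, n
    )
    z_deriv, _ = compare_dependent_correlations(
        r[("alpha", "deriv")], r[("lam", "deriv")], r_param, n
    )
    out = {
        "n": n,
        "r": {f"{p}_{b}": v for (p, b), v in r.items()},
        "d": {
            "lam_rpe": d_from_r(r[("lam", "rpe")]),
            "alpha_deriv": d_from_r(r[("alpha", "deriv")]),
        },
        "z": {"lam_vs_alpha_rpe": z_rpe, "alpha_vs_lam_deriv": z_deriv},
        "group": {
            name: regress_betas(
                table,
                f"beta_{name}",
                ["lam", "alpha", "drift", "snr", "noise_exponent"],
            )
            for name in ("rpe", "deriv")
        },
    }
    if partial_hrf:
        out["partial_r"] = {
            "lam_rpe": correlations(table, "lam", "beta_rpe", ["hrf_scale"]),
            "alpha_deriv": correlations(table, "alpha", "beta_deriv", ["hrf_scale"]),
        }
    return out


def run_fmri(config: CampaignConfig) -> dict:
    """fMRI-like campaign across task durations; returns per-duration results."""
    if config.campaign not in ("fmri_durations", "fmri_hrf_scaling"):
        raise ValueError("run_fmri requires an fmri_* campaign")
    ranges = config.ranges
    if config.campaign == "fmri_hrf_scaling":
        ranges = ranges.with_varying_hrf()
    results = {}
    for duration in config.durations:
        grid = _grid(config, duration)
        specs = sample_participants(
            config.n_participants, ranges, (config.master_seed, duration), duration
        )
        rows = [
            _spec_row(spec) | _fit_fmri_participant(spec, config, grid)
            for spec in specs
        ]
        table = _drop_nonconverged(pd.DataFrame(rows), f"fmri duration={duration}")
        results[duration] = {
            "table": table,
            "stats": _fmri_group_stats(
                table, partial_hrf=config.campaign == "fmri_hrf_scaling"
            ),
        }
        logger.info("fmri duration=%d done (n=%d)", duration, len(table))
    return results


def run_test_retest(config: CampaignConfig) -> dict:
    """Two independent blocks with identical per-participant parameters;
    ICC(3,1) of each beta across blocks (and of the RPE beta refit without
    the derivative regressor)."""
    if config.campaign != "test_retest":
        raise ValueError("run_test_retest requires campaign='test_retest'")
    grid = _grid(config)
    specs = sample_participants(
        config.n_participants, config.ranges, config.master_seed, config.n_trials
    )
    rows = []
    for spec in specs:
        row = _spec_row(spec)
        ok = True
        for block in (1, 2):
            fit = _fit_fmri_participant(
                spec,
                config,
                grid,
                reduced=True,
                schedule_rng=participant_rng(spec, stream=2 * (block - 1)),
                noise_rng=participant_rng(spec, stream=2 * (block - 1) + 1),
            )
            ok = ok and fit["converged"]
            row.update(
                {
                    f"beta_rpe_b{block}": fit["beta_rpe"],
                    f"beta_deriv_b{block}": fit["beta_deriv"],
                    f"beta_rpe_noderiv_b{block}": fit["beta_rpe_noderiv"],
                }
            )
        row["converged"] = ok
        rows.append(row)
    table = _drop_nonconverged(pd.DataFrame(rows), "test_retest")
    iccs = {
        name: icc_3_1(table[[f"{name}_b1", f"{name}_b2"]].to_numpy())
        for name in ("beta_rpe", "beta_deriv", "beta_rpe_noderiv")
    }
    return {"table": table, "icc": iccs}


def run_bic_comparison(config: CampaignConfig) -> dict:
    """Per-duration BIC preference rates for the RPE+derivative model, plus
    the logistic regression of preference on the generative parameters."""
    if config.campaign != "bic_comparison":
        raise ValueError("run_bic_comparison requires campaign='bic_comparison'")
    ranges = config.ranges.with_varying_hrf()
    results = {}
    for duration in config.durations:
        grid = _grid(config, duration)
        specs = sample_participants(
            config.n_participants, ranges, (config.master_seed, duration), duration
        )
        rows = [
            _spec_row(spec)
            | _fit_fmri_participant(spec, config, grid, reduced=True)
            for spec in specs
        ]
        table = _drop_nonconverged(pd.DataFrame(rows), f"bic duration={duration}")
        res = {
            "table": table,
            "preference_rate": float(table["prefers_full"].mean()),
        }
        if table["prefers_full"].nunique() > 1:
            res["logistic"] = bic_preference_logistic(table)
        results[duration] = res
        logger.info(
            "bic duration=%d: %.2f%% prefer the fuller model",
            duration,
            100 * res["preference_rate"],
        )
    return results


def make_fig1_fixture() -> dict[str, pd.DataFrame]:
    """Toy 20-trial sequence (9 non-rewards then 11 rewards) illustrating the
    derivative construction: RPE trajectories for slow/intermediate/fast
    learning rates, the gradient of the intermediate one, and the +/-
    derivative reconstructions of the fast/slow trajectories."""
    outcomes = np.concatenate([np.zeros(9), np.ones(11)])
    rpes = {
        a: model_rpe_trial_values(outcomes, a, lam_model=1.0, q0=0.5)
        for a in (0.2, 0.45, 0.7)
    }
    deriv = gradient_derivative(rpes[0.45])
    trajectories = pd.DataFrame(
        {
            "trial": np.arange(1, 21),
            "outcome": outcomes.astype(int),
            "rpe_alpha_0.2": rpes[0.2],
            "rpe_alpha_0.45": rpes[0.45],
            "rpe_alpha_0.7": rpes[0.7],
            "gradient_0.45": deriv,
        }
    )
    reconstructions = pd.DataFrame(
        {
            "trial": np.arange(1, 21),
            "rpe_plus_gradient": rpes[0.45] + deriv,
            "rpe_minus_gradient": rpes[0.45] - deriv,
            "rpe_alpha_0.7": rpes[0.7],
            "rpe_alpha_0.2": rpes[0.2],
        }
    )
    return {"trajectories": trajectories, "reconstructions": reconstructions}


_RUNNERS = {
    "basic_pavlovian": run_basic,
    "basic_instrumental": run_basic,
    "derivative_gradient": run_derivative,
    "derivative_highlow": run_derivative,
    "derivative_plus_outcome": run_derivative,
    "fmri_durations": run_fmri,
    "fmri_hrf_scaling": run_fmri,
    "test_retest": run_test_retest,
    "bic_comparison": run_bic_comparison,
}


def run_campaign(config: CampaignConfig) -> dict:
    """Dispatch a campaign to its runner."""
    return _RUNNERS[config.campaign](config)
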