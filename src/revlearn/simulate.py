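"""Simulated agents, cohorts, and regressor-modulated oscillatory series.

Every downstream stage of the pipeline (model inversion, behavioural
statistics, convolution GLM, cluster tests) is exercisable on data produced
here.  Agents behave according to the binary HGF plus one of the three
response models; cohorts emulate a two-group design in which the "high"
group holds a larger initial expectation on log-volatility (mu3_0), which
through the volatility coupling produces faster belief updating and more
stochastic, switch-prone choices.  Synthetic neural series are band-limited
oscillations whose trial-wise envelope is scaled by known regressor values,
so deconvolution can be validated against ground truth.

Randomness: a single seed fans out to per-subject / per-stage streams via
``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hgf import (
    REGRESSOR_ALIGNMENT,
    AgentParams,
    BeliefTrajectory,
    hgf_filter,
    trajectory_regressors,
)
from .responses import MODELS, choice_probabilities
from .task import TaskSchedule, generate_schedule

__all__ = [
    "simulate_agent",
    "CohortSpec",
    "generate_cohort",
    "SyntheticNeuralSpec",
    "generate_neural",
]


def simulate_agent(
    params: AgentParams,
    schedule: TaskSchedule,
    model: str = "hgf3_mu3",
    seed: int | None = None,
    no_response_rate: float = 0.0,
):
    """Simulate one agent on a schedule.

    Outcomes ``u`` are Bernoulli draws from the schedule's true contingency;
    beliefs are filtered forward; responses ``y`` are Bernoulli draws from the
    response model's choice probability.  ``no_response_rate`` injects
    timeouts (y = NaN, outcome "none") at the given rate.

    Returns
    -------
    trials : DataFrame with columns trial, u, y, outcome, p_true, block_id and
        the event onset columns.
    traj : BeliefTrajectory of the simulated agent.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    rng = np.random.default_rng(seed)
    n = schedule.n_trials
    u = (rng.random(n) < schedule.p_true).astype(float)
    levels = 2 if model == "hgf2" else 3
    traj = hgf_filter(u, params, levels=levels)
    zeta = None if model == "hgf3_mu3" else params.zeta
    cp = choice_probabilities(traj, model, zeta=zeta)
    y = (rng.random(n) < cp.p_y1).astype(float)
    if no_response_rate > 0:
        y[rng.random(n) < no_response_rate] = np.nan
    outcome = np.where(np.isnan(y), "none", np.where(y == u, "win", "lose"))
    trials = pd.DataFrame(
        {
            "trial": np.arange(n),
            "u": u,
            "y": y,
            "outcome": outcome,
            "p_true": schedule.p_true,
            "block_id": schedule.block_id,
        }
    )
    trials = pd.concat([trials, schedule.onsets.reset_index(drop=True)], axis=1)
    return trials, traj


def _default_group_means():
    # "high" group: larger initial expectation on log-volatility; everything
    # else shared.  Through the exp(kappa*mu3 + omega2) coupling this yields
    # faster updating, larger sigma2/environmental uncertainty, and noisier
    # choices (zeta_k = exp(-mu3)) in the high group.
    return {
        "low": {"omega2": -3.0, "omega3": -6.0, "mu3_0": 0.0, "sigma3_0": 1.0},
        "high": {"omega2": -3.0, "omega3": -6.0, "mu3_0": 1.0, "sigma3_0": 1.0},
    }


def _default_group_sds():
    shared = {"omega2": 0.3, "omega3": 0.5, "mu3_0": 0.25, "sigma3_0": 0.0}
    return {"low": dict(shared), "high": dict(shared)}


@dataclass
class CohortSpec:
    """Two-group synthetic cohort specification.

    ``group_means``/``group_sds`` give, per labelled group, the normal
    distribution of each free generative parameter.  Both groups share the
    schedule-generation procedure; each subject gets an independent schedule.
    """

    n_per_group: dict = field(default_factory=lambda: {"low": 20, "high": 19})
    group_means: dict = field(default_factory=_default_group_means)
    group_sds: dict = field(default_factory=_default_group_sds)
    model: str = "hgf3_mu3"
    zeta: float | None = None  # only for fixed-noise generative models
    blocks: int = 2
    trials_per_block: int = 160
    no_response_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for g in self.group_sds.values():
            if any(s < 0 for s in g.values()):
                raise ValueError("parameter spreads must be non-negative")


@dataclass
class Subject:
    """One simulated participant."""

    group: str
    params: AgentParams
    schedule: TaskSchedule
    trials: pd.DataFrame
    trajectory: BeliefTrajectory


def generate_cohort(spec: CohortSpec) -> list[Subject]:
    """Simulate an independent schedule and session per subject."""
    root = np.random.SeedSequence(spec.seed)
    subjects = []
    groups = sorted(spec.n_per_group)
    streams = root.spawn(sum(spec.n_per_group[g] for g in groups))
    i = 0
    for group in groups:
        means, sds = spec.group_means[group], spec.group_sds[group]
        for _ in range(spec.n_per_group[group]):
            ss = streams[i]
            i += 1
            rng = np.random.default_rng(ss)
            draws = {k: rng.normal(means[k], sds[k]) for k in means}
            if "sigma3_0" in draws:
                draws["sigma3_0"] = max(draws["sigma3_0"], 1e-3)
            params = AgentParams(zeta=spec.zeta, **draws)
            sched_seed, sim_seed = [int(s.generate_state(1)[0] % 2**31)
                                    for s in ss.spawn(2)]
            schedule = generate_schedule(spec.blocks, spec.trials_per_block, sched_seed)
            trials, traj = simulate_agent(
                params, schedule, spec.model, sim_seed, spec.no_response_rate
            )
            subjects.append(Subject(group, params, schedule, trials, traj))
    return subjects


@dataclass
class SyntheticNeuralSpec:
    """Specification of regressor-modulated oscillatory source activity.

    Each carrier is a fixed-frequency oscillation emitted around events of one
    type; its envelope is a smooth impulse response (Hann window of
    ``duration_s`` starting ``latency_s`` after the event) scaled by
    ``1 + sum_r gain_r * z_r`` where z_r are the trial's regressor values.
    White Gaussian noise of ``noise_sd`` is added to the series.
    """

    sampling_rate: float = 250.0
    carriers: list = field(
        default_factory=lambda: [
            {
                "freq": 75.0,
                "event_type": "outcome",
                "base_amplitude": 1.0,
                "gains": {"abs_eps2": 0.5},
                "latency_s": 0.3,
                "duration_s": 0.4,
            }
        ]
    )
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        fmax = max(c["freq"] for c in self.carriers)
        if self.sampling_rate <= 2 * fmax:
            raise ValueError("sampling rate must exceed twice the highest carrier")
        for c in self.carriers:
            if not all(np.isfinite(list(c["gains"].values()) or [0.0])):
                raise ValueError("gains must be finite")


def _hann_envelope(t, latency, duration):
    """Hann impulse-response shape over peri-event time ``t`` (seconds)."""
    tau = (np.asarray(t) - latency) / duration
    inside = (tau >= 0) & (tau <= 1)
    env = np.zeros_like(np.asarray(t, dtype=float))
    env[inside] = 0.5 * (1 - np.cos(2 * np.pi * tau[inside]))
    return env


def build_event_table(trials: pd.DataFrame, traj: BeliefTrajectory) -> pd.DataFrame:
    """Discrete and parametric event streams for one session.

    Discrete events: outcome_win / outcome_lose / outcome_none at the outcome
    onset, stimulus at the stimulus onset (value 1).  Parametric events place
    each regressor's trial value at its aligned onset (outcome for abs_eps2,
    sigma2, sigma3, eps3; stimulus for abs_mu2hat).
    """
    regs = trajectory_regressors(traj)
    rows = []
    for k in range(len(trials)):
        t_out = trials["onset_outcome_s"].iloc[k]
        t_stim = trials["onset_stimulus_s"].iloc[k]
        rows.append((t_stim, "stimulus", 1.0))
        rows.append((t_out, f"outcome_{trials['outcome'].iloc[k]}", 1.0))
        for name, align in REGRESSOR_ALIGNMENT.items():
            val = regs[name].iloc[k]
            if np.isnan(val):
                continue
            onset = t_out if align == "outcome" else t_stim
            rows.append((onset, name, float(val)))
    return pd.DataFrame(rows, columns=["onset_s", "type", "value"]).sort_values(
        "onset_s", kind="stable", ignore_index=True
    )


def generate_neural(
    trials: pd.DataFrame,
    traj: BeliefTrajectory,
    spec: SyntheticNeuralSpec,
    duration_s: float | None = None,
):
    """Synthesize a continuous series with known event-locked responses.

    Returns
    -------
    series : 1-D array at ``spec.sampling_rate``.
    events : EventTable DataFrame (onset_s, type, value).
    truth : dict mapping regressor (or discrete event type) to a dict with the
        injected peri-event envelope in signal-amplitude units per unit
        regressor value, its time axis and carrier frequency — the ground
        truth against which deconvolution is checked.
    """
    if len(trials) != traj.n_trials:
        raise ValueError("trials and trajectory are not aligned")
    events = build_event_table(trials, traj)
    sr = spec.sampling_rate
    end_needed = float(trials["onset_outcome_s"].max()) + 2.5
    if duration_s is None:
        duration_s = end_needed
    if events["onset_s"].max() >= duration_s:
        raise ValueError("event onsets fall outside the series duration")
    n = int(round(duration_s * sr))
    t = np.arange(n) / sr
    rng = np.random.default_rng(spec.seed)
    series = (
        rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else np.zeros(n)
    )
    regs = trajectory_regressors(traj)
    truth = {}
    for c in spec.carriers:
        onset_col = (
            "onset_outcome_s" if c["event_type"] == "outcome" else "onset_stimulus_s"
        )
        peri = np.arange(0.0, c["latency_s"] + c["duration_s"] + 1.0 / sr, 1.0 / sr)
        shape = _hann_envelope(peri, c["latency_s"], c["duration_s"])
        for k in range(len(trials)):
            onset = trials[onset_col].iloc[k]
            gain_term = 1.0
            for rname, g in c["gains"].items():
                val = regs[rname].iloc[k]
                if not np.isnan(val):
                    gain_term += g * val
            amp = c["base_amplitude"] * gain_term
            i0 = int(round(onset * sr))
            i1 = min(i0 + len(peri), n)
            seg = t[i0:i1]
            series[i0:i1] += (
                amp * shape[: i1 - i0] * np.cos(2 * np.pi * c["freq"] * seg)
            )
        truth[f"discrete_{c['event_type']}"] = {
            "times": peri,
            "envelope": c["base_amplitude"] * shape,
            "freq": c["freq"],
        }
        for rname, g in c["gains"].items():
            truth[rname] = {
                "times": peri,
                "envelope": c["base_amplitude"] * g * shape,
                "freq": c["freq"],
            }
    return series, events, truth
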