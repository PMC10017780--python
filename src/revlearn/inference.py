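"""Model inversion helpers: MAP fitting, parameter recovery, and
random-effects Bayesian model selection (BMS).

``fit_map`` is a thin functional wrapper over :class:`HGFEstimator`.  ``bms``
implements the variational random-effects scheme in which models are treated
as random effects in the population: per-subject posterior model
probabilities and a Dirichlet posterior over model frequencies are updated
until convergence, yielding expected frequencies and (Monte-Carlo) exceedance
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma

from .estimators import FitResult, HGFEstimator, PriorSpec, default_priors
from .hgf import AgentParams, InvalidTrajectoryError
from .simulate import simulate_agent
from .task import generate_schedule

__all__ = ["fit_map", "recovery_study", "bms", "BMSResult"]


def fit_map(
    trials,
    model: str = "hgf3_mu3",
    priors: PriorSpec | None = None,
    seed: int = 0,
    n_restarts: int = 8,
) -> FitResult:
    """MAP-fit one model to a trial table (columns ``u`` and ``y``)."""
    est = HGFEstimator(
        model=model, priors=priors, n_restarts=n_restarts, random_state=seed
    )
    est.fit(trials)
    return est.result_


#: default distributions of generating parameters for recovery simulations
DEFAULT_RECOVERY_GRID = {
    "omega2": (-3.0, 1.0),
    "omega3": (-6.0, 1.0),
    "mu3_0": (1.0, 0.5),
}


def recovery_study(
    model: str = "hgf3_mu3",
    param_grid: dict | None = None,
    n_reps: int = 50,
    seed: int = 0,
    blocks: int = 2,
    trials_per_block: int = 160,
    n_restarts: int = 4,
    zeta: float | None = None,
):
    """Simulate-and-refit study of parameter recoverability.

    Draws generating parameters from normal distributions given as
    ``{name: (mean, sd)}``, simulates one session per replicate, refits the
    same model, and tabulates per-parameter bias, RMSE and (for n_reps > 1)
    the Pearson correlation between true and recovered values.

    Returns
    -------
    summary : DataFrame indexed by parameter with columns bias, rmse and
        correlation (correlation absent for a single replicate).
    draws : DataFrame of true and recovered values per replicate.
    """
    grid = dict(DEFAULT_RECOVERY_GRID if param_grid is None else param_grid)
    root = np.random.SeedSequence(seed)
    rows = []
    for rep, ss in enumerate(root.spawn(n_reps)):
        rng = np.random.default_rng(ss)
        s1, s2, s3 = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3)]
        schedule = generate_schedule(blocks, trials_per_block, s1)
        # reject generating draws whose trajectories are invalid (an
        # experimenter only ever fits realisable behaviour)
        for attempt in range(100):
            true = {k: float(rng.normal(m, s)) for k, (m, s) in grid.items()}
            params = AgentParams(zeta=zeta, **true)
            try:
                trials, _ = simulate_agent(params, schedule, model, s2)
                break
            except InvalidTrajectoryError:
                continue
        else:
            raise RuntimeError("could not draw a valid generating agent")
        fit = fit_map(trials, model, seed=s3, n_restarts=n_restarts)
        row = {"rep": rep}
        for k in grid:
            row[f"true_{k}"] = true[k]
            row[f"fit_{k}"] = getattr(fit.map_params, k)
        rows.append(row)
    draws = pd.DataFrame(rows)
    summary = {}
    for k in grid:
        err = draws[f"fit_{k}"] - draws[f"true_{k}"]
        entry = {"bias": err.mean(), "rmse": float(np.sqrt(np.mean(err**2)))}
        if n_reps > 1:
            entry["correlation"] = float(
                np.corrcoef(draws[f"true_{k}"], draws[f"fit_{k}"])[0, 1]
            )
        summary[k] = entry
    return pd.DataFrame(summary).T, draws


#: population distributions (mean, sd) of the generating parameters used in
#: model-selection experiments; centred near the default priors
DEFAULT_GENERATING_POPULATION = {
    "omega2": (-3.0, 0.3),
    "omega3": (-6.0, 0.5),
    "mu3_0": (1.0, 0.25),
}


def model_selection_experiment(
    n_subjects: int = 39,
    seed: int = 0,
    models=("hgf2", "hgf3", "hgf3_mu3"),
    generating_model: str = "hgf3_mu3",
    population: dict | None = None,
    n_restarts: int = 4,
    blocks: int = 2,
    trials_per_block: int = 160,
):
    """Simulate a cohort from one model, fit all candidates, and run BMS.

    Each subject gets an independent schedule and generative parameters drawn
    from ``population`` (``{name: (mean, sd)}``); all candidate models are
    MAP-fitted per subject and the resulting LME matrix is submitted to
    random-effects model selection.

    Returns
    -------
    lme : (n_subjects, n_models) array; result : BMSResult.
    """
    pop = dict(DEFAULT_GENERATING_POPULATION if population is None else population)
    root = np.random.SeedSequence(seed)
    lme = np.empty((n_subjects, len(models)))
    for i, ss in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(ss)
        true = {k: float(rng.normal(m, s)) for k, (m, s) in pop.items()}
        params = AgentParams(**true)
        s1, s2, s3 = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3)]
        schedule = generate_schedule(blocks, trials_per_block, s1)
        trials, _ = simulate_agent(params, schedule, generating_model, s2)
        for j, model in enumerate(models):
            lme[i, j] = fit_map(trials, model, seed=s3 + j, n_restarts=n_restarts).lme
    bms_seed = int(root.generate_state(1)[0] % 2**31)
    return lme, bms(lme, seed=bms_seed, model_names=list(models))


@dataclass
class BMSResult:
    """Random-effects model-selection posterior."""

    alpha: np.ndarray
    expected_freq: np.ndarray
    exceedance: np.ndarray
    n_subjects: int
    model_names: list | None = None


def bms(
    lme_matrix,
    alpha0: float = 1.0,
    n_samples: int = 10**6,
    seed: int = 0,
    model_names=None,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> BMSResult:
    """Random-effects Bayesian model selection from a subjects x models LME
    matrix.

    Variational update: per-subject posterior model probabilities
    g_nk proportional to exp(lme_nk + digamma(alpha_k) - digamma(sum alpha)),
    Dirichlet concentration alpha = alpha0 + sum_n g_n, iterated to
    convergence.  Exceedance probabilities are estimated by Monte-Carlo
    sampling of the Dirichlet posterior.  The result is invariant to adding a
    per-subject constant to the LMEs.
    """
    lme = np.asarray(lme_matrix, dtype=float)
    if lme.ndim != 2 or lme.shape[0] < 1 or lme.shape[1] < 2:
        raise ValueError("need a subjects x models matrix with >= 2 models")
    bad = np.argwhere(~np.isfinite(lme))
    if len(bad):
        s, m = bad[0]
        raise ValueError(f"non-finite log-model evidence for subject {s}, model {m}")
    n, k = lme.shape
    lme = lme - lme.max(axis=1, keepdims=True)  # per-subject shift invariance

    alpha = np.full(k, float(alpha0))
    for _ in range(max_iter):
        log_u = lme + digamma(alpha) - digamma(alpha.sum())
        log_u -= log_u.max(axis=1, keepdims=True)
        g = np.exp(log_u)
        g /= g.sum(axis=1, keepdims=True)
        new_alpha = alpha0 + g.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha

    expected = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    samples = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(samples, axis=1)
    exceedance = np.bincount(winners, minlength=k) / n_samples
    return BMSResult(
        alpha=alpha,
        expected_freq=expected,
        exceedance=exceedance,
        n_subjects=n,
        model_names=list(model_names) if model_names is not None else None,
    )
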