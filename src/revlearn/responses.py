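"""Response models mapping beliefs to choice probabilities.

Three candidate models share the unit-square sigmoid observation function

    p(y=1 | m, zeta) = m**zeta / (m**zeta + (1-m)**zeta)

where m is the predictive probability of outcome 1 and zeta > 0 is inverse
decision noise (the sigmoid tends to a step function as zeta -> inf).  The
two fixed-noise models (2- and 3-level HGF) estimate a constant zeta; the
volatility-coupled model sets the per-trial inverse decision noise to
exp(-mu3^(k-1)), so a higher predicted log-volatility makes choices more
stochastic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .hgf import BeliefTrajectory

__all__ = [
    "MODELS",
    "ChoiceProbability",
    "unit_square_sigmoid",
    "choice_probabilities",
    "log_likelihood",
]

#: candidate model identifiers
MODELS = ("hgf2", "hgf3", "hgf3_mu3")

_CLAMP = 1e-16


@dataclass
class ChoiceProbability:
    """Per-trial predictive probability, inverse decision noise and p(y=1)."""

    m: np.ndarray
    zeta_k: np.ndarray
    p_y1: np.ndarray


def unit_square_sigmoid(m, zeta):
    """Unit-square sigmoid p(y=1) = m^zeta / (m^zeta + (1-m)^zeta).

    Computed in log space for numerical stability.  Exact 0/1 inputs are
    clamped to the machine-eps interior with a warning.
    """
    m = np.asarray(m, dtype=float)
    if np.any((m <= 0) | (m >= 1)):
        warnings.warn("predictive probability clamped away from {0,1}")
        m = np.clip(m, _CLAMP, 1.0 - _CLAMP)
    zeta = np.asarray(zeta, dtype=float)
    if np.any(zeta <= 0):
        raise ValueError("zeta must be positive")
    # logit form: p = logistic(zeta * logit(m))
    logit_m = np.log(m) - np.log1p(-m)
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-zeta * logit_m))
    # keep strictly inside (0, 1) without flattening the tails
    return np.clip(p, 1e-300, np.nextafter(1.0, 0.0))


def choice_probabilities(
    traj: BeliefTrajectory, model: str, zeta: float | None = None
) -> ChoiceProbability:
    """Choice probabilities for a belief trajectory under a candidate model.

    For ``hgf2``/``hgf3``, ``zeta`` must be given and is constant across
    trials.  For ``hgf3_mu3``, ``zeta`` must be None; the per-trial inverse
    decision noise is exp(-mu3) of the *previous* trial, i.e. the prediction
    of log-volatility for the current trial.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    m = np.asarray(traj.mu1hat, dtype=float)
    if model == "hgf3_mu3":
        if zeta is not None:
            raise ValueError("hgf3_mu3 derives zeta from the volatility prediction")
        mu3_prev = np.concatenate([[traj.params.mu3_0], traj.mu3[:-1]])
        zeta_k = np.exp(-np.clip(mu3_prev, -500.0, 500.0))
    else:
        if zeta is None:
            raise ValueError(f"{model} requires a fixed zeta")
        zeta_k = np.full(len(m), float(zeta))
    return ChoiceProbability(m=m, zeta_k=zeta_k, p_y1=unit_square_sigmoid(m, zeta_k))


def log_likelihood(y, cp: ChoiceProbability) -> float:
    """Bernoulli log-likelihood of responses under the choice probabilities.

    ``y`` holds 0/1 responses with NaN marking missing responses, which
    contribute zero to the sum.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != len(cp.p_y1):
        raise ValueError("responses and choice probabilities differ in length")
    valid = ~np.isnan(y)
    p = np.clip(cp.p_y1[valid], _CLAMP, 1.0 - _CLAMP)
    yy = y[valid]
    return float(np.sum(yy * np.log(p) + (1.0 - yy) * np.log1p(-p)))
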