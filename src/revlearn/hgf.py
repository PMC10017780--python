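"""Binary Hierarchical Gaussian Filter (HGF) forward filtering.

The HGF models a learner tracking a binary outcome sequence ``u``.  Hidden
state x2 is the log-odds tendency of the outcome; x3 is the log-volatility of
x2.  Both evolve as Gaussian random walks coupled through their variances: the
step size of x2 on a given trial is exp(kappa * x3 + omega2), so a higher
volatility estimate inflates level-2 uncertainty and speeds learning.  Forward
filtering yields trial-wise posterior means/variances (mu_i, sigma_i),
prediction errors (delta_1, delta_2) and precision-weighted prediction errors
(eps_2, eps_3); these trajectories are the regressors and statistics used
downstream.

For binary outcomes the level-2 precision ratio reduces to sigma2 itself, so
eps2 = sigma2 * delta1 exactly.  A two-level variant freezes x3 at its initial
value (constant learning rate).

Missing inputs (timeouts) are marked by NaN in ``u``: the filter runs the
prediction step only and carries the posterior forward unchanged; prediction
errors on such trials are NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AgentParams",
    "BeliefTrajectory",
    "InvalidTrajectoryError",
    "hgf_filter",
    "trajectory_regressors",
    "REGRESSOR_ALIGNMENT",
]


class InvalidTrajectoryError(ValueError):
    """Raised when filtering produces a non-positive posterior precision."""

    def __init__(self, trial: int, message: str):
        self.trial = trial
        super().__init__(f"trial {trial}: {message}")


@dataclass
class AgentParams:
    """Parameters of the binary HGF and its response model.

    omega2/omega3 are tonic log-volatilities at levels 2/3 (lower values mean
    slower updating); kappa couples level 3 into level 2 (fixed at 1 unless
    stated otherwise); zeta is the inverse decision noise of the unit-square
    sigmoid response model (None for the volatility-coupled response model,
    where the per-trial inverse decision noise is exp(-mu3) instead).
    """

    omega2: float = -3.0
    omega3: float = -6.0
    kappa: float = 1.0
    zeta: float | None = None
    mu2_0: float = 0.0
    sigma2_0: float = 1.0
    mu3_0: float = 1.0
    sigma3_0: float = 1.0

    def __post_init__(self):
        if self.sigma2_0 <= 0 or self.sigma3_0 <= 0:
            raise ValueError("initial variances must be positive")
        if self.zeta is not None and self.zeta <= 0:
            raise ValueError("zeta must be positive when present")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")

    def updated(self, **kwargs) -> "AgentParams":
        return replace(self, **kwargs)


@dataclass
class BeliefTrajectory:
    """Trial-wise sufficient statistics of the filtered belief.

    All arrays have one entry per trial.  ``mu2hat`` is the prediction
    (previous trial's posterior mean); ``mu1hat = logistic(mu2hat)`` is the
    predictive probability of outcome 1; ``env_uncertainty`` is
    exp(kappa * mu3^(k-1) + omega2), the volatility-driven variance inflation
    of level-2 predictions.
    """

    mu1hat: np.ndarray
    da1: np.ndarray
    mu2: np.ndarray
    sigma2: np.ndarray
    mu2hat: np.ndarray
    eps2: np.ndarray
    da2: np.ndarray
    mu3: np.ndarray
    sigma3: np.ndarray
    eps3: np.ndarray
    env_uncertainty: np.ndarray
    params: AgentParams = field(repr=False)
    levels: int = 3

    @property
    def n_trials(self) -> int:
        return len(self.mu2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mu1hat": self.mu1hat,
                "da1": self.da1,
                "mu2": self.mu2,
                "sigma2": self.sigma2,
                "mu2hat": self.mu2hat,
                "eps2": self.eps2,
                "da2": self.da2,
                "mu3": self.mu3,
                "sigma3": self.sigma3,
                "eps3": self.eps3,
                "env_uncertainty": self.env_uncertainty,
            }
        )


def _logistic(x: float) -> float:
    if x >= 0:
        v = 1.0 / (1.0 + math.exp(-x))
    else:
        e = math.exp(x)
        v = e / (1.0 + e)
    # keep predictions strictly inside (0, 1) even when beliefs saturate
    return min(max(v, 1e-16), 1.0 - 1e-16)


def hgf_filter(u, params: AgentParams, levels: int = 3) -> BeliefTrajectory:
    """Filter a binary input sequence through the 2- or 3-level binary HGF.

    Parameters
    ----------
    u : sequence of 0/1 (NaN marks a missing input, passed through without a
        posterior update).
    params : generative parameters; ``kappa`` couples levels 2 and 3.
    levels : 2 freezes the third level at (mu3_0, sigma3_0).

    Returns
    -------
    BeliefTrajectory

    Raises
    ------
    InvalidTrajectoryError
        If the level-3 posterior precision becomes non-positive.
    """
    if levels not in (2, 3):
        raise ValueError("levels must be 2 or 3")
    u = np.asarray(u, dtype=float)
    n = len(u)
    ka, om2, om3 = params.kappa, params.omega2, params.omega3
    if om3 > 700.0:
        raise InvalidTrajectoryError(0, "level-3 step size overflow")

    mu2, sa2 = params.mu2_0, params.sigma2_0
    mu3, sa3 = params.mu3_0, params.sigma3_0

    out = {k: np.empty(n) for k in (
        "mu1hat", "da1", "mu2", "sigma2", "mu2hat", "eps2", "da2",
        "mu3", "sigma3", "eps3", "env_uncertainty")}

    for k in range(n):
        # prediction step
        muhat2 = mu2
        muhat1 = _logistic(muhat2)
        muhat3 = mu3
        arg = ka * mu3 + om2
        if not math.isfinite(arg) or arg > 700.0:
            raise InvalidTrajectoryError(k, "level-2 variance inflation overflow")
        v2 = math.exp(arg)                     # environmental uncertainty
        uk = u[k]

        out["mu2hat"][k] = muhat2
        out["mu1hat"][k] = muhat1
        out["env_uncertainty"][k] = v2

        if math.isnan(uk):
            # timeout: carry beliefs forward unchanged
            out["da1"][k] = out["eps2"][k] = out["da2"][k] = out["eps3"][k] = np.nan
            out["mu2"][k], out["sigma2"][k] = mu2, sa2
            out["mu3"][k], out["sigma3"][k] = mu3, sa3
            continue

        # level-2 update: predicted precision plus Bernoulli information
        sahat2 = sa2 + v2
        pihat2 = 1.0 / sahat2
        da1 = uk - muhat1
        pi2 = pihat2 + muhat1 * (1.0 - muhat1)
        if not pi2 > 0:
            raise InvalidTrajectoryError(k, "non-positive level-2 precision")
        new_sa2 = 1.0 / pi2
        eps2 = new_sa2 * da1
        new_mu2 = muhat2 + eps2

        if levels == 3:
            # volatility prediction error and level-3 update
            w2 = v2 * pihat2
            da2 = (new_sa2 + eps2 * eps2) * pihat2 - 1.0
            pihat3 = 1.0 / (sa3 + math.exp(om3))
            pi3 = pihat3 + 0.5 * ka * ka * w2 * (w2 + (2.0 * w2 - 1.0) * da2)
            if not pi3 > 0:
                raise InvalidTrajectoryError(k, "non-positive level-3 precision")
            new_sa3 = 1.0 / pi3
            eps3 = 0.5 * new_sa3 * ka * w2 * da2
            new_mu3 = muhat3 + eps3
        else:
            da2, eps3 = np.nan, np.nan
            new_mu3, new_sa3 = mu3, sa3

        mu2, sa2, mu3, sa3 = new_mu2, new_sa2, new_mu3, new_sa3
        if not (math.isfinite(mu2) and math.isfinite(mu3) and sa2 > 0 and sa3 > 0):
            raise InvalidTrajectoryError(k, "non-finite or degenerate belief state")
        out["da1"][k] = da1
        out["eps2"][k] = eps2
        out["mu2"][k], out["sigma2"][k] = mu2, sa2
        out["da2"][k], out["eps3"][k] = da2, eps3
        out["mu3"][k], out["sigma3"][k] = mu3, sa3

    return BeliefTrajectory(params=params, levels=levels, **out)


#: event onset each parametric regressor is aligned to
REGRESSOR_ALIGNMENT = {
    "abs_eps2": "outcome",
    "sigma2": "outcome",
    "sigma3": "outcome",
    "eps3": "outcome",
    "abs_mu2hat": "stimulus",
}


def trajectory_regressors(traj: BeliefTrajectory) -> pd.DataFrame:
    """Per-trial parametric regressor values derived from a trajectory.

    The signs of eps2 and mu2hat are arbitrary (they depend on which stimulus
    is coded as 1), so absolute values are used.  ``REGRESSOR_ALIGNMENT``
    records whether each regressor is tied to the outcome or stimulus onset.
    """
    return pd.DataFrame(
        {
            "abs_eps2": np.abs(traj.eps2),
            "sigma2": traj.sigma2,
            "sigma3": traj.sigma3,
            "abs_mu2hat": np.abs(traj.mu2hat),
            "eps3": traj.eps3,
        }
    )
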