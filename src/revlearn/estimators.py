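"""MAP inversion of the HGF candidate models (scikit-learn style).

Each candidate model (hgf2, hgf3, hgf3_mu3) is inverted by maximising the
Bernoulli response log-likelihood plus Gaussian log-priors in an unconstrained
estimation space (log transforms for positive parameters), using multi-start
quasi-Newton (L-BFGS-B) optimisation.  The log-model evidence is approximated
by the Laplace method at the MAP: log joint + d/2 log(2 pi) + 1/2 log det of
the posterior covariance, with the covariance obtained from a symmetrised
central-difference Hessian of the negative log joint.

Priors default to broad TAPAS-style surrogate settings (documented in
``default_priors``); parameters with zero prior variance are fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .hgf import AgentParams, InvalidTrajectoryError, hgf_filter
from .responses import MODELS, choice_probabilities, log_likelihood

__all__ = ["Prior", "PriorSpec", "default_priors", "FitResult", "HGFEstimator"]

_BIG = 1e12  # objective value standing in for an invalid trajectory


@dataclass
class Prior:
    """Gaussian prior on one parameter in estimation space (var 0 = fixed)."""

    mean: float
    var: float

    def __post_init__(self):
        if self.var < 0:
            raise ValueError("prior variance must be non-negative")

    @property
    def fixed(self) -> bool:
        return self.var == 0.0


@dataclass
class PriorSpec:
    """Priors and estimation-space transforms for one model's parameters.

    ``transforms`` maps each parameter to "identity" or "log"; the prior is
    stated in the transformed (estimation) space.
    """

    priors: dict = field(default_factory=dict)
    transforms: dict = field(default_factory=dict)

    @property
    def free_names(self) -> list[str]:
        return [k for k, p in self.priors.items() if not p.fixed]

    def to_native(self, name: str, value: float) -> float:
        return float(np.exp(value)) if self.transforms[name] == "log" else float(value)

    def to_estimation(self, name: str, value: float) -> float:
        return float(np.log(value)) if self.transforms[name] == "log" else float(value)


def default_priors(model: str) -> PriorSpec:
    """Broad surrogate priors in the style of the TAPAS binary-HGF defaults.

    omega2 ~ N(-3, 16), omega3 ~ N(-6, 16), log zeta ~ N(log 48, 1),
    mu3_0 ~ N(1, 1) and log sigma3_0 ~ N(0, 1) where estimated; kappa is
    fixed at 1, (mu2_0, sigma2_0) at (0, 1).  Free parameters per model:
    hgf2: omega2, zeta; hgf3: omega2, omega3, zeta;
    hgf3_mu3: omega2, omega3, mu3_0, sigma3_0.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    priors = {
        "omega2": Prior(-3.0, 16.0),
        "omega3": Prior(-6.0, 16.0 if model != "hgf2" else 0.0),
        "kappa": Prior(1.0, 0.0),
        "mu2_0": Prior(0.0, 0.0),
        "sigma2_0": Prior(0.0, 0.0),  # log space: fixed at 1
        "mu3_0": Prior(1.0, 1.0 if model == "hgf3_mu3" else 0.0),
        "sigma3_0": Prior(0.0, 1.0 if model == "hgf3_mu3" else 0.0),  # log space
    }
    transforms = {
        "omega2": "identity",
        "omega3": "identity",
        "kappa": "identity",
        "mu2_0": "identity",
        "sigma2_0": "log",
        "mu3_0": "identity",
        "sigma3_0": "log",
        "zeta": "log",
    }
    if model in ("hgf2", "hgf3"):
        priors["zeta"] = Prior(float(np.log(48.0)), 1.0)
    return PriorSpec(priors=priors, transforms=transforms)


@dataclass
class FitResult:
    """MAP fit of one model to one subject."""

    model: str
    map_params: AgentParams
    lme: float
    neg_log_joint: float
    n_restarts_used: int
    converged: bool
    posterior_covariance: np.ndarray
    free_names: list
    map_estimation_space: np.ndarray


class _Objective:
    """Negative log joint over the free parameters in estimation space."""

    def __init__(self, u, y, model: str, spec: PriorSpec):
        self.u = np.asarray(u, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.model = model
        self.spec = spec
        self.free = spec.free_names
        self.levels = 2 if model == "hgf2" else 3

    def build_params(self, theta) -> tuple[AgentParams, float | None]:
        native = {
            k: self.spec.to_native(k, p.mean) for k, p in self.spec.priors.items()
        }
        for name, value in zip(self.free, theta):
            native[name] = self.spec.to_native(name, value)
        zeta = native.pop("zeta", None)
        return AgentParams(zeta=zeta, **native), zeta

    def __call__(self, theta) -> float:
        try:
            params, zeta = self.build_params(theta)
        except (ValueError, OverflowError):
            return _BIG
        try:
            traj = hgf_filter(self.u, params, levels=self.levels)
        except InvalidTrajectoryError:
            return _BIG
        zeta_arg = None if self.model == "hgf3_mu3" else zeta
        ll = log_likelihood(self.y, choice_probabilities(traj, self.model, zeta_arg))
        lp = 0.0
        for name, value in zip(self.free, theta):
            pr = self.spec.priors[name]
            lp += -0.5 * np.log(2 * np.pi * pr.var) - 0.5 * (value - pr.mean) ** 2 / pr.var
        out = -(ll + lp)
        return out if np.isfinite(out) else _BIG


def _hessian(f, x, rel_step=1e-4):
    """Symmetrised central-difference Hessian of ``f`` at ``x``."""
    d = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((d, d))
    for i in range(d):
        for j in range(i, d):
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                H[i, i] = (f(xp) - 2.0 * f(x) + f(xm)) / h[i] ** 2
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[[i, j]] += [h[i], h[j]]
                xpm[i] += h[i]
                xpm[j] -= h[j]
                xmp[i] -= h[i]
                xmp[j] += h[j]
                xmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (
                    4.0 * h[i] * h[j]
                )
    return 0.5 * (H + H.T)


def _laplace_lme(obj, theta, eig_floor=1e-10):
    """Laplace log-model evidence and posterior covariance at the MAP."""
    d = len(theta)
    nlj = obj(theta)
    if d == 0:
        return -nlj, np.zeros((0, 0))
    H = _hessian(obj, theta)
    w, V = np.linalg.eigh(H)
    w = np.maximum(w, eig_floor)
    cov = (V * (1.0 / w)) @ V.T
    lme = -nlj + 0.5 * d * np.log(2 * np.pi) - 0.5 * np.sum(np.log(w))
    return float(lme), cov


class HGFEstimator(BaseEstimator):
    """MAP estimator of one HGF candidate model for a single subject.

    Parameters
    ----------
    model : "hgf2" | "hgf3" | "hgf3_mu3".
    priors : PriorSpec or None for the model defaults.
    n_restarts : multi-start count; start points are the prior mean plus
        seeded Gaussian perturbations scaled by the prior SD.
    random_state : seed of the restart perturbations (fits are deterministic
        given data and seed).

    Attributes (after ``fit``)
    --------------------------
    params_ : AgentParams at the MAP; lme_ : Laplace log-model evidence;
    trajectory_ : belief trajectory under the MAP parameters;
    posterior_covariance_ : covariance over the free parameters in
    estimation space; result_ : the full FitResult.
    """

    def __init__(self, model="hgf3_mu3", priors=None, n_restarts=8, random_state=0):
        self.model = model
        self.priors = priors
        self.n_restarts = n_restarts
        self.random_state = random_state

    def _resolve(self, X, y):
        if hasattr(X, "columns"):  # trial table
            u = X["u"].to_numpy(dtype=float)
            y = X["y"].to_numpy(dtype=float)
        else:
            u = np.asarray(X, dtype=float)
            if y is None:
                raise ValueError("responses y are required when X is the input array")
            y = np.asarray(y, dtype=float)
        return u, y

    def fit(self, X, y=None):
        """Fit by multi-start quasi-Newton MAP estimation.

        ``X`` is either a trial table (DataFrame with columns u, y) or the
        binary input array, with ``y`` the response array.
        """
        u, y = self._resolve(X, y)
        spec = self.priors if self.priors is not None else default_priors(self.model)
        obj = _Objective(u, y, self.model, spec)
        free = spec.free_names
        rng = np.random.default_rng(self.random_state)
        mean = np.array([spec.priors[k].mean for k in free])
        sd = np.array([np.sqrt(spec.priors[k].var) for k in free])

        best, best_theta, used = np.inf, mean.copy(), 0
        for r in range(max(1, self.n_restarts)):
            theta0 = mean if r == 0 else mean + rng.normal(size=len(free)) * sd
            if len(free) == 0:
                val, theta = obj(theta0), theta0
            else:
                res = minimize(obj, theta0, method="L-BFGS-B")
                val, theta = res.fun, res.x
            used += 1
            if val < best:
                best, best_theta = val, theta.copy()
        if best >= _BIG:
            raise RuntimeError(
                f"all {used} restarts of {self.model} produced invalid trajectories"
            )

        lme, cov = _laplace_lme(obj, best_theta)
        params, _ = obj.build_params(best_theta)
        self.params_ = params
        self.lme_ = lme
        self.neg_log_joint_ = float(best)
        self.posterior_covariance_ = cov
        self.converged_ = bool(np.isfinite(lme))
        self.n_restarts_used_ = used
        self.free_names_ = list(free)
        self.trajectory_ = hgf_filter(u, params, levels=obj.levels)
        self.result_ = FitResult(
            model=self.model,
            map_params=params,
            lme=lme,
            neg_log_joint=float(best),
            n_restarts_used=used,
            converged=self.converged_,
            posterior_covariance=cov,
            free_names=list(free),
            map_estimation_space=best_theta,
        )
        self._objective_ = obj
        return self

    def predict_proba(self, X, y=None):
        """Choice probabilities p(y=1) for a binary input sequence."""
        u = X["u"].to_numpy(dtype=float) if hasattr(X, "columns") else np.asarray(X)
        traj = hgf_filter(u, self.params_, levels=2 if self.model == "hgf2" else 3)
        zeta = None if self.model == "hgf3_mu3" else self.params_.zeta
        return choice_probabilities(traj, self.model, zeta).p_y1

    def score(self, X, y=None):
        """Mean per-trial response log-likelihood under the MAP parameters."""
        u, y = self._resolve(X, y)
        p = self.predict_proba(u)
        valid = ~np.isnan(y)
        yy = y[valid]
        return float(np.mean(yy * np.log(p[valid]) + (1 - yy) * np.log1p(-p[valid])))
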