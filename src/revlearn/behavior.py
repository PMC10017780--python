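"""Descriptive behavioural statistics and non-parametric inference.

Win-stay / lose-shift rates are normalised per outcome type (e.g. lose-shift
= lose trials followed by a switch / all lose trials with a following
response).  Group comparisons use label-permutation and sign-flip tests with
probability-of-superiority effect sizes (Delta for independent samples,
Delta_dep for paired differences) and percentile-bootstrap confidence
intervals; the 2x2 mixed design (between-subject group x within-subject
block) is tested with synchronised rearrangements; multiplicity is handled by
the adaptive two-stage linear step-up false-discovery-rate procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BehavioralSummary",
    "PermResult",
    "summarize_behaviour",
    "perm_test_independent",
    "perm_test_paired",
    "factorial_2x2",
    "fdr_step_up",
    "spearman",
]


@dataclass
class BehavioralSummary:
    """Session-level behavioural rates (NaN where undefined)."""

    win_rate: float
    win_stay: float
    lose_shift: float
    switch_rate: float
    n_trials: int
    per_block: pd.DataFrame | None = None


def _rates(y, outcome, count_none_as_loss=True):
    y = np.asarray(y, dtype=float)
    outcome = np.asarray(outcome, dtype=object)
    n = len(y)
    wins = np.sum(outcome == "win")
    denom = n if count_none_as_loss else np.sum(outcome != "none")
    win_rate = wins / denom if denom else np.nan

    # consecutive response pairs with both responses present
    valid_pair = ~np.isnan(y[:-1]) & ~np.isnan(y[1:])
    switched = (y[:-1] != y[1:]) & valid_pair
    n_pairs = valid_pair.sum()
    switch_rate = switched.sum() / n_pairs if n_pairs else np.nan

    win_prev = (outcome[:-1] == "win") & valid_pair
    lose_prev = (outcome[:-1] == "lose") & valid_pair
    win_stay = (
        np.sum(win_prev & ~switched) / win_prev.sum() if win_prev.sum() else np.nan
    )
    lose_shift = (
        np.sum(lose_prev & switched) / lose_prev.sum() if lose_prev.sum() else np.nan
    )
    return win_rate, win_stay, lose_shift, switch_rate


def summarize_behaviour(
    trials: pd.DataFrame, count_none_as_loss: bool = True
) -> BehavioralSummary:
    """Win rate, win-stay, lose-shift and switch rates for one session.

    The last trial contributes no stay/shift pair; pairs involving a missing
    response are excluded.  No-response trials count as losses in the win-rate
    denominator by default (they score no points); set
    ``count_none_as_loss=False`` to drop them from the denominator instead.
    Zero lose (win) trials leave lose_shift (win_stay) as NaN rather than 0.
    """
    if len(trials) < 2:
        raise ValueError("need at least two trials")
    wr, ws, ls, sw = _rates(trials["y"], trials["outcome"], count_none_as_loss)
    per_block = None
    if "block_id" in trials:
        rows = {}
        for b, sub in trials.groupby("block_id"):
            rows[b] = dict(
                zip(
                    ("win_rate", "win_stay", "lose_shift", "switch_rate"),
                    _rates(sub["y"], sub["outcome"], count_none_as_loss),
                )
            )
        per_block = pd.DataFrame(rows).T
    return BehavioralSummary(
        win_rate=wr,
        win_stay=ws,
        lose_shift=ls,
        switch_rate=sw,
        n_trials=len(trials),
        per_block=per_block,
    )


@dataclass
class PermResult:
    """Permutation-test outcome with probability-of-superiority effect size."""

    observed_stat: float
    p_value: float
    n_perms: int
    effect_size: float
    ci_low: float
    ci_high: float


def _two_sided_p(null_stats, observed):
    n = len(null_stats)
    p_high = (1 + np.sum(null_stats >= observed)) / (n + 1)
    p_low = (1 + np.sum(null_stats <= observed)) / (n + 1)
    return min(1.0, 2.0 * min(p_low, p_high))


def _delta_independent(a, b):
    gt = np.sum(a[:, None] > b[None, :])
    eq = np.sum(a[:, None] == b[None, :])
    return (gt + 0.5 * eq) / (len(a) * len(b))


def perm_test_independent(
    a, b, n_perms: int = 5000, seed: int = 0, statistic=None, n_boot: int = 1000
) -> PermResult:
    """Two-sample label-permutation test with effect size Delta.

    The default statistic is the difference of means.  Delta is the
    probability of superiority P(a > b) + 0.5 P(a = b) over all pairs, with a
    seeded percentile-bootstrap confidence interval.
    """
    if n_perms < 100:
        raise ValueError("n_perms must be at least 100")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    stat = statistic or (lambda x, y: np.mean(x) - np.mean(y))
    observed = stat(a, b)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    na = len(a)
    null = np.empty(n_perms)
    for i in range(n_perms):
        perm = rng.permutation(pooled)
        null[i] = stat(perm[:na], perm[na:])
    p = _two_sided_p(null, observed)
    delta = _delta_independent(a, b)
    if n_boot > 0:
        boots = np.empty(n_boot)
        for i in range(n_boot):
            boots[i] = _delta_independent(
                rng.choice(a, len(a), replace=True), rng.choice(b, len(b), replace=True)
            )
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = np.nan
    return PermResult(float(observed), p, n_perms, float(delta), float(lo), float(hi))


def perm_test_paired(
    d, n_perms: int = 5000, seed: int = 0, n_boot: int = 1000
) -> PermResult:
    """Sign-flip permutation test on paired differences with Delta_dep.

    Delta_dep = P(d > 0) + 0.5 P(d = 0); if every difference is zero the test
    is degenerate (p = 1, Delta_dep = 0.5).
    """
    if n_perms < 100:
        raise ValueError("n_perms must be at least 100")
    d = np.asarray(d, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least two pairs")
    delta = float(np.mean(d > 0) + 0.5 * np.mean(d == 0))
    rng = np.random.default_rng(seed)
    if np.all(d == 0):
        return PermResult(0.0, 1.0, n_perms, 0.5, 0.5, 0.5)
    observed = float(np.mean(d))
    signs = rng.choice([-1.0, 1.0], size=(n_perms, len(d)))
    null = (signs * d).mean(axis=1)
    p = _two_sided_p(null, observed)
    if n_boot > 0:
        boots = np.empty(n_boot)
        for i in range(n_boot):
            res = rng.choice(d, len(d), replace=True)
            boots[i] = np.mean(res > 0) + 0.5 * np.mean(res == 0)
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = np.nan
    return PermResult(observed, p, n_perms, delta, float(lo), float(hi))


def factorial_2x2(
    values, group_labels, block_labels, subject_ids, n_perms: int = 5000, seed: int = 0
) -> dict:
    """Non-parametric 2x2 mixed factorial test by synchronised rearrangements.

    ``group`` is between-subject (two levels), ``block`` within-subject (two
    levels; each subject contributes one value per block).  The group main
    effect permutes group labels over subject means; the block main effect
    sign-flips within-subject block differences; the interaction permutes
    group labels over the within-subject differences — each test rearranging
    only the factor under test while keeping the other factor's structure
    aligned.

    Returns ``{"p_group", "p_block", "p_interaction"}``.
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "group": np.asarray(group_labels),
            "block": np.asarray(block_labels),
            "subject": np.asarray(subject_ids),
        }
    )
    groups = np.unique(df["group"])
    blocks = np.unique(df["block"])
    if len(groups) != 2 or len(blocks) != 2:
        raise ValueError("each factor must have exactly two levels")
    wide = df.pivot_table(
        index=["subject", "group"], columns="block", values="value"
    ).reset_index()
    if wide[blocks[0]].isna().any() or wide[blocks[1]].isna().any():
        counts = df.groupby(["group", "block"]).size()
        raise ValueError(f"incomplete within-subject design; cell counts:\n{counts}")
    is_a = (wide["group"] == groups[0]).to_numpy()
    mean_sub = wide[[blocks[0], blocks[1]]].mean(axis=1).to_numpy()
    diff_sub = (wide[blocks[0]] - wide[blocks[1]]).to_numpy()
    rng = np.random.default_rng(seed)
    n_sub = len(wide)

    def label_perm_p(x):
        obs = x[is_a].mean() - x[~is_a].mean()
        null = np.empty(n_perms)
        for i in range(n_perms):
            mask = np.zeros(n_sub, dtype=bool)
            mask[rng.choice(n_sub, is_a.sum(), replace=False)] = True
            null[i] = x[mask].mean() - x[~mask].mean()
        return _two_sided_p(null, obs)

    p_group = label_perm_p(mean_sub)
    p_interaction = label_perm_p(diff_sub)
    obs_block = diff_sub.mean()
    signs = rng.choice([-1.0, 1.0], size=(n_perms, n_sub))
    null_block = (signs * diff_sub).mean(axis=1)
    p_block = _two_sided_p(null_block, obs_block)
    return {"p_group": p_group, "p_block": p_block, "p_interaction": p_interaction}


def fdr_step_up(p_values, q: float = 0.05):
    """Adaptive two-stage linear step-up FDR control.

    Stage 1 runs the linear step-up procedure at q/(1+q) to estimate the
    number of true nulls m0 = m - r1; stage 2 reruns it at the level scaled by
    m/m0.  Returns the rejection mask and the adjusted p-value threshold (the
    largest rejected p, or 0.0 when nothing is rejected).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_tsbh")
    threshold = float(p[reject].max()) if reject.any() else 0.0
    return reject, threshold


def spearman(x, y, n_perms: int = 10**4, seed: int = 0) -> dict:
    """Spearman rank correlation (midrank ties) with a permutation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return {"rho": np.nan, "p": np.nan, "degenerate": True}
    rho = stats.spearmanr(x, y).statistic
    rng = np.random.default_rng(seed)
    null = np.empty(n_perms)
    for i in range(n_perms):
        null[i] = stats.spearmanr(x, rng.permutation(y)).statistic
    p = (1 + np.sum(np.abs(null) >= abs(rho))) / (n_perms + 1)
    return {"rho": float(rho), "p": float(p), "degenerate": False}
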