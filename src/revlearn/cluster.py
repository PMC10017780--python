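"""Group-level spectrotemporal cluster-based permutation testing.

Response images (subjects x [labels x] frequencies x times) are compared
between two groups with a two-sample t-test at every grid point; contiguous
supra-threshold points (8-connectivity within a label's time-frequency grid;
no adjacency across labels) form clusters whose mass is the summed t-value.
The family-wise error rate is controlled by permuting group labels and
comparing each observed cluster mass against the permutation distribution of
the maximum mass over the whole grid, separately per sign, at 0.025 per tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = ["Cluster", "ClusterResult", "cluster_perm_test", "restrict_to_windows"]

_STRUCTURES = {
    8: np.ones((3, 3), dtype=bool),
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
}


@dataclass
class Cluster:
    label: int
    mask: np.ndarray  # boolean (n_freqs, n_times) within the label's grid
    mass: float
    sign: int
    p_value: float


@dataclass
class ClusterResult:
    clusters: list
    n_perms: int
    alpha_fwer: float
    t_obs: np.ndarray
    times: np.ndarray | None = None
    freqs: np.ndarray | None = None
    inputs: tuple | None = field(default=None, repr=False)

    @property
    def significant(self) -> list:
        return [c for c in self.clusters if c.p_value < self.alpha_fwer]


def _tmap(a, b):
    """Two-sample t (equal variances) per grid point; groups on axis 0."""
    na, nb = len(a), len(b)
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    return np.nan_to_num(t)


def _clusters_by_label(t, t_crit, connectivity=8):
    """(label_index, mask, mass, sign) for each supra-threshold cluster.

    ``t`` has shape (n_labels, n_freqs, n_times); clustering never crosses
    label boundaries.
    """
    structure = _STRUCTURES[connectivity]
    found = []
    for lab in range(t.shape[0]):
        for sign in (1, -1):
            supra = (sign * t[lab]) > t_crit
            comp, n = ndimage.label(supra, structure=structure)
            for c in range(1, n + 1):
                mask = comp == c
                found.append((lab, mask, float(t[lab][mask].sum()), sign))
    return found


def _max_masses(t, t_crit, connectivity=8):
    """Maximum positive and |minimum negative| cluster mass over all labels."""
    pos, neg = 0.0, 0.0
    for lab, mask, mass, sign in _clusters_by_label(t, t_crit, connectivity):
        if sign > 0:
            pos = max(pos, mass)
        else:
            neg = max(neg, -mass)
    return pos, neg


def cluster_perm_test(
    group_a,
    group_b,
    n_perms: int = 1000,
    seed: int = 0,
    alpha_fwer: float = 0.025,
    cluster_alpha: float = 0.05,
    times=None,
    freqs=None,
    time_window=None,
    connectivity: int = 8,
) -> ClusterResult:
    """Two-group spectrotemporal cluster permutation test.

    ``group_a``/``group_b``: arrays of shape (n_subjects, n_freqs, n_times) or
    (n_subjects, n_labels, n_freqs, n_times).  The cluster-forming threshold
    is the two-sided t critical value at ``cluster_alpha``; FWER is controlled
    at ``alpha_fwer`` per tail.  ``connectivity`` selects 8- (default, with
    diagonals) or 4-neighbour adjacency on the time-frequency grid.  ``time_window`` (with ``times``) restricts
    clustering and testing to an interval of interest before anything is
    computed.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim == 3:
        a, b = a[:, None], b[:, None]
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("groups must share label/frequency/time axes")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two subjects per group")
    times = None if times is None else np.asarray(times)
    if time_window is not None:
        if times is None:
            raise ValueError("time_window requires a time axis")
        lo, hi = time_window
        sel = (times >= lo) & (times <= hi)
        if not sel.any():
            raise ValueError("empty analysis window")
        a, b, times = a[..., sel], b[..., sel], times[sel]

    na, nb = len(a), len(b)
    df = na + nb - 2
    t_crit = stats.t.ppf(1.0 - cluster_alpha / 2.0, df)
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    t_obs = _tmap(a, b)
    observed = _clusters_by_label(t_obs, t_crit, connectivity)

    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b], axis=0)
    null_pos = np.empty(n_perms)
    null_neg = np.empty(n_perms)
    for i in range(n_perms):
        idx = rng.permutation(na + nb)
        t_perm = _tmap(pooled[idx[:na]], pooled[idx[na:]])
        null_pos[i], null_neg[i] = _max_masses(t_perm, t_crit, connectivity)

    clusters = []
    for lab, mask, mass, sign in observed:
        null = null_pos if sign > 0 else null_neg
        p = (1 + np.sum(null >= abs(mass))) / (n_perms + 1)
        clusters.append(Cluster(lab, mask, mass, sign, float(p)))
    clusters.sort(key=lambda c: c.p_value)
    return ClusterResult(
        clusters=clusters,
        n_perms=n_perms,
        alpha_fwer=alpha_fwer,
        t_obs=t_obs,
        times=times,
        freqs=None if freqs is None else np.asarray(freqs),
        inputs=(a, b, seed, cluster_alpha, connectivity),
    )


def restrict_to_windows(result: ClusterResult, analysis_window) -> ClusterResult:
    """Re-run a cluster test restricted to a temporal window of interest."""
    if result.inputs is None or result.times is None:
        raise ValueError("result does not carry its inputs/time axis")
    a, b, seed, cluster_alpha, connectivity = result.inputs
    return cluster_perm_test(
        a,
        b,
        n_perms=result.n_perms,
        seed=seed,
        alpha_fwer=result.alpha_fwer,
        cluster_alpha=cluster_alpha,
        times=result.times,
        freqs=result.freqs,
        time_window=analysis_window,
        connectivity=connectivity,
    )
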