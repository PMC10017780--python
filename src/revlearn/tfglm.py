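"""Morlet time-frequency transforms and the convolution GLM.

The convolution GLM deconvolves overlapping event-locked responses from a
pseudo-continuous time-frequency amplitude series Y (time x frequency).  Each
event stream (discrete event types with value 1, parametric regressors
carrying trial-wise model quantities) is convolved with a Fourier basis B of
order m (m sines and m cosines spanning the peri-event window), giving the
design X = U * B plus a global intercept.  Ordinary least squares per
frequency yields coefficients beta, and the deconvolved peri-event response
image of regressor i is R_i = B beta_i.  An order-m basis over a window of
length T resolves envelope modulations up to m/T Hz, i.e. a temporal
resolution of T/m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from mne.time_frequency import tfr_array_morlet
from scipy.signal import fftconvolve
from sklearn.base import BaseEstimator

__all__ = [
    "TFImage",
    "DesignMatrix",
    "ResponseImage",
    "morlet_tf",
    "build_design",
    "ConvolutionGLM",
    "fit_convolution_glm",
    "baseline_normalize",
    "collinearity_screen",
    "BANDS",
]

#: analysis bands: (f_min, f_max, wavelet cycles), 2-Hz frequency steps
BANDS = {"low": (8.0, 30.0, 5.0), "gamma": (32.0, 100.0, 7.0)}


@dataclass
class TFImage:
    """Time-frequency amplitude image (square root of Morlet power)."""

    freqs: np.ndarray
    times: np.ndarray
    values: np.ndarray  # (n_freqs, n_times)
    sfreq: float
    units: str = "amplitude"
    meta: dict = field(default_factory=dict)


def morlet_tf(series, sfreq: float, band: str = "low") -> TFImage:
    """Morlet wavelet amplitude of a 1-D series in 2-Hz bins.

    ``band`` selects 8-30 Hz with 5-cycle wavelets ("low") or 32-100 Hz with
    7-cycle wavelets ("gamma").  Power is converted to amplitude by a square
    root, which brings the GLM closer to its error assumptions.
    """
    if band not in BANDS:
        raise ValueError(f"band must be one of {sorted(BANDS)}")
    fmin, fmax, cycles = BANDS[band]
    if sfreq < 2 * fmax:
        raise ValueError("sampling rate below twice the highest band frequency")
    series = np.asarray(series, dtype=float)
    freqs = np.arange(fmin, fmax + 1e-9, 2.0)
    # Morlet support is ~10 Gaussian SDs: sigma_t = cycles / (2 pi f)
    longest = 10.0 * cycles / (2 * np.pi * fmin)
    if len(series) / sfreq <= longest:
        raise ValueError(
            f"series ({len(series) / sfreq:.2f} s) shorter than the longest "
            f"wavelet ({longest:.2f} s)"
        )
    power = tfr_array_morlet(
        series[np.newaxis, np.newaxis, :],
        sfreq=sfreq,
        freqs=freqs,
        n_cycles=cycles,
        output="power",
        verbose="error",
    )[0, 0]
    return TFImage(
        freqs=freqs,
        times=np.arange(len(series)) / sfreq,
        values=np.sqrt(power),
        sfreq=sfreq,
        meta={"band": band, "n_cycles": cycles},
    )


@dataclass
class DesignMatrix:
    """Convolved design X = U * B with one global intercept column (last)."""

    X: np.ndarray  # (n_samples, n_regressors * 2*order + 1)
    B: np.ndarray  # (n_peri, 2*order)
    U: np.ndarray  # (n_samples, n_regressors)
    regressors: list
    col_slices: dict
    peri_times: np.ndarray
    window: tuple
    order: int
    sfreq: float


def fourier_basis(order: int, window: tuple, sfreq: float, dc: bool = False):
    """Sine/cosine pairs at integer multiples of the window fundamental.

    With ``dc=True`` a constant column is appended, letting each regressor
    carry its own window-mean level instead of deferring it to the global
    intercept (useful when absolute response units matter; the 2m-function
    convention omits it).
    """
    w0, w1 = window
    if not order >= 1:
        raise ValueError("order must be >= 1")
    if not w1 > w0:
        raise ValueError("window must have positive length")
    p = int(round((w1 - w0) * sfreq))
    tau = np.arange(p) / sfreq  # time within window
    T = w1 - w0
    cols = []
    for j in range(1, order + 1):
        cols.append(np.sin(2 * np.pi * j * tau / T))
        cols.append(np.cos(2 * np.pi * j * tau / T))
    if dc:
        cols.append(np.ones(p))
    B = np.column_stack(cols)
    peri_times = w0 + tau
    return B, peri_times


def build_design(
    events: pd.DataFrame,
    duration_s: float,
    sfreq: float,
    order: int = 20,
    window: tuple = (-0.5, 1.8),
    dc: bool = False,
) -> DesignMatrix:
    """Build the convolution design from an event table.

    ``events`` has columns onset_s, type, value.  Each event type becomes one
    input function with the event value placed at its onset sample; identical-
    type events landing on the same sample are merged (values summed) with a
    warning.  Every input function is convolved with the Fourier basis,
    shifted so that basis sample j corresponds to lag window[0] + j/sfreq
    relative to the event.
    """
    B, peri_times = fourier_basis(order, window, sfreq, dc=dc)
    n = int(round(duration_s * sfreq))
    if (events["onset_s"] < 0).any() or (events["onset_s"] >= duration_s).any():
        raise ValueError("event onsets outside the series duration")
    regressors = list(pd.unique(events["type"]))
    U = np.zeros((n, len(regressors)))
    for r, name in enumerate(regressors):
        sub = events[events["type"] == name]
        idx = np.round(sub["onset_s"].to_numpy() * sfreq).astype(int)
        if len(np.unique(idx)) < len(idx):
            warnings.warn(f"merged overlapping {name!r} events on the same sample")
        np.add.at(U[:, r], idx, sub["value"].to_numpy(dtype=float))
    offset = int(round(window[0] * sfreq))
    ncols = U.shape[1] * B.shape[1]
    X = np.zeros((n, ncols + 1))
    col_slices = {}
    for r, name in enumerate(regressors):
        conv = fftconvolve(U[:, r][:, None], B, axes=0)  # (n + p - 1, 2m)
        shifted = np.zeros((n, B.shape[1]))
        start = -offset  # offset <= 0 for windows starting before the event
        if start >= 0:
            avail = conv[start : start + n]
        else:
            avail = np.vstack([np.zeros((-start, B.shape[1])), conv[: n + start]])
        shifted[: len(avail)] = avail[:n]
        sl = slice(r * B.shape[1], (r + 1) * B.shape[1])
        X[:, sl] = shifted
        col_slices[name] = sl
    X[:, -1] = 1.0  # global intercept
    return DesignMatrix(
        X=X,
        B=B,
        U=U,
        regressors=regressors,
        col_slices=col_slices,
        peri_times=peri_times,
        window=tuple(window),
        order=order,
        sfreq=sfreq,
    )


@dataclass
class ResponseImage:
    """Deconvolved peri-event time x frequency response for one regressor."""

    regressor: str
    times: np.ndarray
    freqs: np.ndarray
    values: np.ndarray  # (n_freqs, n_peri)
    units: str = "a.u."
    baseline_mean: np.ndarray | None = None
    baseline_sd: np.ndarray | None = None


class ConvolutionGLM(BaseEstimator):
    """Convolution GLM deconvolving TF responses to event regressors.

    Parameters
    ----------
    order : Fourier basis order m (2m basis functions); resolves envelope
        modulations up to order/(window length) Hz.
    window : peri-event interval in seconds.
    rcond : pseudoinverse cutoff relative to the largest singular value.

    Attributes (after ``fit``)
    --------------------------
    design_ : DesignMatrix; coef_ : (n_columns, n_freqs) OLS coefficients;
    response_images_ : dict regressor -> ResponseImage.
    """

    def __init__(self, order: int = 20, window: tuple = (-0.5, 1.8), rcond=1e-10,
                 dc: bool = False):
        self.order = order
        self.window = window
        self.rcond = rcond
        self.dc = dc

    def fit(self, tf: TFImage, events: pd.DataFrame, sample_mask=None):
        design = build_design(
            events,
            duration_s=len(tf.times) / tf.sfreq,
            sfreq=tf.sfreq,
            order=self.order,
            window=self.window,
            dc=self.dc,
        )
        X = design.X
        Y = tf.values.T  # (n_times, n_freqs)
        if X.shape[0] != Y.shape[0]:
            raise ValueError("TF image and design matrix time axes differ")
        if sample_mask is not None:
            X, Y = X[sample_mask], Y[sample_mask]
        rank = np.linalg.matrix_rank(X, tol=self.rcond * np.linalg.norm(X, 2))
        if rank < X.shape[1]:
            _, R = np.linalg.qr(X)
            diag = np.abs(np.diag(R))
            bad = np.flatnonzero(diag < self.rcond * diag.max())
            names = []
            for c in bad:
                for nm, sl in design.col_slices.items():
                    if sl.start <= c < sl.stop:
                        names.append(f"{nm}[{c - sl.start}]")
            raise ValueError(f"rank-deficient design; collinear columns: {names}")
        beta = np.linalg.pinv(X, rcond=self.rcond) @ Y
        self.design_ = design
        self.coef_ = beta
        self.response_images_ = {}
        for name, sl in design.col_slices.items():
            values = (design.B @ beta[sl]).T  # (n_freqs, n_peri)
            self.response_images_[name] = ResponseImage(
                regressor=name,
                times=design.peri_times,
                freqs=tf.freqs,
                values=values,
            )
        return self

    def transform(self, tf: TFImage):
        """Model-predicted TF amplitude (n_freqs, n_times) from the fit."""
        return (self.design_.X @ self.coef_).T


def fit_convolution_glm(
    tf: TFImage,
    events: pd.DataFrame,
    order: int = 20,
    window: tuple = (-0.5, 1.8),
    sample_mask=None,
    dc: bool = False,
) -> dict:
    """Functional wrapper over :class:`ConvolutionGLM`; returns the response
    images keyed by regressor."""
    glm = ConvolutionGLM(order=order, window=window, dc=dc)
    glm.fit(tf, events, sample_mask=sample_mask)
    return glm.response_images_


def baseline_normalize(
    r: ResponseImage, window: tuple = (-0.3, -0.05)
) -> ResponseImage:
    """Express a response image in SD units of its pre-event baseline.

    Per frequency bin, subtracts the baseline-window mean and divides by the
    baseline-window SD.  The stats are stored on the result so the transform
    can be inverted.
    """
    lo, hi = window
    sel = (r.times >= lo) & (r.times <= hi)
    if not sel.any() or lo < r.times[0] or hi > r.times[-1]:
        raise ValueError("baseline window outside the response time axis")
    mean = r.values[:, sel].mean(axis=1)
    sd = r.values[:, sel].std(axis=1, ddof=0)
    if np.any(sd == 0):
        raise ValueError("zero baseline SD (degenerate input)")
    return ResponseImage(
        regressor=r.regressor,
        times=r.times,
        freqs=r.freqs,
        values=(r.values - mean[:, None]) / sd[:, None],
        units="SD",
        baseline_mean=mean,
        baseline_sd=sd,
    )


def collinearity_screen(
    regressors: pd.DataFrame,
    threshold: float = 0.2,
    exclude_policy: str = "eps3_vs_abs_eps2",
) -> dict:
    """Pairwise Pearson screening of parametric regressors.

    Flags pairs with |r| >= threshold.  With the default policy, eps3 is
    dropped from the retained set when it is collinear with abs_eps2 (the
    level-2 and level-3 precision-weighted prediction errors are strongly
    correlated by construction); other flagged pairs are reported only.
    Constant regressors are reported as degenerate and excluded.
    """
    if regressors.shape[1] < 2:
        raise ValueError("need at least two regressors")
    cols = list(regressors.columns)
    degenerate = [c for c in cols if np.nanstd(regressors[c].to_numpy()) == 0]
    rows = []
    retained = [c for c in cols if c not in degenerate]
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            if a in degenerate or b in degenerate:
                continue
            valid = regressors[[a, b]].dropna()
            rho = float(np.corrcoef(valid[a], valid[b])[0, 1])
            flagged = abs(rho) >= threshold
            rows.append({"pair": (a, b), "r": rho, "flagged": flagged})
            if (
                flagged
                and exclude_policy == "eps3_vs_abs_eps2"
                and {a, b} == {"eps3", "abs_eps2"}
                and "eps3" in retained
            ):
                retained.remove("eps3")
    return {
        "report": pd.DataFrame(rows),
        "retained": retained,
        "degenerate": degenerate,
    }
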