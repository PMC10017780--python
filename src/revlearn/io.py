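"""Delimited-text I/O for trial tables, trajectories, event tables, LME
matrices, and plain numeric time series with a sidecar metadata file.

Formats
-------
Trial table (TSV): columns ``trial, u, y, outcome, p_true, block_id,
onset_stimulus_s, onset_response_s, onset_outcome_s``; missing responses are
empty cells.

Trajectory (TSV): one row per trial, columns named exactly as the
:class:`~revlearn.hgf.BeliefTrajectory` fields.

Event table (TSV): ``onset_s, type, value``.

Time series: one float per line, with ``<name>.meta.yaml`` holding
``sampling_rate`` (Hz) and ``start_s``.

LME matrix (TSV): rows subjects, columns models (header = model names).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "write_trials",
    "read_trials",
    "write_trajectory",
    "read_trajectory",
    "write_events",
    "read_events",
    "write_series",
    "read_series",
    "write_lme",
    "read_lme",
]


def write_trials(trials: pd.DataFrame, path):
    trials.to_csv(path, sep="\t", index=False)


def read_trials(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_trajectory(traj, path):
    traj.to_frame().to_csv(path, sep="\t", index=False)


def read_trajectory(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_events(events: pd.DataFrame, path):
    events.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_series(series, path, sampling_rate: float, start_s: float = 0.0):
    path = Path(path)
    np.savetxt(path, np.asarray(series, dtype=float))
    meta = {"sampling_rate": float(sampling_rate), "start_s": float(start_s)}
    path.with_suffix(path.suffix + ".meta.yaml").write_text(yaml.safe_dump(meta))


def read_series(path):
    path = Path(path)
    series = np.loadtxt(path)
    meta = yaml.safe_load(path.with_suffix(path.suffix + ".meta.yaml").read_text())
    return series, meta


def write_lme(lme: np.ndarray, path, model_names=None):
    k = np.asarray(lme).shape[1]
    names = model_names or [f"model_{i}" for i in range(k)]
    pd.DataFrame(np.asarray(lme), columns=names).to_csv(path, sep="\t", index=False)


def read_lme(path):
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), list(df.columns)
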