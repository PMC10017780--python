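"""Probabilistic reversal-learning task schedules.

The task presents two stimuli whose reward probabilities are reciprocal
(p, 1-p).  Within each block of 160 trials the contingency p(win | reference
stimulus) is piecewise constant: five segments, one per mapping in
{0.9, 0.1, 0.7, 0.3, 0.5}, in pseudorandom order, each lasting 26-38 trials.
Event onsets (stimulus, response highlight, outcome) carry uniform jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: the five contingency mappings used within every block
CONTINGENCIES = (0.9, 0.1, 0.7, 0.3, 0.5)

MIN_SEGMENT = 26
MAX_SEGMENT = 38

# event timing in seconds: (mean, half-range) of the uniform jitter
RESPONSE_WINDOW = (1.300, 0.125)
HIGHLIGHT = (1.000, 0.200)
OUTCOME_DURATION = (1.900, 0.100)
ITI = (1.750, 0.250)


@dataclass
class TaskSchedule:
    """Per-trial ground truth of one simulated session.

    Attributes
    ----------
    p_true : per-trial probability that the reference stimulus is rewarded.
    segment_id : global index of the piecewise-constant segment.
    block_id : 1-based block index.
    onsets : DataFrame with columns ``onset_stimulus_s``, ``onset_response_s``,
        ``onset_outcome_s``, strictly increasing within and across trials.
    """

    p_true: np.ndarray
    segment_id: np.ndarray
    block_id: np.ndarray
    onsets: pd.DataFrame = field(repr=False)

    @property
    def n_trials(self) -> int:
        return len(self.p_true)

    def n_contingency_changes(self) -> int:
        """Number of trials where p_true changes from the previous trial."""
        return int(np.sum(np.diff(self.p_true) != 0))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "trial": np.arange(self.n_trials),
                "p_true": self.p_true,
                "segment_id": self.segment_id,
                "block_id": self.block_id,
            }
        )
        return pd.concat([df, self.onsets.reset_index(drop=True)], axis=1)


def _segment_lengths(n_trials: int, rng: np.random.Generator) -> np.ndarray:
    """Five integer lengths in [26, 38] summing to ``n_trials``.

    Draw uniformly, then repair the sum by +/-1 adjustments of randomly chosen
    segments that can move without leaving the bounds.
    """
    n_seg = len(CONTINGENCIES)
    if not n_seg * MIN_SEGMENT <= n_trials <= n_seg * MAX_SEGMENT:
        raise ValueError(
            f"cannot partition {n_trials} trials into {n_seg} segments "
            f"of length {MIN_SEGMENT}-{MAX_SEGMENT}"
        )
    lengths = rng.integers(MIN_SEGMENT, MAX_SEGMENT + 1, size=n_seg)
    while (excess := lengths.sum() - n_trials) != 0:
        step = -1 if excess > 0 else 1
        movable = np.flatnonzero(
            (lengths + step >= MIN_SEGMENT) & (lengths + step <= MAX_SEGMENT)
        )
        lengths[rng.choice(movable)] += step
    return lengths


def generate_schedule(
    blocks: int = 2, trials_per_block: int = 160, seed: int | None = None
) -> TaskSchedule:
    """Generate a pseudorandom contingency schedule.

    Each block uses every contingency in :data:`CONTINGENCIES` exactly once, in
    a random order drawn independently per block, so a mapping may repeat
    across a block boundary.  Identical seeds give identical schedules.
    """
    rng = np.random.default_rng(seed)
    p_true, segment_id, block_id = [], [], []
    seg_counter = 0
    for b in range(blocks):
        order = rng.permutation(len(CONTINGENCIES))
        lengths = _segment_lengths(trials_per_block, rng)
        for idx, length in zip(order, lengths):
            p_true.extend([CONTINGENCIES[idx]] * length)
            segment_id.extend([seg_counter] * length)
            seg_counter += 1
        block_id.extend([b + 1] * trials_per_block)

    n = len(p_true)
    jitter = lambda spec, size: rng.uniform(spec[0] - spec[1], spec[0] + spec[1], size)
    t = 0.0
    stim, resp, outc = np.empty(n), np.empty(n), np.empty(n)
    rw = jitter(RESPONSE_WINDOW, n)
    hl = jitter(HIGHLIGHT, n)
    od = jitter(OUTCOME_DURATION, n)
    iti = jitter(ITI, n)
    for k in range(n):
        stim[k] = t
        resp[k] = stim[k] + rw[k]
        outc[k] = resp[k] + hl[k]
        t = outc[k] + od[k] + iti[k]
    onsets = pd.DataFrame(
        {"onset_stimulus_s": stim, "onset_response_s": resp, "onset_outcome_s": outc}
    )
    return TaskSchedule(
        p_true=np.asarray(p_true),
        segment_id=np.asarray(segment_id),
        block_id=np.asarray(block_id),
        onsets=onsets,
    )


def ceiling_win_rate(schedule: TaskSchedule) -> float:
    """Expected win rate of an oracle always choosing the more rewarded option.

    The oracle wins with probability max(p, 1-p) on every trial; the ceiling is
    the mean of that quantity over the schedule.
    """
    p = schedule.p_true
    return float(np.mean(np.maximum(p, 1.0 - p)))


def payment(points: float) -> float:
    """Convert accumulated reward points to the monetary payout.

    The payout rule is ``points / 6 + 400`` currency units.
    """
    if points < 0:
        raise ValueError("points must be non-negative")
    return points / 6 + 400
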