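"""Behavioral scoring: conditioned responses and cumulative response curves.

A trial counts as a conditioned response (CR) if the agent enters the left
arm of the maze within its first 50 time steps (the junction columns above
the stem do not belong to either arm).  Learning dynamics are summarized by
cumulative response curves (CRC): per-run running counts of CR trials,
averaged across independent runs.  Renewal is quantified as the jump in CR
rate at the context-B to context-A transition: the mean CR fraction over the
first trials of the test phase minus the mean over the last trials of the
extinction phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .maze import MazeGraph

__all__ = [
    "TrialTrajectory",
    "CRCurve",
    "classify_cr",
    "cumulative_response_curve",
    "renewal_index",
    "CR_WINDOW_STEPS",
    "RENEWAL_WINDOW_TRIALS",
]

#: The CR rule window: the arm entry must occur within this many time steps.
CR_WINDOW_STEPS = 50

#: Trials averaged on each side of the phase-2/phase-3 boundary for renewal.
RENEWAL_WINDOW_TRIALS = 20


@dataclass(frozen=True)
class TrialTrajectory:
    """Sequence of visited grid points of one trial (start node included)."""

    nodes: tuple
    reached_goal: bool = False

    @property
    def length(self) -> int:
        return len(self.nodes) - 1


@dataclass(frozen=True)
class CRCurve:
    """Cumulative response curves over a collection of runs.

    ``indicator`` is the (n_runs, n_trials) CR matrix, ``cumulative`` its
    per-run running sum; mean/sd are taken across runs per trial index, and
    ``response_rate`` is the cross-run mean CR indicator (the CRC increment).
    """

    indicator: np.ndarray
    cumulative: np.ndarray
    cum_mean: np.ndarray
    cum_sd: np.ndarray
    response_rate: np.ndarray


def classify_cr(traj: TrialTrajectory, maze: MazeGraph,
                window: int = CR_WINDOW_STEPS) -> bool:
    """True iff the trajectory visits a left-arm node within ``window`` steps.

    All time steps count, including steps wasted bumping into walls; the
    visited node at step ``t`` is ``traj.nodes[t]``.
    """
    visited = np.asarray(traj.nodes[: window + 1], dtype=np.int64)
    return bool(np.any(maze.arm_labels[visited] == "left_arm"))


def cumulative_response_curve(cr_indicator: np.ndarray | Sequence) -> CRCurve:
    """Build the CRC from a (n_runs, n_trials) CR indicator matrix."""
    ind = np.atleast_2d(np.asarray(cr_indicator, dtype=float))
    if ind.ndim != 2:
        raise ValueError("CR indicator must be a (n_runs, n_trials) matrix")
    cum = np.cumsum(ind, axis=1)
    return CRCurve(
        indicator=ind,
        cumulative=cum,
        cum_mean=cum.mean(axis=0),
        cum_sd=cum.std(axis=0),
        response_rate=ind.mean(axis=0),
    )


def renewal_index(cr_indicator: np.ndarray, phase_lengths: Sequence[int],
                  window: int = RENEWAL_WINDOW_TRIALS) -> np.ndarray:
    """Per-run renewal index for a three-phase experiment.

    The index is the mean CR fraction over the first ``window`` trials of
    phase 3 minus the mean CR fraction over the last ``window`` trials of
    phase 2; positive values indicate renewal of the conditioned response on
    return to context A.
    """
    if len(phase_lengths) != 3:
        raise ValueError("renewal index requires a three-phase experiment")
    n2, n3 = int(phase_lengths[1]), int(phase_lengths[2])
    if n2 < window or n3 < window:
        raise ValueError(
            f"phases must contain at least {window} trials (got {n2}, {n3})"
        )
    ind = np.atleast_2d(np.asarray(cr_indicator, dtype=float))
    if ind.shape[1] != sum(int(n) for n in phase_lengths):
        raise ValueError("indicator width does not match total trial count")
    b2 = int(phase_lengths[0]) + n2
    tail2 = ind[:, b2 - window : b2].mean(axis=1)
    head3 = ind[:, b2 : b2 + window].mean(axis=1)
    return head3 - tail2
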