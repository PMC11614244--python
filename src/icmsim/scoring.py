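"""Pattern-score objective: configuration, joint, and meta scores.

The patterning objective compares realized lineage counts ``Z = (Z_EPI,
Z_PRE, Z_UND)`` against a target count vector ``w`` via an exponential
transform of their l1 distance,

    S = (exp(-||Z - w||_1 / ||w||_1) - w*) / (1 - w*),
    w* = exp(-2 max(w) / ||w||_1),

which equals 1 exactly at ``Z = w`` and saturates at 0 for l1 distances of
``2 max(w)`` or beyond (larger distances are reachable only through counts
on zero-target components, e.g. undifferentiated cells).  Two system
configurations (signaling on / signaling off) give two marginal scores that
are combined with an l1 penalty,

    S = ((S0 + S1) - |S0 - S1|) / 2  =  min(S0, S1),

favoring simultaneously high marginals.  An ensemble of joint-score time
series is summarized by the meta score: per time point take the median m
and the 5-95 percentile spread penalty b = ((p95 - p5)/2)^2, then average
max(m - b, 0) over the scoring window (the last 12 h of a 48 h run).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "TargetSpec",
    "configuration_score",
    "joint_score",
    "meta_score",
    "build_target_observation",
    "window_indices",
    "score_time_series",
    "TARGETS_ITWT_ON",
    "TARGETS_ITWT_OFF",
]

#: EPI-PRE-UND target proportions by system configuration.
TARGETS_ITWT_ON = (0.40, 0.60, 0.0)   # functional signaling
TARGETS_ITWT_OFF = (1.0, 0.0, 0.0)    # signaling inactivated


@dataclass(frozen=True)
class TargetSpec:
    """Target lineage count vector for one system configuration."""

    m: int                      # configuration index (0 or 1)
    w: tuple[int, int, int]     # (EPI, PRE, UND) target counts

    @staticmethod
    def from_proportions(m: int, n_cells: int,
                         proportions: tuple[float, float, float]) -> "TargetSpec":
        w = [int(round(p * n_cells)) for p in proportions]
        w[2] = n_cells - w[0] - w[1]  # force exact total
        if min(w) < 0:
            raise ValueError("proportions do not yield valid counts")
        return TargetSpec(m, (w[0], w[1], w[2]))

    @property
    def total(self) -> int:
        return sum(self.w)


def configuration_score(Z: Sequence[int], target: TargetSpec) -> float:
    """Marginal pattern score of one fate-count vector against one target."""
    Z = np.asarray(Z, dtype=float)
    w = np.asarray(target.w, dtype=float)
    norm = w.sum()
    if Z.sum() != norm:
        raise ValueError("count vector and target must have equal totals")
    dist = np.abs(Z - w).sum()
    w_star = np.exp(-2.0 * w.max() / norm)
    raw = (np.exp(-dist / norm) - w_star) / (1.0 - w_star)
    # distances beyond 2*max(w) occur when counts sit on a zero-target
    # component (e.g. an all-undifferentiated tissue); the score saturates
    # at its floor there, keeping the range [0, 1]
    return float(min(max(raw, 0.0), 1.0))


def joint_score(s0: float, s1: float) -> float:
    """Penalty-combined pattern score of two marginals; equals min(s0, s1)."""
    return ((s0 + s1) - abs(s0 - s1)) / 2.0


def window_indices(times_h: np.ndarray, t_end_h: float = 48.0,
                   window_h: float = 12.0, closed_left: bool = False) -> np.ndarray:
    """Grid indices of the scoring window.

    Default is the half-open interval (t_end - window, t_end] on the 0.25 h
    grid (48 points for the defaults); ``closed_left`` includes the left
    boundary as well.
    """
    if window_h <= 0:
        raise ValueError("window must be positive")
    if window_h > t_end_h:
        raise ValueError("window cannot exceed the simulated period")
    lo = t_end_h - window_h
    if closed_left:
        mask = (times_h >= lo - 1e-9) & (times_h <= t_end_h + 1e-9)
    else:
        mask = (times_h > lo + 1e-9) & (times_h <= t_end_h + 1e-9)
    return np.nonzero(mask)[0]


def build_target_observation(t_end_h: float = 48.0, window_h: float = 12.0,
                             dt_h: float = 0.25,
                             closed_left: bool = False) -> np.ndarray:
    """The synthetic goal observation: a score series of all ones over the
    scoring window (48 entries for the defaults)."""
    times = np.arange(int(np.floor(t_end_h / dt_h + 1e-9)) + 1) * dt_h
    idx = window_indices(times, t_end_h, window_h, closed_left)
    if idx.size == 0:
        raise ValueError("degenerate scoring window")
    return np.ones(idx.size)


def score_time_series(counts: np.ndarray, target: TargetSpec) -> np.ndarray:
    """Marginal score series for a (T, 3) fate-count array."""
    return np.array([configuration_score(z, target) for z in counts])


def meta_score(score_series: Sequence[np.ndarray]) -> float:
    """Accuracy-and-precision summary of an ensemble of score series.

    Per time point: median alpha50 and spread penalty
    beta = ((alpha95 - alpha5)/2)^2 over the ensemble; the meta score is the
    time average of max(alpha50 - beta, 0).  Percentiles use linear
    interpolation.
    """
    arr = np.asarray(list(score_series), dtype=float)
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise ValueError("need a non-empty ensemble on a common time grid")
    a5, a50, a95 = np.percentile(arr, [5, 50, 95], axis=0)
    beta = ((a95 - a5) / 2.0) ** 2
    return float(np.mean(np.maximum(a50 - beta, 0.0)))
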