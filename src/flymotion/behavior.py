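"""Optomotor turning analysis: aggregation and quality control, declining-phase
slope, paired-edge percent recovery, and the two-control significance rule.

Yaw velocities in the direction of stimulus motion are positive; leftward
epochs are sign-inverted before pooling so mirror-symmetric presentations
average together. Flies walking forward slower than 3 mm/s, or turning
against the stimulus on average, are discarded. The temporal-resolution
statistic for paired edges is

    % recovery = (V_peak - V_lowest) / V_peak * 100,

with V_peak the mean of the eight highest trial-averaged yaw samples over
the first edge and V_lowest the mean of the eight lowest samples in the
first 0.25 s of the second edge, computed per fly before any group mean.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import BehaviorRecording

log = logging.getLogger(__name__)

MIN_FORWARD_MM_S = 3.0
DECEL_WINDOW_S = (0.45, 0.75)
N_EXTREME = 8

__all__ = [
    "NoSurvivingFliesError",
    "InsufficientDataError",
    "UndefinedRecoveryError",
    "UndefinedTestError",
    "FlyTrace",
    "RecoveryResult",
    "TTestResult",
    "aggregate_turning",
    "deceleration_slope",
    "percent_recovery",
    "controls_ttest",
]


class NoSurvivingFliesError(ValueError):
    """Every fly was rejected by quality control."""


class InsufficientDataError(ValueError):
    """Too few samples inside the analysis window."""


class UndefinedRecoveryError(ValueError):
    """V_peak <= 0: percent recovery is undefined for this fly."""


class UndefinedTestError(ValueError):
    """Both groups have zero variance; the t statistic is undefined."""


@dataclass
class FlyTrace:
    """Trial-averaged signed yaw of one fly, aligned to motion onset."""

    fly_id: str
    genotype: str
    yaw: np.ndarray  # [n_samples], signed (+ = with the stimulus)
    sample_rate: float
    n_epochs: int

    def time(self) -> np.ndarray:
        return np.arange(len(self.yaw)) / self.sample_rate


@dataclass
class RecoveryResult:
    fly_id: str
    v_peak: float
    v_lowest: float
    percent_recovery: float
    peak_window_s: tuple[float, float]
    lowest_window_s: tuple[float, float]


@dataclass
class TTestResult:
    p_control1: float
    p_control2: float
    significant: bool
    alpha: float


def aggregate_turning(
    recordings: list[BehaviorRecording],
    min_forward: float = MIN_FORWARD_MM_S,
    post_window: float = 1.5,
) -> tuple[list[FlyTrace], pd.DataFrame]:
    """Trial-average signed yaw per fly, rejecting QC violators.

    Leftward-epoch (direction -1) responses are sign-inverted, pooled with
    rightward ones, and averaged over epochs in a window from motion onset
    to motion end + ``post_window``. A fly is rejected when its mean forward
    speed is below ``min_forward`` mm/s (reason ``forward``) or its mean
    signed yaw over the motion windows is negative (reason ``opposite``).
    Returns (surviving fly traces, rejection report).
    """
    traces: list[FlyTrace] = []
    rejected = []
    for rec in recordings:
        rate = rec.sample_rate
        reasons = []
        if rec.forward.mean() < min_forward:
            reasons.append("forward")
        snippets = []
        signed_motion = []
        for row in rec.epochs.itertuples():
            i0 = int(round(row.t_start * rate))
            i1 = int(round((row.t_end + post_window) * rate))
            i1 = min(i1, len(rec.yaw))
            snip = rec.yaw[i0:i1] * row.direction
            snippets.append(snip)
            i_motion = int(round((row.t_end - row.t_start) * rate))
            signed_motion.append(snip[:i_motion])
        if signed_motion and np.concatenate(signed_motion).mean() < 0:
            reasons.append("opposite")
        if reasons:
            rejected.append(dict(fly_id=rec.fly_id, genotype=rec.genotype,
                                 reason="+".join(reasons)))
            continue
        n = min(len(s) for s in snippets)
        mean_yaw = np.mean([s[:n] for s in snippets], axis=0)
        traces.append(
            FlyTrace(rec.fly_id, rec.genotype, mean_yaw, rate,
                     n_epochs=len(snippets))
        )
    report = pd.DataFrame(rejected, columns=["fly_id", "genotype", "reason"])
    if not traces:
        raise NoSurvivingFliesError(
            f"all {len(recordings)} flies rejected: "
            f"{report['reason'].tolist()}"
        )
    return traces, report


def _window_slice(n: int, rate: float, t0: float, t1: float) -> slice:
    i0 = int(math.ceil(t0 * rate - 1e-9))
    i1 = int(math.ceil(t1 * rate - 1e-9))
    return slice(max(i0, 0), min(i1, n))


def deceleration_slope(
    trace: FlyTrace, window: tuple[float, float] = DECEL_WINDOW_S
) -> float:
    """OLS slope (deg/s per s) of the trial-averaged yaw over the declining
    phase, 0.45 - 0.75 s after motion onset by default."""
    sl = _window_slice(len(trace.yaw), trace.sample_rate, *window)
    y = trace.yaw[sl]
    if len(y) < 3:
        raise InsufficientDataError(
            f"only {len(y)} samples in window {window}"
        )
    t = (np.arange(sl.start, sl.stop)) / trace.sample_rate
    return float(np.polyfit(t, y, 1)[0])


def percent_recovery(
    trace: FlyTrace,
    edge_duration: float = 0.75,
    n_extreme: int = N_EXTREME,
    lowest_window: float = 0.25,
) -> RecoveryResult:
    """Per-fly paired-edge recovery statistic.

    V_peak is the mean of the ``n_extreme`` highest yaw samples over the
    first edge [0, D]; V_lowest the mean of the ``n_extreme`` lowest samples
    over the early second edge [D, D + 0.25 s]. Raises
    :class:`UndefinedRecoveryError` when V_peak <= 0 (the fly is excluded
    upstream, with a log entry)."""
    rate = trace.sample_rate
    D = edge_duration
    peak_w = (0.0, D)
    low_w = (D, D + lowest_window)
    y_peak = trace.yaw[_window_slice(len(trace.yaw), rate, *peak_w)]
    y_low = trace.yaw[_window_slice(len(trace.yaw), rate, *low_w)]
    if len(y_peak) < n_extreme or len(y_low) < n_extreme:
        raise InsufficientDataError(
            f"need >= {n_extreme} samples per window "
            f"(got {len(y_peak)} and {len(y_low)})"
        )
    v_peak = float(np.sort(y_peak)[-n_extreme:].mean())
    v_lowest = float(np.sort(y_low)[:n_extreme].mean())
    if v_peak <= 0:
        raise UndefinedRecoveryError(
            f"fly {trace.fly_id}: V_peak = {v_peak:.3g} <= 0"
        )
    return RecoveryResult(
        fly_id=trace.fly_id, v_peak=v_peak, v_lowest=v_lowest,
        percent_recovery=(v_peak - v_lowest) / v_peak * 100.0,
        peak_window_s=peak_w, lowest_window_s=low_w,
    )


def controls_ttest(
    experimental: np.ndarray,
    control1: np.ndarray,
    control2: np.ndarray,
    alpha: float = 0.05,
) -> TTestResult:
    """Two-control significance rule: two independent two-tailed Student's
    t tests (pooled variance); the experimental group is significant only
    when it differs from BOTH genetic controls at ``alpha``."""
    groups = [np.asarray(g, float) for g in (experimental, control1, control2)]
    if any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 flies per group")
    ps = []
    for ctrl in groups[1:]:
        if groups[0].std(ddof=1) == 0 and ctrl.std(ddof=1) == 0:
            raise UndefinedTestError("zero variance in both groups")
        ps.append(float(stats.ttest_ind(groups[0], ctrl, equal_var=True).pvalue))
    return TTestResult(
        p_control1=ps[0], p_control2=ps[1],
        significant=bool(ps[0] < alpha and ps[1] < alpha), alpha=alpha,
    )
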