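"""Fluorescence preprocessing: dF/F conversion, resampling, trial averaging.

dF/F = (F - F0) / F0 after background subtraction, with three baseline
conventions for F0: the mean of a non-stimulus epoch preceding stimulation,
the mean of the whole trace, or the mean over gray interleaves.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

F0_MODES = ("prestim_epoch", "whole_trace_mean", "gray_interleaves")

__all__ = [
    "DegenerateBaselineError",
    "ResponseTrace",
    "compute_dff",
    "resample_trace",
    "trial_average",
    "average_rois_then_flies",
]


class DegenerateBaselineError(ValueError):
    """Baseline fluorescence F0 <= 0 after background subtraction."""


@dataclass
class ResponseTrace:
    """Uniformly sampled response trace with its epoch alignment."""

    values: np.ndarray
    rate: float
    t0: float = 0.0
    epochs: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.rate

    @property
    def span(self) -> float:
        return (len(self.values) - 1) / self.rate

    def window(self, t_start: float, t_end: float) -> np.ndarray:
        """Values with t_start <= t < t_end (half-open, sample-aligned)."""
        i0 = int(math.ceil((t_start - self.t0) * self.rate - 1e-9))
        i1 = int(math.ceil((t_end - self.t0) * self.rate - 1e-9))
        return self.values[max(i0, 0) : max(i1, 0)]


def _estimate_f0(
    F: np.ndarray,
    rate: float,
    f0_mode: str,
    epochs: pd.DataFrame | None,
) -> float:
    if f0_mode == "whole_trace_mean":
        return float(F.mean())
    if epochs is None:
        raise ValueError(f"f0_mode {f0_mode!r} requires an epoch table")
    kind = "prestim" if f0_mode == "prestim_epoch" else "gray"
    sel = epochs[epochs["kind"] == kind]
    if sel.empty:
        raise ValueError(f"no {kind!r} epochs available for f0_mode {f0_mode!r}")
    chunks = []
    for row in sel.itertuples():
        i0 = int(round(row.onset_s * rate))
        i1 = int(round(row.offset_s * rate))
        chunks.append(F[i0:i1])
    return float(np.concatenate(chunks).mean())


def compute_dff(
    F: np.ndarray,
    background: float | np.ndarray = 0.0,
    f0_mode: str = "whole_trace_mean",
    rate: float = 1.0,
    epochs: pd.DataFrame | None = None,
    name: str = "trace",
) -> ResponseTrace:
    """Convert raw fluorescence to dF/F = (F - F0) / F0.

    The background signal is subtracted before F0 is estimated. ``f0_mode``
    selects the baseline estimator: mean over the pre-stimulus epoch, over
    the whole trace, or over gray interleaves (epoch table rows of kind
    ``prestim`` / ``gray`` respectively).
    """
    if f0_mode not in F0_MODES:
        raise ValueError(f"unknown f0_mode {f0_mode!r}; choose from {F0_MODES}")
    F = np.asarray(F, float) - background
    f0 = _estimate_f0(F, rate, f0_mode, epochs)
    if f0 <= 0:
        raise DegenerateBaselineError(
            f"baseline F0 = {f0:.4g} <= 0 for {name!r} ({f0_mode})"
        )
    return ResponseTrace(
        (F - f0) / f0, rate, epochs=epochs,
        meta={"f0": f0, "f0_mode": f0_mode},
    )


def resample_trace(
    trace: ResponseTrace,
    target_rate: float,
    mode: str = "interpolate",
    duration: float | None = None,
) -> ResponseTrace:
    """Linearly resample onto a uniform grid at ``target_rate``.

    The output grid is t0 + k / target_rate for k = 0 .. floor(span * rate)
    (or up to a requested ``duration``). ``extrapolate_hold`` repeats the
    edge values outside the original support, as used when stretching a
    trace onto the 20 Hz noise-stimulus clock; plain ``interpolate``
    refuses to leave the support.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if mode not in ("interpolate", "extrapolate_hold"):
        raise ValueError(f"unknown resampling mode {mode!r}")
    if len(trace.values) < 2:
        raise ValueError("need at least 2 samples to resample")
    span = duration if duration is not None else trace.span
    n_out = int(math.floor(span * target_rate + 1e-9)) + 1
    t_new = trace.t0 + np.arange(n_out) / target_rate
    if mode == "interpolate" and t_new[-1] > trace.t0 + trace.span + 1e-9:
        raise ValueError(
            "requested grid extends beyond the trace; use extrapolate_hold"
        )
    values = np.interp(t_new, trace.time, trace.values)  # holds edges
    meta = dict(trace.meta, resample_mode=mode, source_rate=trace.rate)
    return ResponseTrace(values, target_rate, t0=trace.t0,
                         epochs=trace.epochs, meta=meta)


def trial_average(traces) -> tuple[np.ndarray, int]:
    """Elementwise mean across aligned repeats; returns (mean, n_repeats)."""
    arr = np.asarray(list(traces), float)
    if arr.ndim == 0 or arr.shape[0] == 0:
        raise ValueError("trial_average requires at least one repeat")
    if arr.ndim == 1:
        arr = arr[None, :]
    return arr.mean(axis=0), arr.shape[0]


def average_rois_then_flies(
    traces_by_fly: dict[str, np.ndarray],
) -> tuple[np.ndarray, dict]:
    """Hierarchical averaging: repeats -> ROIs within fly -> flies.

    ``traces_by_fly`` maps fly id -> array [n_rois, n_repeats, n_samples]
    (already aligned). Returns the grand mean and the sample counts at each
    level, so group statistics can report n correctly.
    """
    if not traces_by_fly:
        raise ValueError("no flies to average")
    per_fly = {}
    counts = {}
    for fly, arr in traces_by_fly.items():
        arr = np.asarray(arr, float)
        if arr.ndim != 3 or arr.shape[0] == 0 or arr.shape[1] == 0:
            raise ValueError(f"fly {fly!r}: expected [n_rois, n_repeats, T]")
        per_fly[fly] = arr.mean(axis=1).mean(axis=0)
        counts[fly] = {"n_rois": arr.shape[0], "n_repeats": arr.shape[1]}
    grand = np.mean(list(per_fly.values()), axis=0)
    return grand, {"n_flies": len(per_fly), "per_fly": counts,
                   "fly_means": per_fly}
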