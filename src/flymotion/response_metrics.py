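"""Flash-response and direction-tuning metrics for single ROIs.

Flash responses are quantified as the difference between the mean dF/F in a
2 s window before light onset/offset and the peak response within 2 s after;
the decay constant comes from a single-term exponential fit (kept only if
negative). Direction tuning is summarized by the response-weighted circular
resultant

    L_dir = | sum_k R(theta_k) exp(i theta_k) / sum_k R(theta_k) |,

whose magnitude (1 - circular variance) measures tuning sharpness and whose
angle is the preferred direction.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .preprocessing import ResponseTrace

log = logging.getLogger(__name__)

__all__ = [
    "WindowError",
    "FlashMetrics",
    "TuningResult",
    "flash_metrics",
    "fit_decay_constant",
    "direction_tuning",
]


class WindowError(ValueError):
    """Trace does not cover the requested analysis window."""


@dataclass
class FlashMetrics:
    on_step: float
    off_step: float
    time_to_peak: float  # s from light onset
    decay_rate: float | None = None  # 1/s, negative when present


@dataclass
class TuningResult:
    responses_per_direction: np.ndarray
    angles_deg: np.ndarray
    ldir_magnitude: float
    tuning_angle: float  # deg in [0, 360)
    dsi: float


def _step(trace: ResponseTrace, t_event: float, window: float) -> float:
    """Signed extreme deviation from the pre-event mean within the post
    window; antisymmetric under trace negation."""
    pre = trace.window(t_event - window, t_event)
    post = trace.window(t_event, t_event + window)
    if len(pre) == 0 or len(post) == 0:
        raise WindowError(
            f"trace does not cover +/-{window} s around t = {t_event} s"
        )
    base = pre.mean()
    dev = post - base
    return float(dev[np.argmax(np.abs(dev))])


def flash_metrics(
    trace: ResponseTrace, t_on: float, t_off: float, window: float = 2.0
) -> FlashMetrics:
    """Step amplitudes at light onset/offset and the time to the ON peak.

    on_step (off_step) is the peak deviation within ``window`` s after the
    onset (offset) relative to the mean over ``window`` s before it;
    time_to_peak is the delay from onset to the response maximum over the
    ON epoch.
    """
    on_step = _step(trace, t_on, window)
    off_step = _step(trace, t_off, window)
    on_epoch = trace.window(t_on, t_off)
    if len(on_epoch) == 0:
        raise WindowError("empty ON epoch")
    i_peak = int(np.argmax(on_epoch))
    i_on = int(math.ceil((t_on - trace.t0) * trace.rate - 1e-9))
    t_peak = (max(i_on, 0) + i_peak) / trace.rate + trace.t0 - t_on
    return FlashMetrics(on_step=on_step, off_step=off_step,
                        time_to_peak=float(t_peak))


def fit_decay_constant(
    trace: ResponseTrace,
    t_on: float,
    fit_horizon: float = 3.0,
    anchor: str = "peak",
) -> float | None:
    """Exponential decay constant b of A*exp(b*t) fitted to the response
    after light onset; returned only if negative, else None.

    ``anchor='peak'`` starts the fitted segment at the ON-peak time (the
    decaying phase); ``anchor='onset'`` starts at the light onset. The fit
    window always ends at t_on + fit_horizon.
    """
    if anchor not in ("peak", "onset"):
        raise ValueError(f"unknown anchor {anchor!r}")
    seg = trace.window(t_on, t_on + fit_horizon)
    if len(seg) < 5:
        raise WindowError("need >= 5 samples in the decay-fit window")
    if anchor == "peak":
        i0 = int(np.argmax(seg))
        seg = seg[i0:]
        if len(seg) < 5:
            # peak at the window's end: nothing decays after it
            log.info("no decaying segment after the response peak")
            return None
    t = np.arange(len(seg)) / trace.rate
    a0 = seg[0] if seg[0] != 0 else (seg.max() or 1.0)
    try:
        popt, _ = curve_fit(
            lambda t, a, b: a * np.exp(b * t), t, seg,
            p0=(a0, -1.0), maxfev=5000,
        )
    except RuntimeError as err:
        log.info("decay fit did not converge: %s", err)
        return None
    b = float(popt[1])
    if b >= 0:
        return None
    return b


def direction_tuning(
    responses: np.ndarray, angles_deg: np.ndarray | None = None
) -> TuningResult | None:
    """Circular tuning vector from peak responses at each motion direction.

    Negative responses are clipped to zero before the vector sum (weights
    must be non-negative for the circular-variance reading). Returns None
    when every response is zero (tuning undefined). DSI uses the maximal
    response (PD) and the response at the angle closest to PD + 180 deg.
    """
    r = np.asarray(responses, float)
    if angles_deg is None:
        angles_deg = np.arange(len(r)) * 360.0 / len(r)
    angles_deg = np.asarray(angles_deg, float)
    if len(r) < 2:
        raise ValueError("need responses for at least 2 directions")
    if not np.all(np.isfinite(r)):
        raise ValueError("responses must be finite")
    r = np.clip(r, 0.0, None)
    total = r.sum()
    if total == 0:
        log.info("all-zero responses: tuning undefined")
        return None
    z = np.sum(r * np.exp(1j * np.radians(angles_deg))) / total
    i_pd = int(np.argmax(r))
    nd_target = (angles_deg[i_pd] + 180.0) % 360.0
    diff = np.abs((angles_deg - nd_target + 180.0) % 360.0 - 180.0)
    i_nd = int(np.argmin(diff))
    pd_val = r[i_pd]
    dsi = (pd_val - r[i_nd]) / pd_val if pd_val > 0 else np.nan
    return TuningResult(
        responses_per_direction=r,
        angles_deg=angles_deg,
        ldir_magnitude=float(np.abs(z)),
        tuning_angle=float(np.degrees(np.angle(z)) % 360.0),
        dsi=float(dsi),
    )
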