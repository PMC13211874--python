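"""Spatiotemporal receptive fields by reverse correlation against ternary noise.

The STRF is the response-weighted stimulus average over a 2 s window
propagated backwards in time: for lag tau and bar b,

    STRF[tau, b] = 1 / (T - n_lags) * sum_{t >= n_lags} r_t * s[t - tau, b],

with the response mean-centered and resampled to the 20 Hz stimulus clock.
Validity is judged by the squared Pearson correlation (R^2) between the
STRF-convolved stimulus and the measured response; STRFs below the 0.26
threshold are discarded, survivors are averaged with R^2 weights. The
temporal filter's ON-peak time and the spatial profile's Gaussian FWHM are
the summary statistics.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

from .synth import TernaryNoise

log = logging.getLogger(__name__)

R2_MIN = 0.26
CSI_MIN = 0.5
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

__all__ = [
    "AlignmentError",
    "InsufficientDataError",
    "STRF",
    "TemporalFilter",
    "SpatialProfile",
    "select_strf_pixels",
    "reverse_correlate",
    "predict_response",
    "strf_prediction_r2",
    "weighted_average_strf",
    "temporal_filter_metrics",
    "spatial_fwhm",
]


class AlignmentError(ValueError):
    """Response and stimulus are not aligned sample-for-sample."""


class InsufficientDataError(ValueError):
    """Fewer time points than the correlation window."""


@dataclass
class STRF:
    """Reverse-correlation filter: [n_lags x n_bars] correlation weights."""

    weights: np.ndarray
    lag_step: float  # s per lag (1 / update rate)
    orientation: str = "vertical"
    r2: float | None = None
    cell_id: str | None = None

    @property
    def n_lags(self) -> int:
        return self.weights.shape[0]

    @property
    def n_bars(self) -> int:
        return self.weights.shape[1]

    @property
    def lags_s(self) -> np.ndarray:
        return np.arange(self.n_lags) * self.lag_step


@dataclass
class TemporalFilter:
    values: np.ndarray
    lag_step: float
    on_peak_time: float | None  # s; None when the filter has no positive lobe


@dataclass
class SpatialProfile:
    values: np.ndarray
    bar_centers_deg: np.ndarray
    amplitude: float
    center_deg: float
    sigma_deg: float
    fwhm_deg: float
    sub_resolution: bool = False


def select_strf_pixels(
    features: pd.DataFrame, csi_min: float = CSI_MIN
) -> pd.DataFrame:
    """Contrast-selectivity pre-filter: only pixels whose CSI exceeds
    ``csi_min`` enter receptive-field estimation (clean T4/T5 responses)."""
    return features[features["csi"] > csi_min]


def reverse_correlate(
    response: np.ndarray,
    noise: TernaryNoise,
    window: float = 2.0,
    orientation: str | None = None,
    cell_id: str | None = None,
) -> STRF:
    """Reverse-correlation STRF of a mean-centered response against the noise.

    The 2 s window gives n_lags = window * update_rate lags; every lag sums
    the same T - n_lags response samples (t >= n_lags) and is normalized by
    that count, so the estimator is exactly linear in the response.
    """
    r = np.asarray(response, float)
    S = noise.values.astype(float)
    if len(r) != len(S):
        raise AlignmentError(
            f"response length {len(r)} != stimulus length {len(S)}"
        )
    n_lags = int(round(window * noise.update_rate))
    T = len(r)
    if T <= n_lags:
        raise InsufficientDataError(
            f"{T} samples <= {n_lags}-lag window"
        )
    r = r - r.mean()
    W = np.empty((n_lags, noise.n_bars))
    rv = r[n_lags:]
    for tau in range(n_lags):
        W[tau] = rv @ S[n_lags - tau : T - tau]
    W /= T - n_lags
    return STRF(W, 1.0 / noise.update_rate,
                orientation or noise.orientation, cell_id=cell_id)


def predict_response(strf: STRF, noise: TernaryNoise) -> np.ndarray:
    """Linear prediction sum_tau sum_b W[tau, b] * s[t - tau, b] for
    t >= n_lags (the first window is discarded to avoid edge effects)."""
    S = noise.values.astype(float)
    T = len(S)
    n_lags = strf.n_lags
    if T <= n_lags:
        raise InsufficientDataError(f"{T} samples <= {n_lags}-lag window")
    pred = np.zeros(T - n_lags)
    for tau in range(n_lags):
        pred += S[n_lags - tau : T - tau] @ strf.weights[tau]
    return pred


def strf_prediction_r2(
    strf: STRF, noise: TernaryNoise, response: np.ndarray
) -> float:
    """Squared Pearson correlation between the STRF prediction and the
    measured response over the valid range (t >= n_lags)."""
    r = np.asarray(response, float)
    if len(r) != noise.n_frames:
        raise AlignmentError(
            f"response length {len(r)} != stimulus length {noise.n_frames}"
        )
    pred = predict_response(strf, noise)
    meas = r[strf.n_lags :] - r.mean()
    if pred.std() == 0 or meas.std() == 0:
        log.warning("zero-variance prediction or response: R^2 = 0")
        return 0.0
    return float(pearsonr(pred, meas)[0] ** 2)


def weighted_average_strf(
    strfs: list[STRF], r2_min: float = R2_MIN, align: bool = False
) -> tuple[STRF | None, dict]:
    """R^2-weighted average of valid STRFs.

    STRFs with r2 < ``r2_min`` are discarded; with ``align`` each survivor
    is shifted along the bar axis (zero-padded) so its maximal-|weight| bar
    sits at the center bar before averaging. Returns (average or None, a
    report with the surviving / discarded counts).
    """
    valid = [s for s in strfs if s.r2 is not None and s.r2 >= r2_min]
    report = {"n_input": len(strfs), "n_valid": len(valid),
              "n_discarded": len(strfs) - len(valid)}
    if not valid:
        log.warning("no STRFs passed the R^2 >= %g filter", r2_min)
        return None, report
    n_bars = valid[0].n_bars
    center = n_bars // 2
    acc = np.zeros_like(valid[0].weights)
    wsum = 0.0
    for s in valid:
        w = s.weights
        if align:
            peak_bar = int(
                np.unravel_index(np.argmax(np.abs(w)), w.shape)[1]
            )
            shifted = np.zeros_like(w)
            shift = center - peak_bar
            if shift >= 0:
                shifted[:, shift:] = w[:, : n_bars - shift]
            else:
                shifted[:, :shift] = w[:, -shift:]
            w = shifted
        acc += s.r2 * w
        wsum += s.r2
    return STRF(acc / wsum, valid[0].lag_step, valid[0].orientation), report


def temporal_filter_metrics(strf: STRF, mode: str = "center_bar") -> TemporalFilter:
    """Temporal filter of an STRF and its ON-peak latency.

    ``center_bar`` takes the time course at the maximal-|weight| bar
    (consistent with the spatial-FWHM slice); ``bar_average`` takes the
    mean over bars. The ON peak is the lag of the highest positive
    correlation; a filter with no positive lobe has no ON peak.
    """
    if mode == "center_bar":
        bar = int(np.unravel_index(np.argmax(np.abs(strf.weights)),
                                   strf.weights.shape)[1])
        values = strf.weights[:, bar].copy()
    elif mode == "bar_average":
        values = strf.weights.mean(axis=1)
    else:
        raise ValueError(f"unknown temporal-filter mode {mode!r}")
    if values.max() <= 0:
        log.warning("temporal filter has no positive lobe: ON peak undefined")
        return TemporalFilter(values, strf.lag_step, None)
    on_peak = float(np.argmax(values) * strf.lag_step)
    return TemporalFilter(values, strf.lag_step, on_peak)


def spatial_fwhm(
    strf: STRF, bar_width: float = 5.0
) -> SpatialProfile | None:
    """Gaussian fit along the spatial slice of maximal response.

    The slice is the lag row holding the global maximum |weight|; bars sit
    at ``bar_width`` spacing in degrees. FWHM = 2 sqrt(2 ln 2) sigma.
    Profiles narrower than one bar are flagged sub-resolution. Returns None
    if the fit diverges.
    """
    if strf.n_bars < 4:
        raise ValueError("need >= 4 bars for a spatial fit")
    tau, _ = np.unravel_index(np.argmax(np.abs(strf.weights)),
                              strf.weights.shape)
    slice_ = strf.weights[tau]
    x = (np.arange(strf.n_bars) + 0.5) * bar_width
    i0 = int(np.argmax(np.abs(slice_)))
    p0 = (slice_[i0], x[i0], 2.0 * bar_width)
    try:
        popt, _ = curve_fit(
            lambda x, a, mu, sig: a * np.exp(-0.5 * ((x - mu) / sig) ** 2),
            x, slice_, p0=p0, maxfev=5000,
        )
    except RuntimeError as err:
        log.info("spatial Gaussian fit diverged: %s", err)
        return None
    a, mu, sigma = popt
    sigma = abs(float(sigma))
    fwhm = FWHM_PER_SIGMA * sigma
    return SpatialProfile(
        values=slice_, bar_centers_deg=x, amplitude=float(a),
        center_deg=float(mu), sigma_deg=sigma, fwhm_deg=float(fwhm),
        sub_resolution=fwhm <= bar_width,
    )
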