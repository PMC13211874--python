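"""Automated axon-terminal segmentation for direction-selective neurons.

The stages mirror how T4/T5 terminals are isolated from a motion-stimulus
recording: Otsu foreground detection on the smoothed mean image, a
responsiveness filter (peak > mean + k.SD of the trial-averaged trace),
per-pixel direction/contrast selectivity indices, and average-linkage
hierarchical clustering of (x, y, PD-response timing) features with the
cut height chosen to maximize the number of clusters of terminal size
(1 - 6.5 um^2). Clusters outside that size range are discarded.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import gaussian_filter

log = logging.getLogger(__name__)

AREA_RANGE_UM2 = (1.0, 6.5)

__all__ = [
    "DegenerateImageError",
    "GeometryError",
    "ROICluster",
    "otsu_threshold",
    "foreground_mask",
    "pixel_selectivity",
    "cluster_terminals",
    "match_clusters",
    "extract_cluster_traces",
]


class DegenerateImageError(ValueError):
    """Image has no intensity variation to threshold."""


class GeometryError(ValueError):
    """Pixel grids of two recordings do not match."""


# ---------------------------------------------------------------------------
# Foreground detection
# ---------------------------------------------------------------------------

def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold over an equal-width histogram of the observed range.

    Returns the bin edge maximizing the between-class variance
    w0 * w1 * (mu0 - mu1)^2 over all nbins - 1 cut points; ties are broken
    by the lowest qualifying edge. Foreground is ``values > threshold``.
    """
    v = np.asarray(values, float).ravel()
    vmin, vmax = float(v.min()), float(v.max())
    if vmax <= vmin:
        raise DegenerateImageError("constant input has no threshold")
    hist, edges = np.histogram(v, bins=nbins, range=(vmin, vmax))
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = hist / hist.sum()
    w0 = np.cumsum(p)[:-1]  # cut after bin k, k = 0 .. nbins-2
    w1 = 1.0 - w0
    csum = np.cumsum(p * centers)
    total = csum[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = csum[:-1] / w0
        mu1 = (total - csum[:-1]) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where(np.isfinite(sigma_b), sigma_b, -np.inf)
    k = int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximum
    return float(edges[k + 1])


def foreground_mask(frames: np.ndarray, sigma: float = 1.5) -> np.ndarray:
    """Foreground pixels: Gaussian-smoothed (sigma px) time-mean image
    thresholded by Otsu's method."""
    frames = np.asarray(frames, float)
    if frames.size == 0:
        raise DegenerateImageError("empty movie")
    mean_img = gaussian_filter(frames.mean(axis=0), sigma)
    return mean_img > otsu_threshold(mean_img)


# ---------------------------------------------------------------------------
# Per-pixel selectivity features
# ---------------------------------------------------------------------------

def _pixel_dff(
    F: np.ndarray,
    rate: float,
    epochs: pd.DataFrame,
    f0_mode: str,
    background: float,
) -> tuple[np.ndarray, np.ndarray]:
    """dF/F per pixel column; returns (dff, keep mask of valid baselines)."""
    F = F - background
    if f0_mode == "whole_trace_mean":
        f0 = F.mean(axis=0)
    elif f0_mode in ("prestim_epoch", "gray_interleaves"):
        kind = "prestim" if f0_mode == "prestim_epoch" else "gray"
        sel = epochs[epochs["kind"] == kind]
        if sel.empty:
            raise ValueError(f"no {kind!r} epochs for f0_mode {f0_mode!r}")
        idx = []
        for row in sel.itertuples():
            idx.extend(range(int(round(row.onset_s * rate)),
                             int(round(row.offset_s * rate))))
        f0 = F[idx].mean(axis=0)
    else:
        raise ValueError(f"unknown f0_mode {f0_mode!r}")
    keep = f0 > 0
    if not keep.all():
        log.warning("dropping %d pixels with non-positive baseline",
                    int((~keep).sum()))
    dff = np.zeros_like(F)
    dff[:, keep] = (F[:, keep] - f0[keep]) / f0[keep]
    return dff, keep


def pixel_selectivity(
    frames: np.ndarray,
    rate: float,
    epochs: pd.DataFrame,
    k_sd: float = 2.0,
    foreground: np.ndarray | None = None,
    f0_mode: str = "prestim_epoch",
    background: float = 0.0,
    layer_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-pixel tuning features from a four-direction ON/OFF edge recording.

    Pixels must exceed the responsiveness criterion -- peak of the
    trial-averaged trace larger than its mean + ``k_sd`` standard deviations
    (k_sd = 2 for tuning, 3 for receptive-field mapping). For survivors the
    preferred direction (PD) is the direction of maximal peak dF/F at the
    preferred contrast, ND the direction 180 deg opposite, and

        DSI = (PD - ND) / PD,    CSI = (PC - NC) / PC.

    Pixels with PD = 0 or PC = 0 have undefined indices and are dropped
    (count logged). Returns one row per surviving pixel with columns
    x, y, dsi, csi, pd_angle, t_pd_peak, contrast_class, layer, peak.
    """
    frames = np.asarray(frames, float)
    if foreground is None:
        foreground = foreground_mask(frames)
    ys, xs = np.nonzero(foreground)
    if len(ys) == 0:
        return pd.DataFrame(
            columns=["x", "y", "dsi", "csi", "pd_angle", "t_pd_peak",
                     "contrast_class", "layer", "peak"]
        )
    F = frames[:, ys, xs]
    dff, keep = _pixel_dff(F, rate, epochs, f0_mode, background)

    motion = epochs[epochs["kind"].isin(["edge", "bar"])]
    if motion.empty:
        raise ValueError("epoch table contains no motion epochs")
    conditions: dict[tuple[float, float], np.ndarray] = {}
    for (d, c), grp in motion.groupby(["direction", "contrast"]):
        windows = []
        for row in grp.itertuples():
            i0 = int(round(row.onset_s * rate))
            i1 = int(round(row.offset_s * rate))
            windows.append(dff[i0:i1])
        n = min(len(w) for w in windows)
        conditions[(float(d), float(c))] = np.mean(
            [w[:n] for w in windows], axis=0
        )
    directions = sorted({d for d, _ in conditions})
    contrasts = sorted({c for _, c in conditions})

    # responsiveness filter: the peak of the trial-averaged trace must beat
    # the mean + k_sd standard deviations of the full (unaveraged) trace --
    # trial averaging shrinks a noise-only peak by sqrt(n_repeats), so pixels
    # without a repeatable response fail while true responses pass easily
    full = np.concatenate(
        [conditions[k] for k in sorted(conditions)], axis=0
    )
    peak = full.max(axis=0)
    responsive = keep & (peak > dff.mean(axis=0) + k_sd * dff.std(axis=0))

    # peak response per (direction, contrast)
    resp = {k: v.max(axis=0) for k, v in conditions.items()}
    n_px = len(ys)
    per_contrast = {
        c: np.max([resp[(d, c)] for d in directions], axis=0)
        for c in contrasts
    }
    rows = []
    n_undefined = 0
    for j in range(n_px):
        if not responsive[j]:
            continue
        pc_val = max(per_contrast[c][j] for c in contrasts)
        c_pref = max(contrasts, key=lambda c: per_contrast[c][j])
        nc_val = min(per_contrast[c][j] for c in contrasts) if len(contrasts) > 1 else np.nan
        r_dir = {d: resp[(d, c_pref)][j] for d in directions}
        pd_angle = max(r_dir, key=r_dir.get)
        nd_angle = (pd_angle + 180.0) % 360.0
        pd_val = r_dir[pd_angle]
        nd_val = r_dir.get(nd_angle, np.nan)
        if pd_val <= 0 or pc_val <= 0:
            n_undefined += 1
            continue
        cond = conditions[(pd_angle, c_pref)]
        rows.append(
            dict(
                x=int(xs[j]), y=int(ys[j]),
                dsi=(pd_val - nd_val) / pd_val,
                csi=(pc_val - nc_val) / pc_val,
                pd_angle=float(pd_angle),
                t_pd_peak=int(np.argmax(cond[:, j])),
                contrast_class="ON" if c_pref > 0 else "OFF",
                layer=(
                    str(layer_mask[ys[j], xs[j]])
                    if layer_mask is not None else "unassigned"
                ),
                peak=float(peak[j]),
            )
        )
    if n_undefined:
        log.info("dropped %d pixels with PD=0 or PC=0", n_undefined)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Area-constrained hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class ROICluster:
    """One retained terminal cluster (feature-space; connectivity not required)."""

    pixels: np.ndarray  # [n, 2] (row, col)
    area: float  # um^2
    centroid: tuple[float, float]  # (row, col)
    contrast_class: str
    layer: str
    cluster_id: str


def _best_cut(
    Z: np.ndarray, n_points: int, pixel_size: float,
    area_range: tuple[float, float],
) -> tuple[float, np.ndarray]:
    """Scan every merge height; return (height, labels) maximizing the count
    of clusters whose area lies in area_range. Ties take the smallest height."""
    lo, hi = area_range
    candidates = np.concatenate([[0.0], np.unique(Z[:, 2])])
    best = (-1, 0.0, None)
    for h in candidates:
        labels = fcluster(Z, t=h, criterion="distance")
        sizes = np.bincount(labels)[1:]
        areas = sizes * pixel_size**2
        count = int(((areas >= lo) & (areas <= hi)).sum())
        if count > best[0]:
            best = (count, h, labels)
    return best[1], best[2]


def cluster_terminals(
    features: pd.DataFrame,
    pixel_size: float,
    area_range: tuple[float, float] = AREA_RANGE_UM2,
    time_weight: float = 1.0,
) -> tuple[list[ROICluster], dict]:
    """Group selective pixels into terminal-sized ROIs.

    Clustering runs separately per (contrast_class, layer) group on the
    feature vector (x, y, time_weight * t_pd_peak) with average-linkage
    agglomerative clustering. The cut height is chosen among all merge
    heights to maximize the number of clusters whose area
    (n_pixels * pixel_size^2) falls within ``area_range``; clusters outside
    the range are excluded. Returns (clusters, chosen cut height per group).
    """
    lo, hi = area_range
    clusters: list[ROICluster] = []
    cut_heights: dict[tuple[str, str], float] = {}
    if features.empty:
        return clusters, cut_heights
    for (contrast, layer), grp in features.groupby(["contrast_class", "layer"]):
        # canonical row order makes the dendrogram, and therefore the
        # partition, independent of input order even under distance ties
        grp = grp.sort_values(["y", "x", "t_pd_peak"]).reset_index(drop=True)
        X = np.column_stack(
            [grp["x"], grp["y"], time_weight * grp["t_pd_peak"]]
        ).astype(float)
        if len(grp) == 1:
            labels = np.array([1])
            height = 0.0
        else:
            Z = linkage(X, method="average")
            height, labels = _best_cut(Z, len(grp), pixel_size, area_range)
        cut_heights[(contrast, layer)] = float(height)
        group_clusters = []
        for lab in np.unique(labels):
            idx = np.nonzero(labels == lab)[0]
            area = len(idx) * pixel_size**2
            if not (lo <= area <= hi):
                continue
            px = grp.loc[idx, ["y", "x"]].to_numpy(int)
            group_clusters.append(
                (px, area, (float(px[:, 0].mean()), float(px[:, 1].mean())))
            )
        if not group_clusters:
            log.warning(
                "group (%s, %s): no clusters within %g-%g um^2",
                contrast, layer, lo, hi,
            )
        group_clusters.sort(key=lambda t: t[2])
        for k, (px, area, cen) in enumerate(group_clusters):
            clusters.append(
                ROICluster(px, area, cen, contrast, layer,
                           f"{contrast}_{layer}_{k:03d}")
            )
    return clusters, cut_heights


def match_clusters(
    clusters: list[ROICluster],
    frames2: np.ndarray,
    foreground2: np.ndarray | None = None,
) -> tuple[list[ROICluster], pd.DataFrame]:
    """Re-apply saved cluster masks to a second recording of the same cells.

    The grids must be identical; masks carry over by pixel identity. The
    report lists, per cluster, how many of its pixels fall outside the
    second recording's foreground.
    """
    if clusters and (
        frames2.ndim != 3
        or frames2.shape[1] <= max(c.pixels[:, 0].max() for c in clusters)
        or frames2.shape[2] <= max(c.pixels[:, 1].max() for c in clusters)
    ):
        raise GeometryError(
            f"second recording grid {frames2.shape[1:]} does not cover the "
            "saved cluster masks"
        )
    if foreground2 is None:
        foreground2 = foreground_mask(frames2)
    rows = []
    for c in clusters:
        outside = int((~foreground2[c.pixels[:, 0], c.pixels[:, 1]]).sum())
        rows.append(dict(cluster_id=c.cluster_id, n_pixels=len(c.pixels),
                         n_outside_foreground=outside))
    return clusters, pd.DataFrame(rows)


def extract_cluster_traces(
    frames: np.ndarray, clusters: list[ROICluster]
) -> np.ndarray:
    """Mean fluorescence trace over each cluster's pixels: [n_clusters, T]."""
    out = np.empty((len(clusters), frames.shape[0]))
    for i, c in enumerate(clusters):
        out[i] = frames[:, c.pixels[:, 0], c.pixels[:, 1]].mean(axis=1)
    return out
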