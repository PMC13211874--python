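"""Synthetic study generator: stimuli, model neurons, movies, behavior, synapse tables.

Every downstream stage of the pipeline (dF/F preprocessing, terminal
segmentation, tuning metrics, receptive-field mapping, optomotor behavior,
connectome summaries) is exercised against data produced here, with the
ground truth planted and recorded so recovery can be verified exactly.

Conventions used throughout the package:

* Screen coordinates are degrees of visual angle, azimuth 0..80 and
  elevation 0..55, discretized at 1 degree per cell by default.
* Motion directions are angles in degrees, counterclockwise, with 0 deg
  meaning rightward motion (increasing azimuth).
* Contrast is unitless in [-1, 1]; 0 is the mean-gray background.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCREEN_AZIMUTH_DEG = 80.0
SCREEN_ELEVATION_DEG = 55.0
GRID_STEP_DEG = 1.0

__all__ = [
    "ParameterError",
    "PlacementError",
    "DimensionError",
    "StimulusSpec",
    "TernaryNoise",
    "NeuronModel",
    "Terminal",
    "GroundTruthMovie",
    "BehaviorRecording",
    "TurningKernel",
    "EdgeEpochDesign",
    "biphasic_filter",
    "screen_grid",
    "make_ternary_noise",
    "make_motion_stimuli",
    "simulate_ln_response",
    "place_terminals",
    "render_terminal_movie",
    "control_kernel",
    "sustained_kernel",
    "simulate_turning_traces",
    "make_synapse_fixture",
    "SYNAPSE_TABLE_COLUMNS",
]


class ParameterError(ValueError):
    """Invalid stimulus or model parameter."""


class PlacementError(ValueError):
    """Terminal placements overlap or fall outside the frame."""


class DimensionError(ValueError):
    """Spatial receptive field does not match the stimulus grid."""


# ---------------------------------------------------------------------------
# Stimuli
# ---------------------------------------------------------------------------

@dataclass
class StimulusSpec:
    """Parameterization of one visual stimulus protocol.

    kind is one of ``flash`` (full-field ON/OFF alternation, 5 s each),
    ``edge`` (full-contrast moving edge), ``bar`` (moving bar of
    ``bar_width`` deg), ``ternary_noise`` or ``behavior_edge``.
    """

    kind: str
    duration: float = 120.0
    frame_rate: float = 15.0
    bar_width: float = 5.0
    speed: float = 20.0
    directions: tuple[float, ...] = (0.0, 90.0, 180.0, 270.0)
    contrast_values: tuple[float, ...] = (1.0, -1.0)
    n_repeats: int = 1
    flash_half_period: float = 5.0
    prestim: float = 2.0
    interleave: float = 1.0
    seed: int | None = None

    _KINDS = ("flash", "edge", "bar", "ternary_noise", "behavior_edge")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ParameterError(f"unknown stimulus kind {self.kind!r}")
        if self.duration <= 0:
            raise ParameterError("duration must be positive")
        if self.frame_rate <= 0:
            raise ParameterError("frame_rate must be positive")
        for d in self.directions:
            if not (0.0 <= d < 360.0):
                raise ParameterError(f"direction {d} outside [0, 360)")


@dataclass
class TernaryNoise:
    """Ternary white-noise stimulus: time x bars matrix with entries in {-1, 0, 1}.

    Bars are 5 x 60 deg stripes tiled along azimuth (``vertical`` bars) or
    elevation (``horizontal``); each bar flips independently at
    ``update_rate`` with equal probability of dark, gray, bright.
    """

    values: np.ndarray
    update_rate: float
    orientation: str = "vertical"
    bar_size: tuple[float, float] = (5.0, 60.0)
    seed: int | None = None

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_bars(self) -> int:
        return self.values.shape[1]

    @property
    def bar_centers(self) -> np.ndarray:
        """Bar-center coordinates in degrees along the tiling axis."""
        w = self.bar_size[0]
        return (np.arange(self.n_bars) + 0.5) * w

    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.update_rate


def make_ternary_noise(
    n_bars: int,
    update_rate: float,
    duration: float,
    orientation: str = "vertical",
    seed: int | None = None,
    bar_size: tuple[float, float] = (5.0, 60.0),
) -> TernaryNoise:
    """Draw an iid ternary noise sequence, each entry uniform over {-1, 0, 1}."""
    if n_bars < 1:
        raise ParameterError("n_bars must be >= 1")
    if duration <= 0 or update_rate <= 0:
        raise ParameterError("duration and update_rate must be positive")
    n_frames = int(round(duration * update_rate))
    if n_frames < 1:
        raise ParameterError("duration x update_rate must be >= 1 frame")
    if orientation not in ("vertical", "horizontal"):
        raise ParameterError(f"unknown orientation {orientation!r}")
    rng = np.random.default_rng(seed)
    values = rng.integers(0, 3, size=(n_frames, n_bars)).astype(np.int8) - 1
    return TernaryNoise(values, update_rate, orientation, bar_size, seed)


def screen_grid(step: float = GRID_STEP_DEG) -> tuple[np.ndarray, np.ndarray]:
    """Cell-center coordinates (azimuth, elevation) of the projection screen."""
    az = np.arange(step / 2, SCREEN_AZIMUTH_DEG, step)
    el = np.arange(step / 2, SCREEN_ELEVATION_DEG, step)
    return az, el


def _motion_epoch_frames(
    direction: float,
    contrast: float,
    speed: float,
    az: np.ndarray,
    el: np.ndarray,
    rate: float,
    bar_width: float | None,
) -> np.ndarray:
    """Frames of one edge (bar_width None) or bar traversal across the screen."""
    th = math.radians(direction)
    # snap the direction cosines so cardinal directions are exactly axis-
    # aligned (sin(pi) is 1.2e-16, enough to flip boundary-cell inclusion
    # asymmetrically between mirror-image directions)
    cos_th = round(math.cos(th), 12)
    sin_th = round(math.sin(th), 12)
    proj = az[None, :] * cos_th + el[:, None] * sin_th
    pmin, pmax = float(proj.min()), float(proj.max())
    travel = pmax - pmin + (bar_width or 0.0)
    n = max(1, int(math.ceil(travel / speed * rate)))
    front = pmin + speed * (np.arange(n) + 1) / rate
    if bar_width is None:
        lit = proj[None, :, :] <= front[:, None, None]
    else:
        lit = (proj[None, :, :] <= front[:, None, None]) & (
            proj[None, :, :] > (front[:, None, None] - bar_width)
        )
    return np.where(lit, np.float32(contrast), np.float32(0.0))


def make_motion_stimuli(
    spec: StimulusSpec, grid_step: float = GRID_STEP_DEG
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a stimulus movie on the screen grid plus its epoch table.

    Returns ``(frames, epochs)`` with frames of shape [T, n_el, n_az]
    (float32 contrast, gray = 0) and an epoch table with columns
    onset_s, offset_s, kind, direction, contrast, repeat. Gray interleaves
    separate motion epochs, and a pre-stimulus gray period opens the movie.
    Per repeat block the (direction, contrast) order is a seeded uniform
    shuffle.
    """
    az, el = screen_grid(grid_step)
    rate = spec.frame_rate
    rng = np.random.default_rng(spec.seed)
    segs: list[np.ndarray] = []
    rows: list[dict] = []
    t = 0.0
    shape = (len(el), len(az))

    def gray(duration: float, kind: str) -> None:
        nonlocal t
        n = int(round(duration * rate))
        if n > 0:
            segs.append(np.zeros((n,) + shape, np.float32))
            rows.append(
                dict(onset_s=t, offset_s=t + n / rate, kind=kind,
                     direction=np.nan, contrast=0.0, repeat=-1)
            )
            t += n / rate

    if spec.kind == "flash":
        gray(spec.prestim, "prestim")
        n_half = int(round(spec.flash_half_period * rate))
        n_cycles = int(spec.duration // (2 * spec.flash_half_period))
        if n_cycles < 1:
            raise ParameterError("duration shorter than one flash cycle")
        for c in range(n_cycles):
            for contrast in (1.0, -1.0):
                segs.append(np.full((n_half,) + shape, np.float32(contrast)))
                rows.append(
                    dict(onset_s=t, offset_s=t + n_half / rate, kind="flash",
                         direction=np.nan, contrast=contrast, repeat=c)
                )
                t += n_half / rate
    elif spec.kind in ("edge", "bar"):
        gray(spec.prestim, "prestim")
        width = spec.bar_width if spec.kind == "bar" else None
        combos = [(d, c) for d in spec.directions for c in spec.contrast_values]
        for rep in range(spec.n_repeats):
            order = list(combos)
            rng.shuffle(order)
            for direction, contrast in order:
                frames = _motion_epoch_frames(
                    direction, contrast, spec.speed, az, el, rate, width
                )
                segs.append(frames)
                rows.append(
                    dict(onset_s=t, offset_s=t + len(frames) / rate,
                         kind=spec.kind, direction=direction,
                         contrast=contrast, repeat=rep)
                )
                t += len(frames) / rate
                gray(spec.interleave, "gray")
    else:
        raise ParameterError(
            f"kind {spec.kind!r} is not a screen movie stimulus"
        )

    movie = np.concatenate(segs, axis=0)
    epochs = pd.DataFrame(rows)
    return movie, epochs


# ---------------------------------------------------------------------------
# LN model neurons
# ---------------------------------------------------------------------------

def biphasic_filter(
    rate: float,
    duration: float = 1.0,
    t_on: float = 0.10,
    sigma_on: float = 0.05,
    t_off: float = 0.35,
    sigma_off: float = 0.12,
    off_gain: float = 0.5,
) -> np.ndarray:
    """Biphasic temporal impulse response: fast positive (ON) lobe followed
    by a delayed negative (OFF) lobe, peak-normalized to 1."""
    t = np.arange(int(round(duration * rate))) / rate
    f = np.exp(-0.5 * ((t - t_on) / sigma_on) ** 2)
    f -= off_gain * np.exp(-0.5 * ((t - t_off) / sigma_off) ** 2)
    return f / np.abs(f).max()


@dataclass
class NeuronModel:
    """Linear-nonlinear model neuron with calcium-indicator dynamics.

    The stimulus is passed through a Gaussian spatial receptive field and a
    biphasic temporal filter, scaled by direction/contrast tuning, optionally
    half-wave rectified at ``rectifier_threshold`` (None disables the
    nonlinearity), convolved with a single-exponential calcium kernel of
    time constant ``calcium_tau``, and reported as dF/F.

    ``dsi_true``/``csi_true`` are the planted selectivity indices: the null
    direction and non-preferred contrast scale the drive by (1 - index), so
    the (PD-ND)/PD and (PC-NC)/PC estimators recover them exactly in the
    noiseless threshold-zero regime.
    """

    temporal_filter: np.ndarray
    filter_rate: float
    rf_center: tuple[float, float] = (40.0, 27.5)
    rf_sigma: float = 6.0
    pref_direction: float = 0.0
    dsi_true: float = 1.0
    contrast_pref: str = "ON"
    csi_true: float = 1.0
    rectifier_threshold: float | None = 0.0
    calcium_tau: float = 0.25
    gain: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dsi_true <= 1.0 and 0.0 <= self.csi_true <= 1.0):
            raise ParameterError("dsi_true and csi_true must lie in [0, 1]")
        if self.calcium_tau <= 0:
            raise ParameterError("calcium_tau must be positive")
        if self.contrast_pref not in ("ON", "OFF"):
            raise ParameterError("contrast_pref must be 'ON' or 'OFF'")
        self.temporal_filter = np.asarray(self.temporal_filter, float)
        if not np.all(np.isfinite(self.temporal_filter)):
            raise ParameterError("temporal_filter must be finite")

    # -- derived filters ----------------------------------------------------

    def calcium_kernel(self) -> np.ndarray:
        """Unit-area single-exponential indicator kernel at the filter rate."""
        n = max(1, int(math.ceil(6 * self.calcium_tau * self.filter_rate)))
        t = np.arange(n) / self.filter_rate
        k = np.exp(-t / self.calcium_tau)
        return k / k.sum()

    def effective_temporal_filter(self, n_lags: int | None = None) -> np.ndarray:
        """Temporal filter as seen through the calcium indicator."""
        f = np.convolve(self.temporal_filter, self.calcium_kernel())
        if n_lags is not None:
            out = np.zeros(n_lags)
            m = min(n_lags, len(f))
            out[:m] = f[:m]
            return out
        return f

    def spatial_weights_bars(self, noise: TernaryNoise) -> np.ndarray:
        """Gaussian receptive-field weight of each noise bar (max 1)."""
        mu = self.rf_center[0] if noise.orientation == "vertical" else self.rf_center[1]
        c = noise.bar_centers
        return np.exp(-0.5 * ((c - mu) / self.rf_sigma) ** 2)

    def spatial_weights_screen(
        self, az: np.ndarray, el: np.ndarray
    ) -> np.ndarray:
        """2-D Gaussian weights on the screen grid, normalized to sum 1 so a
        full-field unit stimulus drives the cell with amplitude 1."""
        g = np.exp(
            -0.5 * ((az[None, :] - self.rf_center[0]) / self.rf_sigma) ** 2
            - 0.5 * ((el[:, None] - self.rf_center[1]) / self.rf_sigma) ** 2
        )
        return g / g.sum()

    def effective_strf(self, noise: TernaryNoise, n_lags: int) -> np.ndarray:
        """Ground-truth separable linear filter [n_lags x n_bars] from the
        noise stimulus to measured dF/F (temporal filter x indicator kernel,
        outer product with the bar weights, times gain)."""
        tf = self.effective_temporal_filter(n_lags)
        return self.gain * np.outer(tf, self.spatial_weights_bars(noise))

    def direction_gain(self, direction: float) -> float:
        """Raised-cosine tuning: 1 at the preferred direction, (1 - dsi_true)
        at the null, interpolated by (1 + cos) / 2 of the angular distance."""
        d = math.radians(direction - self.pref_direction)
        return (1.0 - self.dsi_true) + self.dsi_true * 0.5 * (1.0 + math.cos(d))

    def contrast_gain(self, contrast: float) -> float:
        if contrast == 0:
            return 1.0
        preferred = (contrast > 0) == (self.contrast_pref == "ON")
        return 1.0 if preferred else (1.0 - self.csi_true)


def simulate_ln_response(
    model: NeuronModel,
    stimulus,
    epochs: pd.DataFrame | None = None,
    rate: float | None = None,
    spatial_weights: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    rectify: bool = True,
    calcium: bool = True,
) -> np.ndarray:
    """Response trace (dF/F units) of one model neuron at the stimulus rate.

    ``stimulus`` is a :class:`TernaryNoise`, a raw [T x n_units] drive matrix
    (``spatial_weights`` then selects units; ``rate`` required), or a screen
    movie [T x n_el x n_az] (epoch table required for direction/contrast
    modulation). ``rectify=False`` / ``calcium=False`` bypass the
    nonlinearity and indicator stages for linearity checks.
    """
    if isinstance(stimulus, TernaryNoise):
        rate = stimulus.update_rate
        w = (
            spatial_weights
            if spatial_weights is not None
            else model.spatial_weights_bars(stimulus)
        )
        w = np.asarray(w, float)
        if w.shape != (stimulus.n_bars,):
            raise DimensionError(
                f"spatial weights {w.shape} do not match {stimulus.n_bars} bars"
            )
        drive = stimulus.values.astype(float) @ w
    else:
        stim = np.asarray(stimulus, float)
        if stim.ndim == 2:
            if rate is None:
                raise ParameterError("rate required for a raw drive matrix")
            if spatial_weights is None:
                raise DimensionError("spatial_weights required for a raw matrix")
            w = np.asarray(spatial_weights, float)
            if w.shape != (stim.shape[1],):
                raise DimensionError(
                    f"spatial weights {w.shape} do not match stimulus {stim.shape}"
                )
            drive = stim @ w
        elif stim.ndim == 3:
            if rate is None:
                raise ParameterError("rate required for a screen movie")
            az, el = screen_grid()
            if stim.shape[1:] != (len(el), len(az)):
                raise DimensionError(
                    f"movie grid {stim.shape[1:]} does not match the screen "
                    f"grid {(len(el), len(az))}"
                )
            w2 = model.spatial_weights_screen(az, el)
            # screen movies (edges, bars, flashes) drive the cell by
            # unsigned contrast; ON/OFF selectivity enters through the
            # per-epoch contrast gain below, so OFF-preferring cells respond
            # to dark stimuli just as strongly as ON cells to bright ones
            drive = np.tensordot(np.abs(stim), w2, axes=([1, 2], [0, 1]))
        else:
            raise DimensionError("stimulus must be 2-D or 3-D")

    if abs(rate - model.filter_rate) > 1e-9:
        raise ParameterError(
            f"stimulus rate {rate} Hz does not match the temporal filter "
            f"sampling {model.filter_rate} Hz"
        )

    y = model.gain * np.convolve(drive, model.temporal_filter)[: len(drive)]

    if epochs is not None:
        mod = np.ones_like(y)
        for row in epochs.itertuples():
            if row.kind in ("prestim", "gray"):
                continue
            i0 = int(round(row.onset_s * rate))
            i1 = int(round(row.offset_s * rate))
            g = model.contrast_gain(row.contrast)
            if np.isfinite(row.direction):
                g *= model.direction_gain(row.direction)
            mod[i0:i1] = g
        y = y * mod

    if rectify and model.rectifier_threshold is not None:
        y = np.maximum(y - model.rectifier_threshold, 0.0)
    if calcium:
        y = np.convolve(y, model.calcium_kernel())[: len(y)]
    if noise_sigma > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sigma, len(y))
    return y


# ---------------------------------------------------------------------------
# Imaging movies with planted terminals
# ---------------------------------------------------------------------------

@dataclass
class Terminal:
    """One planted axon terminal: its pixel set, model, and layer label."""

    pixels: np.ndarray  # [n, 2] integer (row, col)
    model: NeuronModel
    layer: str = "A"

    @property
    def centroid(self) -> tuple[float, float]:
        return float(self.pixels[:, 0].mean()), float(self.pixels[:, 1].mean())

    def area_um2(self, pixel_size: float) -> float:
        return len(self.pixels) * pixel_size**2


@dataclass
class GroundTruthMovie:
    """Fluorescence movie with planted terminals recorded as ground truth."""

    frames: np.ndarray  # [T, H, W]
    frame_rate: float
    pixel_size: float  # um / pixel
    terminals: list[Terminal]
    baseline_f0: float
    noise_sigma: float
    seed: int | None = None
    dff_traces: list[np.ndarray] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def terminal_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, bool)
        for t in self.terminals:
            mask[t.pixels[:, 0], t.pixels[:, 1]] = True
        return mask


# Terminal footprints in pixel offsets. At the default 0.5 um/px these span
# 1.0 - 1.75 um^2, inside the 1 - 6.5 um^2 terminal-size range but below
# twice its lower edge, so no footprint can be cut into two pieces that both
# still count as terminal-sized -- the cluster-count scan then has a unique
# optimum at the planted partition.
TERMINAL_FOOTPRINTS: dict[str, np.ndarray] = {
    "block4": np.array([[0, 0], [0, 1], [1, 0], [1, 1]]),
    "l5": np.array([[0, 0], [0, 1], [1, 0], [1, 1], [2, 0]]),
    "block6": np.array([[0, 0], [0, 1], [0, 2], [1, 0], [1, 1], [1, 2]]),
    "t7": np.array(
        [[0, 0], [0, 1], [0, 2], [1, 0], [1, 1], [1, 2], [2, 1]]
    ),
}


def place_terminals(
    n: int,
    shape: tuple[int, int],
    footprints: list[np.ndarray] | None = None,
    min_separation: int = 6,
    margin: int = 3,
    seed: int | None = None,
) -> list[np.ndarray]:
    """Place n disjoint terminal footprints on a jittered grid.

    ``footprints`` cycles through pixel-offset templates (defaults to
    :data:`TERMINAL_FOOTPRINTS`). The grid pitch guarantees at least
    ``min_separation`` px between placements.
    """
    rng = np.random.default_rng(seed)
    if footprints is None:
        footprints = list(TERMINAL_FOOTPRINTS.values())
    extent = max(int(fp.max()) + 1 for fp in footprints)
    pitch = extent + min_separation
    rows = np.arange(margin, shape[0] - margin - extent, pitch)
    cols = np.arange(margin, shape[1] - margin - extent, pitch)
    cells = [(r, c) for r in rows for c in cols]
    if len(cells) < n:
        raise PlacementError(
            f"cannot place {n} terminals of pitch {pitch} in frame {shape}"
        )
    picks = rng.permutation(len(cells))[:n]
    out = []
    for i, k in enumerate(picks):
        r0, c0 = cells[k]
        fp = footprints[i % len(footprints)]
        span = int(fp.max()) + 1
        jr = rng.integers(0, extent - span + 1)
        jc = rng.integers(0, extent - span + 1)
        out.append(fp + np.array([r0 + jr, c0 + jc]))
    return out


def render_terminal_movie(
    terminals: list[Terminal],
    stimulus,
    epochs: pd.DataFrame | None = None,
    frame_rate: float | None = None,
    shape: tuple[int, int] = (128, 128),
    pixel_size: float = 0.5,
    baseline_f0: float = 100.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> GroundTruthMovie:
    """Render an imaging movie: each planted terminal's pixels trace
    baseline_f0 * (1 + dF/F of its model); background pixels sit at
    baseline_f0; iid Gaussian pixel noise is added on top.

    ``stimulus`` is a screen movie (with its epoch table and frame rate) or
    a :class:`TernaryNoise`, in which case frames run on the noise clock.
    """
    if isinstance(stimulus, TernaryNoise):
        frame_rate = stimulus.update_rate
    elif frame_rate is None:
        raise ParameterError("frame_rate required for a screen-movie stimulus")
    occupancy = np.zeros(shape, bool)
    for term in terminals:
        px = np.asarray(term.pixels)
        if px.min() < 0 or px[:, 0].max() >= shape[0] or px[:, 1].max() >= shape[1]:
            raise PlacementError("terminal pixels outside the frame")
        if occupancy[px[:, 0], px[:, 1]].any():
            raise PlacementError("terminal placements overlap")
        occupancy[px[:, 0], px[:, 1]] = True

    n_frames = (
        stimulus.n_frames if isinstance(stimulus, TernaryNoise)
        else stimulus.shape[0]
    )
    frames = np.full((n_frames,) + shape, baseline_f0, np.float32)
    dff_traces = []
    for term in terminals:
        dff = simulate_ln_response(
            term.model, stimulus, epochs=epochs, rate=frame_rate
        )
        dff_traces.append(dff)
        px = np.asarray(term.pixels)
        frames[:, px[:, 0], px[:, 1]] = (
            baseline_f0 * (1.0 + dff[:, None])
        ).astype(np.float32)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, noise_sigma, frames.shape).astype(
            np.float32
        )
    frames = np.clip(frames, 0.0, None)
    return GroundTruthMovie(
        frames, frame_rate, pixel_size, list(terminals), baseline_f0,
        noise_sigma, seed, dff_traces,
    )


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

@dataclass
class TurningKernel:
    """Event-triggered yaw impulse response of one fly to a moving edge.

    A compact rise/decay bump (raised-cosine halves) starting after a
    reaction ``latency``; an optional exponential tail of weight
    ``tail_frac`` models sustained turning that outlasts the stimulus.
    """

    amplitude: float = 20.0  # deg/s at the peak
    latency: float = 1.0 / 12  # s; ~10 samples at 120 Hz
    rise: float = 0.15
    decay: float = 0.35
    tail_frac: float = 0.0
    tail_tau: float | None = None

    def sample(self, rate: float, duration: float = 6.0) -> np.ndarray:
        t = np.arange(int(round(duration * rate))) / rate
        a_bump = self.amplitude * (1.0 - self.tail_frac)
        k = np.zeros_like(t)
        u = (t - self.latency) / self.rise
        m = (u >= 0) & (u < 1)
        k[m] = a_bump * np.sin(0.5 * np.pi * u[m]) ** 2
        v = (t - self.latency - self.rise) / self.decay
        m = (v >= 0) & (v < 1)
        k[m] = a_bump * np.cos(0.5 * np.pi * v[m]) ** 2
        if self.tail_frac > 0 and self.tail_tau:
            a_tail = self.amplitude * self.tail_frac
            m = u >= 0
            rise_part = np.where(u < 1, np.sin(0.5 * np.pi * np.clip(u, 0, 1)) ** 2, 1.0)
            s = t - self.latency - self.rise
            tail = np.where(s >= 0, np.exp(-np.clip(s, 0, None) / self.tail_tau), 1.0)
            k[m] += a_tail * (rise_part * tail)[m]
        return k


def control_kernel(amplitude: float = 20.0) -> TurningKernel:
    """Fast-decaying kernel: back to zero well inside the dark interleave."""
    return TurningKernel(amplitude=amplitude)


def sustained_kernel(
    amplitude: float = 20.0, tail_frac: float = 0.6, tail_tau: float = 2.0
) -> TurningKernel:
    """Kernel with a long exponential tail emulating sustained turning."""
    return TurningKernel(
        amplitude=amplitude, tail_frac=tail_frac, tail_tau=tail_tau
    )


@dataclass
class EdgeEpochDesign:
    """Open-loop edge protocol: single 0.75 s edges at 192 deg/s, or paired
    edges (0.75 s or 0.5 s each, no gap) at 240 deg/s, interleaved by a
    1.5 s dark screen, mirror-symmetric directions in equal number."""

    kind: str = "paired"  # "single" | "paired"
    edge_duration: float = 0.75
    n_epochs: int = 20
    interleave: float = 1.5
    sample_rate: float = 120.0
    lead_in: float = 1.5

    def __post_init__(self) -> None:
        if self.kind not in ("single", "paired"):
            raise ParameterError(f"unknown epoch kind {self.kind!r}")
        if self.edge_duration <= 0 or self.n_epochs < 1:
            raise ParameterError("invalid epoch design")

    @property
    def motion_duration(self) -> float:
        return self.edge_duration * (2 if self.kind == "paired" else 1)


@dataclass
class BehaviorRecording:
    """Yaw/forward velocity traces of one fly with the epoch table.

    Yaw sign follows the arena convention: positive = clockwise. Epoch
    ``direction`` is +1 (rightward) or -1 (leftward); signed analysis
    flips leftward responses downstream, not here.
    """

    yaw: np.ndarray  # deg/s
    forward: np.ndarray  # mm/s
    sample_rate: float
    epochs: pd.DataFrame  # t_start, t_end, direction, kind
    fly_id: str
    genotype: str = "control"
    planted_slow: bool = False
    planted_opposite: bool = False

    def __post_init__(self) -> None:
        if len(self.yaw) != len(self.forward):
            raise ParameterError("yaw and forward must have equal length")


def simulate_turning_traces(
    kernel: TurningKernel,
    design: EdgeEpochDesign,
    n_flies: int = 10,
    seed: int | None = None,
    genotype: str = "control",
    yaw_noise: float = 0.0,
    forward_mean: float = 8.0,
    forward_sd: float = 1.0,
    slow_fraction: float = 0.0,
    opposite_fraction: float = 0.0,
    amplitude_cv: float = 0.1,
) -> list[BehaviorRecording]:
    """Simulate a cohort of tethered flies on the treadmill.

    Each edge onset adds one copy of the fly's turning kernel, signed by the
    stimulus direction. Per fly the kernel amplitude is jittered by
    ``amplitude_cv``; a ``slow_fraction`` of flies walks below the 3 mm/s
    forward cutoff and an ``opposite_fraction`` turns against the stimulus
    (planted quality-control violators, flagged in the recording).
    """
    rng = np.random.default_rng(seed)
    epoch_span = design.motion_duration + design.interleave
    total = design.lead_in + design.n_epochs * epoch_span
    n = int(round(total * design.sample_rate))
    n_slow = int(round(slow_fraction * n_flies))
    n_opp = int(round(opposite_fraction * n_flies))
    roles = rng.permutation(n_flies)
    slow_set = set(roles[:n_slow].tolist())
    opp_set = set(roles[n_slow : n_slow + n_opp].tolist())

    recordings = []
    for f in range(n_flies):
        directions = np.array(
            [1, -1] * math.ceil(design.n_epochs / 2), int
        )[: design.n_epochs]
        rng.shuffle(directions)
        amp = max(0.1, 1.0 + amplitude_cv * rng.standard_normal())
        if f in opp_set:
            amp = -amp
        fly_kernel = kernel.sample(design.sample_rate)

        yaw = np.zeros(n)
        rows = []
        t0 = design.lead_in
        for e in range(design.n_epochs):
            d = int(directions[e])
            onsets = [t0]
            if design.kind == "paired":
                onsets.append(t0 + design.edge_duration)
            for on in onsets:
                i = int(round(on * design.sample_rate))
                m = min(len(fly_kernel), n - i)
                yaw[i : i + m] += d * amp * fly_kernel[:m]
            rows.append(
                dict(t_start=t0, t_end=t0 + design.motion_duration,
                     direction=d, kind=design.kind)
            )
            t0 += epoch_span
        if yaw_noise > 0:
            yaw = yaw + rng.normal(0.0, yaw_noise, n)

        if f in slow_set:
            f_mean = rng.uniform(1.0, 2.5)
        else:
            f_mean = max(3.5, forward_mean + forward_sd * rng.standard_normal())
        forward = np.full(n, f_mean) + 0.2 * rng.standard_normal(n)

        recordings.append(
            BehaviorRecording(
                yaw=yaw, forward=forward, sample_rate=design.sample_rate,
                epochs=pd.DataFrame(rows), fly_id=f"{genotype}_{f:02d}",
                genotype=genotype, planted_slow=f in slow_set,
                planted_opposite=f in opp_set,
            )
        )
    return recordings


# ---------------------------------------------------------------------------
# Synapse tables
# ---------------------------------------------------------------------------

SYNAPSE_TABLE_COLUMNS = [
    "pre_type", "pre_cell_id", "post_type", "post_cell_id",
    "n_synapses", "proofread",
]


def make_synapse_fixture(
    partner_percentages: dict[str, float],
    n_cells: int = 5,
    reference_type: str = "C2",
    direction: str = "output",
    synapses_per_cell: int = 100,
    n_below_threshold: int = 1,
    n_unproofread: int = 1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Toy synapse table whose post-filter partner percentages equal the
    given spec up to integer rounding.

    Each reference cell receives/sends ``pct/100 * synapses_per_cell``
    synapses per partner type. Planted rows with < 3 synapses
    (``SmallPartner``) and rows whose proofread flag is missing
    (``GhostPartner``) exercise the connectome filters and must vanish
    downstream.
    """
    if any(p < 0 for p in partner_percentages.values()):
        raise ParameterError("partner percentages must be non-negative")
    if sum(partner_percentages.values()) > 100 + 1e-9:
        raise ParameterError("partner percentages must sum to <= 100")
    if direction not in ("output", "input"):
        raise ParameterError("direction must be 'output' or 'input'")
    rng = np.random.default_rng(seed)
    rows = []

    def add(ref_id: str, partner: str, partner_id: str, count, proofread):
        if direction == "output":
            rows.append((reference_type, ref_id, partner, partner_id, count, proofread))
        else:
            rows.append((partner, partner_id, reference_type, ref_id, count, proofread))

    for i in range(n_cells):
        ref_id = f"{reference_type}.{i}"
        for p, pct in partner_percentages.items():
            count = int(round(pct / 100.0 * synapses_per_cell))
            if count > 0:
                add(ref_id, p, f"{p}.{i}", count, True)
        for j in range(n_below_threshold):
            add(ref_id, "SmallPartner", f"SmallPartner.{i}_{j}",
                int(rng.integers(1, 3)), True)
        for j in range(n_unproofread):
            add(ref_id, "GhostPartner", f"GhostPartner.{i}_{j}",
                int(rng.integers(5, 50)), np.nan)

    return pd.DataFrame(rows, columns=SYNAPSE_TABLE_COLUMNS)
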