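# Methods

This note documents the models, conventions, numerical choices, and known
limitations behind flymotion. Everything quantitative here is computed by
the test suite or `scripts/acceptance.py`; nothing is asserted that the code
does not measure.

## Coordinate and stimulus conventions

The projection screen spans 80° of azimuth × 55° of elevation, discretized
at 1°/cell (configurable). Motion directions are counterclockwise angles in
degrees with 0° = rightward (increasing azimuth). Contrast is unitless in
[−1, 1] with 0 the mean gray. Edges and bars move at 20°/s (bars are 5°
wide); full-field flashes alternate 5 s ON / 5 s OFF; the ternary noise is
12 bars of 5° × 60° updating at 20 Hz, each bar independently −1/0/+1 with
probability ⅓ each, and runs 500 s in the standard condition. Per repeat
block, the (direction, contrast) presentation order is a seeded uniform
shuffle. Stimulus movies open with a 2 s pre-stimulus gray period and
motion epochs are separated by gray interleaves (1 s default) — these carry
the `prestim` and `gray` epochs the dF/F baselines refer to.

The cosine/sine of the motion direction are rounded at the 12th decimal so
cardinal directions are exactly axis-aligned; without this, sin(π) ≈ 1.2e−16
tilts a 180° edge enough to flip boundary-cell inclusion relative to its 0°
mirror image and break exact direction symmetry.

## The LN forward model

Model neurons are linear–nonlinear cells with calcium-indicator dynamics:

1. **Spatial stage.** A Gaussian receptive field (center in degrees, σ in
   degrees). On the noise stimulus the bar weights are the Gaussian
   evaluated at bar centers; on screen movies it is a normalized 2-D
   Gaussian so a full-field unit stimulus drives the cell with amplitude 1.
2. **Temporal stage.** A biphasic filter (fast positive lobe at ~0.1 s,
   delayed negative lobe at ~0.35 s, peak-normalized), sampled at the
   stimulus rate.
3. **Tuning.** Direction tuning is a raised cosine: the drive is scaled by
   (1 − DSI_true) + DSI_true·(1 + cos Δθ)/2, i.e. 1 at the preferred
   direction and (1 − DSI_true) at the null. The analysis never assumes
   this shape, so DSI recovery is non-circular; the tuning *width* is
   consequently not a recovery target. Contrast preference scales epochs of
   the non-preferred contrast by (1 − CSI_true).
4. **Nonlinearity.** Optional half-wave rectification at a threshold
   (default 0; `None` disables it).
5. **Indicator.** A unit-area single-exponential calcium kernel,
   τ = 0.25 s by default (GCaMP6f-like; the indicator model is a package
   choice, configurable).

Two deliberate modeling choices:

* **Screen movies drive the cell through unsigned contrast**, with ON/OFF
  selectivity entering through the per-epoch contrast gain. With a signed
  luminance drive plus rectification, an OFF-preferring cell would barely
  respond to dark edges (its drive would be negative), contradicting the
  planted CSI semantics. The ternary-noise path stays signed and linear —
  that is what reverse correlation estimates.
* **Recovery ground truth includes the indicator.** The measurable linear
  filter of a calcium-imaged cell is the temporal filter convolved with the
  calcium kernel; `NeuronModel.effective_temporal_filter()` /
  `effective_strf()` expose it, and latency/similarity checks compare
  against these. The spatial profile is unaffected by the indicator.

STRF recovery conditions use the linear regime (rectifier disabled): plain
reverse correlation is unbiased only there, and no linear filter can
predict a half-wave-rectified response with R² ≥ 0.9 (the attainable
correlation is ≈ 0.71, R² ≈ 0.5). With the rectifier at threshold 0, planted
DSI/CSI still pass through to measured peak ratios exactly, so selectivity
recovery keeps the nonlinearity on.

## Synthetic movies

`render_terminal_movie` paints each planted terminal's dF/F onto its pixel
set: F = F0·(1 + dF/F) on terminal pixels, F0 elsewhere, plus iid Gaussian
pixel noise (F0 = 100, pixel size 0.5 μm/px, 15 Hz by default — acquisition
zoom in the emulated experiments is uncalibrated, so pixel size is a
required parameter, not a constant). SNR is defined as
F0·(peak dF/F)/noise_σ. Terminal footprints span 4–7 px (1.0–1.75 μm² at
0.5 μm/px): inside the 1–6.5 μm² terminal-size range but below twice its
lower edge, so no planted terminal can be cut into two pieces that both
count as terminal-sized — the cluster-count scan then has its optimum at
the planted partition. Placements sit on a jittered grid with ≥ 6 px
separation.

What the generator does **not** emulate: motion artifacts (input is assumed
aligned), bleaching, neuropil contamination, correlated noise, anatomical
background structure, or eye optics. Passing tests therefore demonstrate
correctness of the analysis on its own measurement model, not robustness to
those artifacts.

## Segmentation

Foreground: Gaussian-smoothed (σ = 1.5 px) time-mean image, thresholded by
Otsu's method on a 256-equal-width-bin histogram of the observed range,
ties broken toward the lowest qualifying bin edge (exactly reproducible for
float inputs; verified bit-exact against an exhaustive cut search).

Responsiveness: the peak of the trial-averaged trace must exceed the mean +
k·SD **of the full unaveraged dF/F trace** (k = 2; 3 for receptive-field
pixels). The SD is taken before averaging deliberately: the maximum of
~600 samples of pure noise always exceeds its own mean + 2 SD, so a
criterion computed entirely on the averaged trace cannot reject
non-responsive pixels; against the raw SD, trial averaging shrinks a
noise-only peak by √n_repeats and the filter becomes discriminative. Four
stimulus repeats are the standard condition.

Selectivity: PD is the direction of maximal trial-averaged peak dF/F at the
preferred contrast, ND its 180° opposite; DSI = (PD − ND)/PD and
CSI = (PC − NC)/PC. Pixels with PD = 0 or PC = 0 are dropped (logged)
rather than assigned infinite indices. `t_pd_peak` is the frame of the
PD-epoch maximum.

Clustering runs per (contrast class, layer) group on (x, y, w·t_pd_peak)
with average linkage. The paper-style feature mixes pixels and frames in
one Euclidean distance; the weight w (default 1.0, i.e. 1 frame ≡ 1 px) is
exposed in the configuration and is the largest reconstruction uncertainty
of the whole pipeline. The cut height is searched over the merge heights
only (the partition is piecewise constant between them, so this is exact),
choosing the height that maximizes the count of clusters with area in
1–6.5 μm²; ties take the smallest height. A consequence of that tie rule:
for a terminal whose footprint exceeds twice the minimum in-range pixel
count's lower bound, the first in-range sub-piece appears at a lower height
than the full terminal and is what gets retained — cluster counts and
centroids are stable, but retained areas can be smaller than planted ones.
Rows are sorted canonically before linkage so the partition is invariant to
input order even under distance ties. Layer labels come from a user-supplied
region mask (anatomical layer assignment is unavailable for synthetic data);
unassigned pixels form their own group.

## Receptive fields

The response is mean-centered and, when acquired below the noise rate,
linearly resampled onto the 20 Hz stimulus clock (holding edge values where
the grid leaves the original support). The reverse-correlation sum runs
over t ≥ n_lags so every lag averages the same T − n_lags samples and the
estimator is exactly linear in the response; this fixed divisor differs
from a per-lag 1/(T − τ) normalization by < n_lags/T (< 0.4% at 500 s).
Predictions are likewise evaluated only for t ≥ n_lags. R² is the squared
Pearson correlation of prediction and measurement (squaring makes the
validity check sign-invariant). The 0.26 validity threshold and the CSI
> 0.5 pre-filter for T4/T5 pixels are applied as stated; R² weighting of
the average and optional peak-bar alignment (zero-padded shifts) follow.

Temporal-filter extraction has two modes — the time course at the
maximal-|weight| bar (default, consistent with the FWHM slice) or the mean
over bars — because the underlying procedure is describable both ways; the
mode is recorded rather than guessed. The spatial Gaussian fit runs on the
lag row containing the global |weight| maximum, in degree coordinates
(bar centers at 5° spacing); FWHM = 2√(2 ln 2)·σ, with profiles at or below
one bar width flagged sub-resolution. Fit divergence returns an absent
result with a logged diagnostic.

## Behavior

The simulator is event-triggered: each edge onset adds one copy of the
fly's turning kernel, signed by stimulus direction. (A convolution of the
kernel with the continuous motion indicator cannot produce the between-edge
dip that percent recovery measures, because paired edges present motion
without a gap.) The control kernel is a compact raised-cosine bump —
~83 ms latency, 0.15 s rise, 0.35 s decay — back at exactly zero well
inside the 1.5 s dark interleave; the sustained kernel adds an exponential
tail (60% weight, τ = 2 s) emulating slowed response kinetics. Per fly the
amplitude is jittered (CV 0.1); planted quality-control violators walk
below 3 mm/s or turn against the stimulus and are flagged in the recording
so rejection can be checked exactly.

Analysis windows: declining-phase slope over 0.45–0.75 s from motion onset
(ordinary least squares); V_peak from the eight highest trial-averaged
samples over the first edge [0, D]; V_lowest from the eight lowest over
[D, D + 0.25 s] — the first 0.25 s of the second edge, which matches both
printed epoch variants (D = 0.75 and 0.5 s). Percent recovery is computed
per fly before any cross-fly statistics. Flies with V_peak ≤ 0 are excluded
with a log entry. Group comparisons use pooled-variance (Student's) t tests
against both genetic controls, significant only when both reject at α.

## Connectome

Filters are ordered: unproofread (missing-flag) rows first, then
connections with < 3 synapses. Percentages are per reference cell over its
full post-filter budget; the ≥ 70% cell-coverage rule only hides rows from
the display table and never re-normalizes (a cell's percentages describe
its entire budget). The coverage comparison uses ≥ (configurable to
strict >, since the printed rule does not say). SEM is across reference
cells. The fixture plants integer percentages at 100 synapses per cell, so
a correct pipeline reproduces them exactly.

## Pipeline, sizes, determinism

The orchestrated run (`flymotion run-all`) simulates one edge-stimulus
recording (4 repeats, 12 terminals, 96 × 96 px), a noise recording of the
same cells for receptive fields (120 s default), three behavior cohorts
(two controls, one sustained), and a synapse fixture; every stage seed is
the master seed plus a fixed offset, so re-runs are byte-identical (hashes
recorded in the manifest). The acceptance script uses the full 500 s noise
condition, 20 terminals at 128 × 128 px, 10 seeds per planted FWHM, 100
runs per R²-discrimination arm, and 20 behavior cohorts per kernel — sizes
chosen so the whole script completes in well under a minute on one CPU
while keeping every estimate comfortably inside its tolerance.

## Known limitations

* The time-weight of the clustering feature is a genuine unknown of the
  reconstruction; results for crowded terminals can depend on it.
* Reverse correlation is evaluated in the linear regime; rectified cells
  yield attenuated but shape-preserved estimates (Bussgang), and prediction
  R² then reflects the nonlinearity as much as estimation error.
* The behavioral kernel is phenomenological (turning velocity only); it
  does not model forward-speed coupling or closed-loop dynamics.
* Epoch responses bleed slightly across short gray interleaves (the
  impulse response spans ~2.5 s); with 1 s interleaves this biases
  selectivity indices by ≲ 0.01, and vanishes for interleaves longer than
  the impulse-response support.
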