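"""End-to-end orchestration: simulate -> preprocess -> segment -> metrics /
receptive fields, plus the behavior and connectome branches, from one config.

Every stage draws its seed from the master seed by a fixed offset, so a
re-run with the same config reproduces every artifact bit-for-bit. Defaults
equal the analysis constants used throughout the package (k_sd = 2,
R^2 >= 0.26, CSI > 0.5, cluster area 1 - 6.5 um^2, >= 3 synapses, 70% cell
coverage, 8 extreme samples, 3 mm/s forward cutoff).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import connectome as conn
from . import io as fio
from . import response_metrics as rm
from . import segmentation as seg
from . import strf as strf_mod
from . import synth
from .preprocessing import compute_dff

log = logging.getLogger(__name__)

__all__ = ["ConfigError", "RunConfig", "run_pipeline"]

SEED_OFFSETS = {
    "stimulus": 11, "placement": 17, "movie_noise": 23, "noise": 29,
    "noise_movie": 31, "behavior": 37, "synapses": 43,
}


class ConfigError(ValueError):
    """Configuration violates the schema; nothing was computed."""


@dataclass
class RunConfig:
    """All pipeline parameters with their standard defaults."""

    seed: int = 0
    # imaging / segmentation
    frame_rate: float = 15.0
    pixel_size: float = 0.5  # um per pixel
    movie_shape: tuple[int, int] = (96, 96)
    n_terminals: int = 12
    baseline_f0: float = 100.0
    movie_noise_sigma: float = 2.0
    k_sd: float = 2.0
    time_weight: float = 1.0
    area_range: tuple[float, float] = (1.0, 6.5)
    # receptive fields
    noise_n_bars: int = 12
    noise_update_rate: float = 20.0
    noise_duration: float = 120.0
    strf_window: float = 2.0
    r2_min: float = 0.26
    csi_min: float = 0.5
    # behavior
    behavior_kind: str = "paired"
    edge_duration: float = 0.75
    behavior_n_flies: int = 8
    behavior_n_epochs: int = 12
    n_extreme: int = 8
    min_forward: float = 3.0
    behavior_yaw_noise: float = 1.0
    # connectome
    min_synapses: int = 3
    min_cell_fraction: float = 0.7
    partner_percentages: dict = field(
        default_factory=lambda: {"Mi1": 40.0, "Tm1": 30.0, "Mi4": 20.0,
                                 "CT1": 10.0}
    )
    n_reference_cells: int = 5

    def validate(self) -> None:
        checks = [
            (self.frame_rate > 0, "frame_rate must be positive"),
            (self.pixel_size > 0, "pixel_size must be positive"),
            (self.n_terminals >= 1, "n_terminals must be >= 1"),
            (self.k_sd > 0, "k_sd must be positive"),
            (0.0 <= self.r2_min <= 1.0, "r2_min must lie in [0, 1]"),
            (0.0 <= self.csi_min <= 1.0, "csi_min must lie in [0, 1]"),
            (0 < self.area_range[0] < self.area_range[1],
             "area_range must be increasing and positive"),
            (self.noise_n_bars >= 1, "noise_n_bars must be >= 1"),
            (self.noise_duration > self.strf_window,
             "noise_duration must exceed the correlation window"),
            (self.edge_duration > 0, "edge_duration must be positive"),
            (self.n_extreme >= 1, "n_extreme must be >= 1"),
            (self.min_synapses >= 0, "min_synapses must be >= 0"),
            (0.0 <= self.min_cell_fraction <= 1.0,
             "min_cell_fraction must lie in [0, 1]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("movie_shape", "area_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def stage_seed(self, stage: str) -> int:
        return int(self.seed) + SEED_OFFSETS[stage]


def _make_models(cfg: RunConfig, rate: float) -> list[synth.NeuronModel]:
    """Terminal models: preferred directions cycle the four cardinals,
    contrast preference alternates ON/OFF, planted DSI 0.8 and CSI 0.9."""
    tf = synth.biphasic_filter(rate)
    return [
        synth.NeuronModel(
            temporal_filter=tf, filter_rate=rate,
            rf_center=(40.0, 27.5), rf_sigma=6.4,
            pref_direction=(90.0 * i) % 360.0,
            dsi_true=0.8, contrast_pref="ON" if i % 2 == 0 else "OFF",
            csi_true=0.9, rectifier_threshold=0.0, gain=1.0,
        )
        for i in range(cfg.n_terminals)
    ]


def _cluster_condition_peaks(
    dff: np.ndarray, rate: float, epochs: pd.DataFrame
) -> dict[tuple[float, float], np.ndarray]:
    """Peak trial-averaged dF/F per (direction, contrast) per cluster row."""
    motion = epochs[epochs["kind"].isin(["edge", "bar"])]
    out = {}
    for (d, c), grp in motion.groupby(["direction", "contrast"]):
        windows = []
        for row in grp.itertuples():
            i0 = int(round(row.onset_s * rate))
            i1 = int(round(row.offset_s * rate))
            windows.append(dff[:, i0:i1])
        n = min(w.shape[1] for w in windows)
        avg = np.mean([w[:, :n] for w in windows], axis=0)
        out[(float(d), float(c))] = avg.max(axis=1)
    return out


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run every branch of the analysis on freshly simulated data.

    Writes masks (TIFF + CSV), tuning metrics CSV, receptive-field HDF5 and
    summary CSV, behavior summary and rejection CSVs, connectivity CSV, and
    a manifest recording parameters, versions, and output hashes. Returns
    the manifest dict.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    # --- simulate imaging (edge stimulus, planted terminals) ---------------
    spec = synth.StimulusSpec(
        kind="edge", frame_rate=config.frame_rate, n_repeats=4,
        seed=config.stage_seed("stimulus"),
    )
    stim, epochs = synth.make_motion_stimuli(spec)
    models = _make_models(config, config.frame_rate)
    placements = synth.place_terminals(
        config.n_terminals, config.movie_shape,
        seed=config.stage_seed("placement"),
    )
    layers = "ABCD"
    terminals = [
        synth.Terminal(px, m, layers[i % 4])
        for i, (px, m) in enumerate(zip(placements, models))
    ]
    movie = synth.render_terminal_movie(
        terminals, stim, epochs, config.frame_rate, config.movie_shape,
        config.pixel_size, config.baseline_f0, config.movie_noise_sigma,
        seed=config.stage_seed("movie_noise"),
    )
    fio.save_movie_tiff(out / "movie.tif", movie.frames)
    fio.save_epochs_csv(out / "epochs.csv", epochs)
    outputs["movie"] = "movie.tif"
    outputs["epochs"] = "epochs.csv"

    # --- segment ------------------------------------------------------------
    features = seg.pixel_selectivity(
        movie.frames, config.frame_rate, epochs, k_sd=config.k_sd,
    )
    clusters, cut_heights = seg.cluster_terminals(
        features, config.pixel_size, config.area_range, config.time_weight
    )
    fio.save_cluster_masks(
        out / "masks.tif", out / "clusters.csv", clusters, config.movie_shape
    )
    outputs["masks"] = "masks.tif"
    outputs["clusters"] = "clusters.csv"

    # --- tuning metrics per cluster -----------------------------------------
    raw = seg.extract_cluster_traces(movie.frames, clusters)
    rows = []
    if len(clusters):
        dff = np.stack([
            compute_dff(tr, f0_mode="prestim_epoch", rate=config.frame_rate,
                        epochs=epochs, name=c.cluster_id).values
            for tr, c in zip(raw, clusters)
        ])
        peaks = _cluster_condition_peaks(dff, config.frame_rate, epochs)
        directions = sorted({d for d, _ in peaks})
        contrasts = sorted({c for _, c in peaks})
        for i, c in enumerate(clusters):
            per_c = {
                ct: max(peaks[(d, ct)][i] for d in directions)
                for ct in contrasts
            }
            pref_c = max(per_c, key=per_c.get)
            pc, nc = per_c[pref_c], min(per_c.values())
            resp = np.array([peaks[(d, pref_c)][i] for d in directions])
            tuning = rm.direction_tuning(resp, np.array(directions))
            rows.append(dict(
                cluster_id=c.cluster_id, layer=c.layer, area_um2=c.area,
                contrast_class="ON" if pref_c > 0 else "OFF",
                csi=(pc - nc) / pc if pc > 0 else np.nan,
                dsi=tuning.dsi if tuning else np.nan,
                ldir=tuning.ldir_magnitude if tuning else np.nan,
                tuning_angle=tuning.tuning_angle if tuning else np.nan,
            ))
    metrics = pd.DataFrame(rows)
    metrics.to_csv(out / "metrics.csv", index=False)
    outputs["metrics"] = "metrics.csv"

    # --- receptive fields on a second (noise) recording of the same cells ---
    noise = synth.make_ternary_noise(
        config.noise_n_bars, config.noise_update_rate, config.noise_duration,
        seed=config.stage_seed("noise"),
    )
    models20 = _make_models(config, config.noise_update_rate)
    terminals20 = [
        synth.Terminal(t.pixels, m, t.layer)
        for t, m in zip(terminals, models20)
    ]
    noise_movie = synth.render_terminal_movie(
        terminals20, noise, pixel_size=config.pixel_size,
        baseline_f0=config.baseline_f0, noise_sigma=config.movie_noise_sigma,
        shape=config.movie_shape, seed=config.stage_seed("noise_movie"),
    )
    matched, match_report = seg.match_clusters(
        clusters, noise_movie.frames
    )
    match_report.to_csv(out / "match_report.csv", index=False)
    outputs["match_report"] = "match_report.csv"

    strf_rows = []
    strfs = []
    if len(matched):
        raw20 = seg.extract_cluster_traces(noise_movie.frames, matched)
        for tr, c in zip(raw20, matched):
            r = compute_dff(tr, f0_mode="whole_trace_mean",
                            rate=config.noise_update_rate,
                            name=c.cluster_id).values
            s = strf_mod.reverse_correlate(
                r, noise, window=config.strf_window, cell_id=c.cluster_id
            )
            s.r2 = strf_mod.strf_prediction_r2(s, noise, r)
            strfs.append(s)
            tf = strf_mod.temporal_filter_metrics(s)
            prof = strf_mod.spatial_fwhm(s, noise.bar_size[0])
            strf_rows.append(dict(
                cluster_id=c.cluster_id, r2=s.r2,
                valid=s.r2 >= config.r2_min,
                on_peak_s=tf.on_peak_time,
                fwhm_deg=prof.fwhm_deg if prof else np.nan,
            ))
        fio.save_strfs_hdf5(out / "strfs.h5", strfs)
        outputs["strfs"] = "strfs.h5"
    avg, avg_report = strf_mod.weighted_average_strf(
        strfs, r2_min=config.r2_min, align=True
    ) if strfs else (None, {"n_input": 0, "n_valid": 0, "n_discarded": 0})
    pd.DataFrame(strf_rows).to_csv(out / "strf_summary.csv", index=False)
    outputs["strf_summary"] = "strf_summary.csv"

    # --- behavior ------------------------------------------------------------
    design = synth.EdgeEpochDesign(
        kind=config.behavior_kind, edge_duration=config.edge_duration,
        n_epochs=config.behavior_n_epochs,
    )
    seed_b = config.stage_seed("behavior")
    cohorts = {
        "control1": synth.simulate_turning_traces(
            synth.control_kernel(), design, config.behavior_n_flies,
            seed=seed_b, genotype="control1",
            yaw_noise=config.behavior_yaw_noise),
        "control2": synth.simulate_turning_traces(
            synth.control_kernel(), design, config.behavior_n_flies,
            seed=seed_b + 1, genotype="control2",
            yaw_noise=config.behavior_yaw_noise),
        "silenced": synth.simulate_turning_traces(
            synth.sustained_kernel(), design, config.behavior_n_flies,
            seed=seed_b + 2, genotype="silenced",
            yaw_noise=config.behavior_yaw_noise),
    }
    beh_rows, rej_frames = [], []
    recov = {}
    for name, cohort in cohorts.items():
        traces, rej = beh.aggregate_turning(cohort, config.min_forward)
        rej_frames.append(rej)
        vals = []
        for t in traces:
            try:
                r = beh.percent_recovery(
                    t, config.edge_duration, config.n_extreme
                )
            except beh.UndefinedRecoveryError as err:
                log.info("%s", err)
                continue
            vals.append(r.percent_recovery)
            beh_rows.append(dict(
                genotype=name, fly_id=t.fly_id, v_peak=r.v_peak,
                v_lowest=r.v_lowest, percent_recovery=r.percent_recovery,
            ))
        recov[name] = np.array(vals)
    ttest = beh.controls_ttest(
        recov["silenced"], recov["control1"], recov["control2"]
    )
    pd.DataFrame(beh_rows).to_csv(out / "behavior_recovery.csv", index=False)
    pd.concat(rej_frames, ignore_index=True).to_csv(
        out / "behavior_rejections.csv", index=False
    )
    outputs["behavior_recovery"] = "behavior_recovery.csv"
    outputs["behavior_rejections"] = "behavior_rejections.csv"

    # --- connectome ----------------------------------------------------------
    table = synth.make_synapse_fixture(
        config.partner_percentages, config.n_reference_cells,
        seed=config.stage_seed("synapses"),
    )
    fio.save_synapse_table(out / "synapses.csv", table)
    summary = conn.partner_percentages(
        conn.filter_synapse_table(table, config.min_synapses),
        reference_type="C2", direction="output",
        min_cell_fraction=config.min_cell_fraction,
    )
    summary.to_csv(out / "connectivity.csv", index=False)
    outputs["synapses"] = "synapses.csv"
    outputs["connectivity"] = "connectivity.csv"

    # --- manifest ------------------------------------------------------------
    def sha256(p: Path) -> str:
        return hashlib.sha256(p.read_bytes()).hexdigest()

    manifest = {
        "package": "flymotion",
        "versions": {
            "numpy": np.__version__, "pandas": pd.__version__,
        },
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stage_seeds": {k: config.stage_seed(k) for k in SEED_OFFSETS},
        "n_clusters": len(clusters),
        "cut_heights": {f"{k[0]}_{k[1]}": v for k, v in cut_heights.items()},
        "strf_report": avg_report,
        "behavior_ttest": {
            "p_control1": ttest.p_control1, "p_control2": ttest.p_control2,
            "significant": ttest.significant,
        },
        "outputs": {
            k: {"path": v, "sha256": sha256(out / v)}
            for k, v in outputs.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
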