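import numpy as np
import pytest

from flymotion import synth


def make_linear_model(rate=20.0, rf_center=(30.0, 27.5), rf_sigma=6.37,
                      **kw) -> synth.NeuronModel:
    """LN model in the linear regime (no rectifier) at the noise clock."""
    kw.setdefault("rectifier_threshold", None)
    return synth.NeuronModel(
        temporal_filter=synth.biphasic_filter(rate), filter_rate=rate,
        rf_center=rf_center, rf_sigma=rf_sigma, **kw,
    )


def make_terminal_models(n, rate=15.0, dsi=0.8, csi=0.9):
    """Rectified terminal models cycling the four cardinal directions."""
    tf = synth.biphasic_filter(rate)
    return [
        synth.NeuronModel(
            temporal_filter=tf, filter_rate=rate,
            rf_center=(40.0, 27.5), rf_sigma=6.4,
            pref_direction=(90.0 * i) % 360.0, dsi_true=dsi,
            contrast_pref="ON" if i % 2 == 0 else "OFF", csi_true=csi,
            rectifier_threshold=0.0,
        )
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def edge_stimulus():
    """Four-direction ON/OFF edge movie with 4 repeats at 15 Hz."""
    spec = synth.StimulusSpec(kind="edge", frame_rate=15.0, n_repeats=4,
                              seed=5)
    return synth.make_motion_stimuli(spec)


@pytest.fixture(scope="session")
def planted_movie(edge_stimulus):
    """Noiseless 20-terminal ground-truth movie (shared across tests)."""
    stim, epochs = edge_stimulus
    models = make_terminal_models(20)
    placements = synth.place_terminals(20, (128, 128), seed=7)
    terminals = [
        synth.Terminal(px, m, "ABCD"[i % 4])
        for i, (px, m) in enumerate(zip(placements, models))
    ]
    movie = synth.render_terminal_movie(
        terminals, stim, epochs, 15.0, (128, 128), pixel_size=0.5,
        baseline_f0=100.0, noise_sigma=0.0,
    )
    return movie, epochs


def centroid_hits(clusters, terminals, tol=1.0):
    """Number of planted terminals with a recovered centroid within tol px."""
    hits = 0
    for t in terminals:
        tc = t.centroid
        if any(
            max(abs(c.centroid[0] - tc[0]), abs(c.centroid[1] - tc[1])) <= tol
            for c in clusters
        ):
            hits += 1
    return hits
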