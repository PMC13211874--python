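"""Generator tests: stimuli, LN neurons, movies, behavior traces, fixtures."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from flymotion import synth
from flymotion.synth import (
    DimensionError,
    ParameterError,
    PlacementError,
    StimulusSpec,
)

from conftest import make_linear_model


class TestTernaryNoise:
    def test_shape_values_and_determinism(self):
        n = synth.make_ternary_noise(12, 20.0, 500.0, seed=1)
        assert n.values.shape == (10000, 12)
        assert set(np.unique(n.values)) <= {-1, 0, 1}
        again = synth.make_ternary_noise(12, 20.0, 500.0, seed=1)
        np.testing.assert_array_equal(n.values, again.values)

    def test_single_frame(self):
        n = synth.make_ternary_noise(1, 20.0, 0.05)
        assert n.values.shape == (1, 1)

    def test_marginal_is_uniform(self):
        # each contrast level appears ~1/3 of the time at n = 10000
        n = synth.make_ternary_noise(1, 20.0, 500.0, seed=3)
        counts = [int((n.values == v).sum()) for v in (-1, 0, 1)]
        assert chisquare(counts).pvalue > 0.01
        p = np.array(counts) / n.n_frames
        bound = 3 * np.sqrt((1 / 3) * (2 / 3) / n.n_frames)
        assert np.all(np.abs(p - 1 / 3) < bound)

    @pytest.mark.parametrize("kwargs", [
        dict(n_bars=0, update_rate=20.0, duration=1.0),
        dict(n_bars=1, update_rate=-5.0, duration=1.0),
        dict(n_bars=1, update_rate=20.0, duration=0.0),
    ])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ParameterError):
            synth.make_ternary_noise(**kwargs)


class TestMotionStimuli:
    def test_flash_epochs(self):
        spec = StimulusSpec(kind="flash", duration=120.0, frame_rate=15.0,
                            prestim=0.0)
        _, epochs = synth.make_motion_stimuli(spec)
        flashes = epochs[epochs["kind"] == "flash"]
        on = flashes[flashes["contrast"] > 0]
        assert len(on) == 12  # 12 ON/OFF cycles of 10 s in 120 s
        np.testing.assert_allclose(
            flashes["offset_s"] - flashes["onset_s"], 5.0
        )

    def test_edge_traversal_time(self):
        # 80 deg azimuth at 20 deg/s -> 4 s per horizontal traversal
        spec = StimulusSpec(kind="edge", speed=20.0, frame_rate=20.0,
                            directions=(0.0,), contrast_values=(1.0,),
                            prestim=0.0, interleave=0.0)
        movie, epochs = synth.make_motion_stimuli(spec)
        edge = epochs[epochs["kind"] == "edge"].iloc[0]
        assert edge.offset_s - edge.onset_s == pytest.approx(4.0, abs=0.1)

    def test_bar_epoch_counting_and_order(self):
        spec = StimulusSpec(kind="bar", directions=tuple(range(0, 360, 45)),
                            contrast_values=(1.0,), n_repeats=3, seed=2)
        _, epochs = synth.make_motion_stimuli(spec)
        bars = epochs[epochs["kind"] == "bar"]
        assert len(bars) == 24
        assert (bars["direction"].value_counts() == 3).all()
        # seeded shuffle reproducible
        _, epochs2 = synth.make_motion_stimuli(spec)
        pd.testing.assert_frame_equal(epochs, epochs2)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ParameterError):
            StimulusSpec(kind="plaid")


class TestLNModel:
    def test_zero_stimulus_zero_response(self):
        n = synth.make_ternary_noise(12, 20.0, 10.0, seed=0)
        n.values[:] = 0
        m = make_linear_model()
        assert np.allclose(synth.simulate_ln_response(m, n), 0.0)

    def test_untuned_model_symmetric_over_directions(self):
        # dsi_true = 0: preferred and null epochs drive equal peaks
        spec = StimulusSpec(kind="edge", frame_rate=15.0, directions=(0.0, 180.0),
                            contrast_values=(1.0,), interleave=3.0, seed=1)
        stim, epochs = synth.make_motion_stimuli(spec)
        m = synth.NeuronModel(
            temporal_filter=synth.biphasic_filter(15.0), filter_rate=15.0,
            rf_center=(40.0, 27.5), rf_sigma=8.0, dsi_true=0.0,
            rectifier_threshold=0.0,
        )
        r = synth.simulate_ln_response(m, stim, epochs=epochs, rate=15.0)
        peaks = []
        for row in epochs[epochs["kind"] == "edge"].itertuples():
            i0, i1 = int(row.onset_s * 15), int(row.offset_s * 15)
            peaks.append(r[i0:i1].max())
        assert peaks[0] == pytest.approx(peaks[1], rel=1e-6)

    def test_impulse_recovers_temporal_filter(self):
        # impulse in one bar with identity spatial weights reproduces the
        # temporal filter shifted to the impulse time, scaled by gain
        n = synth.make_ternary_noise(4, 20.0, 5.0, seed=0)
        n.values[:] = 0
        n.values[10, 2] = 1
        w = np.array([0.0, 0.0, 1.0, 0.0])
        m = make_linear_model(gain=2.5)
        r = synth.simulate_ln_response(
            m, n, spatial_weights=w, rectify=False, calcium=False
        )
        expected = np.zeros(100)
        tf = 2.5 * m.temporal_filter
        expected[10 : 10 + len(tf)] = tf[: 100 - 10]
        np.testing.assert_allclose(r, expected, atol=1e-12)

    def test_linearity_without_nonlinearities(self):
        rng = np.random.default_rng(4)
        n1 = synth.make_ternary_noise(12, 20.0, 20.0, seed=1)
        n2 = synth.make_ternary_noise(12, 20.0, 20.0, seed=2)
        m = make_linear_model()
        both = synth.TernaryNoise(
            n1.values + n2.values, 20.0, "vertical", n1.bar_size
        )
        r12 = synth.simulate_ln_response(m, both, rectify=False, calcium=False)
        r1 = synth.simulate_ln_response(m, n1, rectify=False, calcium=False)
        r2 = synth.simulate_ln_response(m, n2, rectify=False, calcium=False)
        np.testing.assert_allclose(r12, r1 + r2, atol=1e-10)

    def test_rate_and_shape_mismatches(self):
        n = synth.make_ternary_noise(12, 20.0, 5.0, seed=0)
        with pytest.raises(DimensionError):
            synth.simulate_ln_response(
                make_linear_model(), n, spatial_weights=np.ones(5)
            )
        m15 = synth.NeuronModel(
            temporal_filter=synth.biphasic_filter(15.0), filter_rate=15.0
        )
        with pytest.raises(ParameterError):
            synth.simulate_ln_response(m15, n)


class TestRenderMovie:
    def test_no_terminals_constant_movie(self):
        stim = np.zeros((10, 55, 80), np.float32)
        mv = synth.render_terminal_movie(
            [], stim, None, 15.0, (16, 16), baseline_f0=80.0
        )
        assert np.all(mv.frames == 80.0)

    def test_terminal_pixels_trace_model_dff(self, edge_stimulus):
        stim, epochs = edge_stimulus
        m = synth.NeuronModel(
            temporal_filter=synth.biphasic_filter(15.0), filter_rate=15.0,
            rf_center=(40.0, 27.5), rf_sigma=8.0, rectifier_threshold=0.0,
        )
        px = np.array([[4, 4], [4, 5], [5, 4], [5, 5]])
        mv = synth.render_terminal_movie(
            [synth.Terminal(px, m)], stim, epochs, 15.0, (16, 16),
            baseline_f0=50.0,
        )
        dff = synth.simulate_ln_response(m, stim, epochs=epochs, rate=15.0)
        np.testing.assert_allclose(
            mv.frames[:, 4, 4], 50.0 * (1 + dff), rtol=1e-5
        )
        # ground-truth self-consistency: recomputing dF/F from the planted
        # pixels recovers the model trace
        f = mv.frames[:, px[:, 0], px[:, 1]].mean(axis=1)
        f0 = 50.0
        np.testing.assert_allclose((f - f0) / f0, dff, atol=1e-4)

    def test_planted_area_recorded(self):
        px = np.array([[r, c] for r in range(3) for c in range(3)])
        t = synth.Terminal(px, make_linear_model())
        assert t.area_um2(0.5) == pytest.approx(2.25)

    def test_overlap_rejected(self):
        stim = np.zeros((5, 55, 80), np.float32)
        px = np.array([[1, 1], [1, 2]])
        terms = [synth.Terminal(px, make_linear_model(rate=15.0)),
                 synth.Terminal(px.copy(), make_linear_model(rate=15.0))]
        with pytest.raises(PlacementError):
            synth.render_terminal_movie(terms, stim, None, 15.0, (8, 8))

    def test_seeded_determinism(self, edge_stimulus):
        stim, epochs = edge_stimulus
        px = synth.place_terminals(4, (32, 32), seed=3)
        terms = [
            synth.Terminal(p, m) for p, m in
            zip(px, [make_linear_model(rate=15.0) for _ in range(4)])
        ]
        a = synth.render_terminal_movie(terms, stim, epochs, 15.0, (32, 32),
                                        noise_sigma=1.0, seed=9)
        b = synth.render_terminal_movie(terms, stim, epochs, 15.0, (32, 32),
                                        noise_sigma=1.0, seed=9)
        np.testing.assert_array_equal(a.frames, b.frames)


class TestTurningTraces:
    def test_control_returns_to_zero_before_next_epoch(self):
        design = synth.EdgeEpochDesign(kind="single", n_epochs=4)
        rec = synth.simulate_turning_traces(
            synth.control_kernel(), design, n_flies=1, seed=0,
            amplitude_cv=0.0,
        )[0]
        rate = rec.sample_rate
        for row in rec.epochs.itertuples():
            # last 0.5 s of the dark interleave before the next epoch
            i0 = int((row.t_end + 1.0) * rate)
            i1 = int((row.t_end + 1.5) * rate)
            assert np.allclose(rec.yaw[i0:i1], 0.0)

    def test_mirror_symmetric_epochs_antisymmetric(self):
        design = synth.EdgeEpochDesign(kind="paired", n_epochs=6)
        rec = synth.simulate_turning_traces(
            synth.control_kernel(), design, n_flies=1, seed=1,
            amplitude_cv=0.0,
        )[0]
        rate = rec.sample_rate
        segs = {+1: [], -1: []}
        for row in rec.epochs.itertuples():
            i0 = int(row.t_start * rate)
            segs[row.direction].append(rec.yaw[i0 : i0 + int(1.4 * rate)])
        left = np.mean(segs[-1], axis=0)
        right = np.mean(segs[+1], axis=0)
        np.testing.assert_allclose(left, -right, atol=1e-9)


class TestSynapseFixture:
    def test_round_trip_and_planted_junk(self):
        from flymotion import connectome as conn

        table = synth.make_synapse_fixture(
            {"A": 50.0, "B": 50.0}, n_cells=2, synapses_per_cell=20, seed=0
        )
        assert list(table.columns) == synth.SYNAPSE_TABLE_COLUMNS
        filtered = conn.filter_synapse_table(table)
        assert "GhostPartner" not in set(filtered["post_type"])
        small = table[table["post_type"] == "SmallPartner"]
        assert (small["n_synapses"] < 3).all()
        assert "SmallPartner" not in set(filtered["post_type"])
        summary = conn.partner_percentages(filtered, "C2")
        by_type = summary.set_index("partner_type")["percent_mean"]
        assert by_type["A"] == pytest.approx(50.0)
        assert by_type["B"] == pytest.approx(50.0)

    def test_invalid_percentages(self):
        with pytest.raises(ParameterError):
            synth.make_synapse_fixture({"A": 60.0, "B": 50.0})
        with pytest.raises(ParameterError):
            synth.make_synapse_fixture({"A": -1.0})
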