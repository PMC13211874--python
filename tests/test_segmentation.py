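"""Foreground detection, pixel selectivity, and terminal clustering tests."""
import numpy as np
import pandas as pd
import pytest

from flymotion import segmentation as seg
from flymotion import synth
from flymotion.segmentation import DegenerateImageError, GeometryError

from conftest import centroid_hits, make_terminal_models


def brute_force_otsu(values, nbins=256):
    """Exhaustive search over every histogram cut point."""
    v = np.asarray(values, float).ravel()
    hist, edges = np.histogram(v, bins=nbins, range=(v.min(), v.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_var, best_edge = -1.0, None
    total = hist.sum()
    for k in range(nbins - 1):
        n0 = hist[: k + 1].sum()
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (hist[: k + 1] * centers[: k + 1]).sum() / n0
        mu1 = (hist[k + 1 :] * centers[k + 1 :]).sum() / n1
        var = (n0 / total) * (n1 / total) * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_edge = var, edges[k + 1]
    return best_edge


class TestOtsu:
    def test_separated_modes(self):
        v = np.array([0.0] * 50 + [200.0] * 50)
        th = seg.otsu_threshold(v)
        assert 0.0 < th < 200.0
        assert ((v > th) == (v == 200.0)).all()

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateImageError):
            seg.otsu_threshold(np.full(10, 3.0))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.integers(0, 256, 1000).astype(float)
        assert seg.otsu_threshold(v) == brute_force_otsu(v)

    def test_agrees_with_reference_implementation(self):
        # independent cross-check against scikit-image on a bimodal sample
        skimage_filters = pytest.importorskip("skimage.filters")
        rng = np.random.default_rng(1)
        v = np.concatenate([rng.normal(40, 5, 600), rng.normal(180, 10, 400)])
        ours = seg.otsu_threshold(v)
        ref = skimage_filters.threshold_otsu(v, nbins=256)
        assert abs(ours - ref) < (v.max() - v.min()) / 256 * 2


class TestForegroundMask:
    def test_bright_block_detected(self):
        frames = np.zeros((5, 20, 20), np.float32)
        frames[:, 8:11, 8:11] = 100.0
        mask = seg.foreground_mask(frames)
        assert mask[8:11, 8:11].all()
        assert not mask[:3, :3].any()

    def test_all_zero_movie_rejected(self):
        with pytest.raises(DegenerateImageError):
            seg.foreground_mask(np.zeros((4, 8, 8)))

    def test_covers_planted_terminals_at_snr10(self, edge_stimulus):
        stim, epochs = edge_stimulus
        models = make_terminal_models(8)
        placements = synth.place_terminals(8, (64, 64), seed=2)
        terms = [synth.Terminal(p, m) for p, m in zip(placements, models)]
        peak = max(
            synth.simulate_ln_response(m, stim, epochs=epochs, rate=15.0).max()
            for m in models
        )
        mv = synth.render_terminal_movie(
            terms, stim, epochs, 15.0, (64, 64), baseline_f0=100.0,
            noise_sigma=100.0 * peak / 10.0, seed=5,
        )
        mask = seg.foreground_mask(mv.frames)
        assert mask[mv.terminal_mask()].mean() >= 0.95


class TestPixelSelectivity:
    def test_planted_dsi_extremes(self):
        # dsi_true = 0 measures 0; fully selective model measures 1.
        # 3 s interleaves exceed the impulse-response support, so epochs
        # are fully independent and the indices are exact
        spec = synth.StimulusSpec(kind="edge", frame_rate=15.0, n_repeats=2,
                                  interleave=3.0, seed=5)
        stim, epochs = synth.make_motion_stimuli(spec)
        tf = synth.biphasic_filter(15.0)
        models = [
            synth.NeuronModel(temporal_filter=tf, filter_rate=15.0,
                              rf_center=(40.0, 27.5), rf_sigma=8.0,
                              pref_direction=0.0, dsi_true=d,
                              contrast_pref="ON", csi_true=0.9,
                              rectifier_threshold=0.0)
            for d in (0.0, 1.0)
        ]
        placements = synth.place_terminals(2, (32, 32), seed=1)
        terms = [synth.Terminal(p, m) for p, m in zip(placements, models)]
        mv = synth.render_terminal_movie(terms, stim, epochs, 15.0, (32, 32))
        feats = seg.pixel_selectivity(mv.frames, 15.0, epochs, k_sd=2)
        for term, d in zip(terms, (0.0, 1.0)):
            r, c = term.pixels[0]
            row = feats[(feats.y == r) & (feats.x == c)].iloc[0]
            assert row.dsi == pytest.approx(d, abs=1e-6)
            assert row.contrast_class == "ON"

    def test_dsi_csi_formula_and_classification(self, planted_movie):
        movie, epochs = planted_movie
        feats = seg.pixel_selectivity(movie.frames, 15.0, epochs, k_sd=2)
        # every planted pixel survives in the noiseless movie
        assert len(feats) == sum(len(t.pixels) for t in movie.terminals)
        assert (feats.dsi <= 1.0 + 1e-9).all()
        assert (feats.csi <= 1.0 + 1e-9).all()
        by_pix = {(r, c): i for i, t in enumerate(movie.terminals)
                  for r, c in t.pixels}
        # 0.01 tolerance: the impulse-response tail bleeds slightly across
        # the 1 s interleaves between epochs
        for _, row in feats.iterrows():
            model = movie.terminals[by_pix[(row.y, row.x)]].model
            assert row.contrast_class == model.contrast_pref
            assert row.dsi == pytest.approx(model.dsi_true, abs=0.01)
            assert row.csi == pytest.approx(model.csi_true, abs=0.01)
            assert row.pd_angle == model.pref_direction


class TestClusterTerminals:
    @staticmethod
    def uniform_features(pixels, t_pd=10):
        return pd.DataFrame([
            dict(x=int(c), y=int(r), dsi=1.0, csi=1.0, pd_angle=0.0,
                 t_pd_peak=t_pd, contrast_class="ON", layer="A", peak=1.0)
            for r, c in pixels
        ])

    def test_two_separated_terminals(self):
        px = [(r, c) for r in range(2) for c in range(2)]
        feats = self.uniform_features(px + [(r, c + 20) for r, c in px])
        clusters, _ = seg.cluster_terminals(feats, 0.5)
        assert len(clusters) == 2
        assert all(c.area == pytest.approx(1.0) for c in clusters)

    def test_single_pixel_in_range(self):
        feats = self.uniform_features([(3, 3)])
        clusters, _ = seg.cluster_terminals(feats, 1.5)  # 2.25 um^2
        assert len(clusters) == 1
        assert clusters[0].area == pytest.approx(2.25)

    def test_single_pixel_out_of_range(self):
        clusters, _ = seg.cluster_terminals(
            self.uniform_features([(3, 3)]), 0.5
        )  # 0.25 um^2 < 1
        assert clusters == []

    def test_oversized_blob_split_against_merge_height_scan(self):
        # 40 contiguous px (10 um^2 > 6.5) with uniform features: the chosen
        # cut must attain the count an exhaustive scan of every merge height
        # finds, and every retained cluster must be in range
        from scipy.cluster.hierarchy import fcluster, linkage

        feats = self.uniform_features(
            [(r, c) for r in range(4) for c in range(10)]
        )
        clusters, cuts = seg.cluster_terminals(feats, 0.5)
        X = np.column_stack([feats.x, feats.y, feats.t_pd_peak]).astype(float)
        Z = linkage(X, method="average")
        best = 0
        for h in np.concatenate([[0.0], np.unique(Z[:, 2])]):
            labels = fcluster(Z, t=h, criterion="distance")
            areas = np.bincount(labels)[1:] * 0.25
            best = max(best, int(((areas >= 1) & (areas <= 6.5)).sum()))
        assert len(clusters) == best > 0
        assert all(1.0 <= c.area <= 6.5 for c in clusters)

    def test_input_order_invariance(self, planted_movie):
        movie, epochs = planted_movie
        feats = seg.pixel_selectivity(movie.frames, 15.0, epochs, k_sd=2)
        rng = np.random.default_rng(0)
        shuffled = feats.sample(frac=1.0, random_state=3).reset_index(drop=True)
        c1, _ = seg.cluster_terminals(feats, 0.5)
        c2, _ = seg.cluster_terminals(shuffled, 0.5)
        part1 = sorted(tuple(sorted(map(tuple, c.pixels))) for c in c1)
        part2 = sorted(tuple(sorted(map(tuple, c.pixels))) for c in c2)
        assert part1 == part2

    def test_empty_group_is_empty_list(self):
        clusters, cuts = seg.cluster_terminals(
            pd.DataFrame(columns=["x", "y", "t_pd_peak", "contrast_class",
                                  "layer"]), 0.5
        )
        assert clusters == [] and cuts == {}

    def test_noiseless_planted_recovery(self, planted_movie):
        movie, epochs = planted_movie
        feats = seg.pixel_selectivity(movie.frames, 15.0, epochs, k_sd=2)
        clusters, _ = seg.cluster_terminals(feats, movie.pixel_size)
        assert len(clusters) == 20
        assert centroid_hits(clusters, movie.terminals) == 20


class TestMatchClusters:
    def test_identity_on_same_movie(self, planted_movie):
        movie, epochs = planted_movie
        feats = seg.pixel_selectivity(movie.frames, 15.0, epochs, k_sd=2)
        clusters, _ = seg.cluster_terminals(feats, movie.pixel_size)
        matched, report = seg.match_clusters(clusters, movie.frames)
        assert matched is clusters
        assert (report["n_outside_foreground"] == 0).all()

    def test_grid_mismatch_rejected(self, planted_movie):
        movie, epochs = planted_movie
        feats = seg.pixel_selectivity(movie.frames, 15.0, epochs, k_sd=2)
        clusters, _ = seg.cluster_terminals(feats, movie.pixel_size)
        with pytest.raises(GeometryError):
            seg.match_clusters(clusters, movie.frames[:, :16, :16])

    def test_matched_traces_correlate_with_ground_truth(self, edge_stimulus):
        # masks saved from one recording, applied to a second noisy recording
        # of the same cells, must recover the planted responses (r > 0.9)
        stim, epochs = edge_stimulus
        models = make_terminal_models(6)
        placements = synth.place_terminals(6, (48, 48), seed=4)
        terms = [synth.Terminal(p, m) for p, m in zip(placements, models)]
        first = synth.render_terminal_movie(
            terms, stim, epochs, 15.0, (48, 48)
        )
        feats = seg.pixel_selectivity(first.frames, 15.0, epochs, k_sd=2)
        clusters, _ = seg.cluster_terminals(feats, 0.5)
        peak = max(tr.max() for tr in first.dff_traces)
        second = synth.render_terminal_movie(
            terms, stim, epochs, 15.0, (48, 48),
            noise_sigma=100.0 * peak / 10.0, seed=21,
        )
        matched, _ = seg.match_clusters(clusters, second.frames)
        traces = seg.extract_cluster_traces(second.frames, matched)
        hits = 0
        for tr in traces:
            dff = tr / 100.0 - 1.0
            best = max(
                np.corrcoef(dff, gt)[0, 1] for gt in second.dff_traces
            )
            hits += best > 0.9
        assert hits == len(matched) == 6
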