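"""The synthetic-movie generator: transient curves, scene layout, rendering."""

import numpy as np
import pytest
from scipy import ndimage

from astrofiu import SimulationConfig, generate_scene, render_video, simulate_curve
from astrofiu.simulate import (PlacementError, raw_transient_curve, rescale_curve,
                               shifted_curve, snr_to_sigma, save_scene)


class TestTransientCurve:
    def test_single_transient_shape(self):
        # (t - t0) * exp(-(t - t0)/eta) peaks eta frames after onset
        raw = raw_transient_curve([0], eta=2.0, n_frames=50)
        assert raw[2] == pytest.approx(2 * np.exp(-1.0), abs=1e-12)
        assert np.argmax(raw) == 2

    def test_no_events_is_flat_zero(self):
        assert np.all(raw_transient_curve([], eta=2.0, n_frames=30) == 0)

    def test_two_separated_events_two_local_maxima(self):
        raw = raw_transient_curve([5, 60], eta=2.0, n_frames=100)
        interior = (raw[1:-1] > raw[:-2]) & (raw[1:-1] > raw[2:])
        assert interior.sum() == 2

    def test_rescaled_amplitude_matches_target(self):
        curve = simulate_curve([10, 40], eta=3.0, n_frames=100, max_dff0=2.5)
        assert curve.min() > 0
        assert (curve.max() - curve.min()) / curve.min() == pytest.approx(2.5)

    @pytest.mark.parametrize("kwargs", [
        dict(onsets=[0], eta=0.0),
        dict(onsets=[0], eta=-1.0),
        dict(onsets=[], eta=2.0),
        dict(onsets=[200], eta=2.0),
    ])
    def test_invalid_configurations_raise(self, kwargs):
        with pytest.raises(ValueError):
            simulate_curve(kwargs["onsets"], kwargs["eta"], n_frames=100,
                           max_dff0=1.0)

    def test_rescale_rejects_constant_curve(self):
        with pytest.raises(ValueError):
            rescale_curve(np.ones(20), 1.0)


class TestSnr:
    def test_zero_db_means_sigma_equals_magnitude(self):
        assert snr_to_sigma(1.0, 0.0) == pytest.approx(1.0)

    def test_five_db(self):
        assert snr_to_sigma(1.0, 5.0) == pytest.approx(10 ** -0.25)
        assert snr_to_sigma(1.0, 5.0) == pytest.approx(0.5623, abs=1e-4)


class TestSceneLayout:
    @pytest.fixture(scope="class")
    @classmethod
    def scene(cls):
        return generate_scene(SimulationConfig(height=96, width=96, n_fius=8,
                                               area_range=(20, 120), seed=3))

    def test_masks_pairwise_disjoint(self, scene):
        all_masks = scene.fiu_masks + scene.inactive_masks
        acc = np.zeros_like(all_masks[0], dtype=int)
        for m in all_masks:
            acc += m
        assert acc.max() <= 1

    def test_each_unit_mask_is_connected(self, scene):
        for m in scene.fiu_masks:
            _, n = ndimage.label(m, structure=np.ones((3, 3)))
            assert n == 1

    def test_delays_nonnegative_with_zero_source(self, scene):
        for m, delay, src in zip(scene.fiu_masks, scene.delay_maps, scene.sources):
            assert delay[src] == 0
            assert delay[m].min() >= 0

    def test_beta_fades_toward_boundary(self, scene):
        for m, beta in zip(scene.fiu_masks, scene.beta_maps):
            assert beta[m].min() > 0
            dist = ndimage.distance_transform_edt(m)
            interior = m & (dist >= 3)
            edge = m & (dist <= 1)
            if interior.any() and edge.any():
                assert beta[edge].mean() < beta[interior].mean()

    def test_sigma_positive_everywhere(self, scene):
        assert scene.sigma_map.min() > 0

    def test_infinite_velocity_gives_zero_delays(self):
        cfg = SimulationConfig(height=48, width=48, n_fius=3,
                               velocity_range=(np.inf, np.inf),
                               area_range=(20, 80), seed=4)
        scene = generate_scene(cfg)
        for m, d in zip(scene.fiu_masks, scene.delay_maps):
            assert np.all(d[m] == 0)

    def test_unplaceable_request_raises(self):
        cfg = SimulationConfig(height=16, width=16, n_fius=40,
                               area_range=(30, 60), seed=0, max_place_tries=20)
        with pytest.raises(PlacementError):
            generate_scene(cfg)


class TestRender:
    def test_noiseless_forward_model_is_exact(self):
        cfg = SimulationConfig(height=48, width=48, n_fius=2,
                               velocity_range=(np.inf, np.inf),
                               area_range=(30, 80), seed=5)
        scene = generate_scene(cfg)
        stack = render_video(scene, noise=False)
        for m_idx, mask in enumerate(scene.fiu_masks):
            i, j = np.argwhere(mask)[0]
            expected = (scene.baseline_map[i, j]
                        + scene.beta_maps[m_idx][i, j] * scene.true_curves[m_idx])
            np.testing.assert_allclose(stack.data[:, i, j], expected, rtol=1e-12)

    def test_noiseless_delay_recovered_by_lag_scan(self):
        cfg = SimulationConfig(height=48, width=48, n_fius=2,
                               velocity_range=(1.0, 2.0),
                               area_range=(40, 100), seed=6)
        scene = generate_scene(cfg)
        stack = render_video(scene, noise=False)
        for m_idx, mask in enumerate(scene.fiu_masks):
            curve = scene.true_curves[m_idx]
            pix = np.argwhere(mask)[::7]
            for i, j in pix:
                d_true = scene.delay_maps[m_idx][i, j]
                y = stack.data[:, i, j]
                # brute-force lag scan against the shifted true curve
                corrs = [np.corrcoef(y, shifted_curve(curve, d))[0, 1]
                         for d in range(0, 20)]
                assert np.argmax(corrs) == d_true

    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(height=48, width=48, n_fius=3, seed=7,
                               area_range=(20, 80))
        s1 = generate_scene(cfg)
        s2 = generate_scene(cfg)
        np.testing.assert_array_equal(s1.true_curves, s2.true_curves)
        for a, b in zip(s1.fiu_masks, s2.fiu_masks):
            np.testing.assert_array_equal(a, b)
        v1 = render_video(s1, seed=11)
        v2 = render_video(s2, seed=11)
        np.testing.assert_array_equal(v1.data, v2.data)
        assert not np.array_equal(v1.data, render_video(s1, seed=12).data)

    def test_background_noise_sd_matches_sigma(self):
        cfg = SimulationConfig(height=16, width=16, n_fius=1, duration_s=20000.0,
                               area_range=(10, 20), seed=8)
        scene = generate_scene(cfg)
        stack = render_video(scene)
        bg = ~scene.active_mask
        i, j = np.argwhere(bg)[0]
        sd = stack.data[:, i, j].std()
        assert sd == pytest.approx(scene.sigma_map[i, j], rel=0.03)

    def test_empirical_snr_matches_config(self, small_scene):
        scene, stack = small_scene
        clean = render_video(scene, noise=False).data
        for m_idx, mask in enumerate(scene.fiu_masks):
            pix = np.argwhere(mask)[::2]
            snrs = []
            for i, j in pix:
                magnitude = clean[:, i, j].max() - clean[:, i, j].min()
                noise_sd = (stack.data[:, i, j] - clean[:, i, j]).std()
                snrs.append(20 * np.log10(magnitude / noise_sd))
            assert abs(np.mean(snrs) - scene.config.snr_db) < 0.5


def test_save_scene_writes_readable_ground_truth(tmp_path, small_scene):
    import tifffile
    import pandas as pd
    scene, _ = small_scene
    save_scene(tmp_path, scene)
    labels = tifffile.imread(tmp_path / "labels.tif")
    assert labels.max() == len(scene.fiu_masks)
    curves = pd.read_csv(tmp_path / "true_curves.csv")
    assert set(curves.columns) == {"fiu_id", "frame", "value"}
    assert curves["fiu_id"].nunique() == len(scene.fiu_masks)
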