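"""Curve learning, membership scoring, unit extraction and the full detector."""

import numpy as np
import pytest

from astrofiu import (FIUDetector, SimulationConfig, VideoStack, curve_fidelity,
                      detection_metrics, fit_characteristic, fit_zscore_map,
                      extract_fiu, generate_scene, refine_curve, render_video)
from astrofiu.metrics import attach_fidelities
from astrofiu.scores import correlation_zscore_map
from astrofiu.simulate import raw_transient_curve, rescale_curve


def _flat_init(mask):
    """An init map whose maximum sits inside ``mask``."""
    return np.where(mask, 1.0, 0.0)


def _two_unit_movie(target_corr, snr_db=5.0, seed=0, n=100):
    """Two touching rectangular units whose curves correlate at a set level."""
    rng = np.random.default_rng(seed)
    base = raw_transient_curve([10, 55], 4.0, n)
    other = raw_transient_curve([30, 75], 4.0, n)
    bc = base - base.mean()
    oc = other - other.mean()
    oc = oc - (oc @ bc) / (bc @ bc) * bc
    a = target_corr / np.sqrt(1 - target_corr ** 2) \
        * np.linalg.norm(oc) / np.linalg.norm(bc)
    mixed = a * bc + oc
    curve_a = rescale_curve(base, 2.0)
    curve_b = rescale_curve(mixed - mixed.min(), 2.0)
    h, w = 20, 24
    mask_a = np.zeros((h, w), bool)
    mask_a[4:16, 2:12] = True
    mask_b = np.zeros((h, w), bool)
    mask_b[4:16, 12:22] = True
    sig_a = (curve_a.max() - curve_a.min()) * 10 ** (-snr_db / 20)
    sig_b = (curve_b.max() - curve_b.min()) * 10 ** (-snr_db / 20)
    data = np.zeros((n, h, w)) + 0.2
    data[:, mask_a] += curve_a[:, None]
    data[:, mask_b] += curve_b[:, None]
    sig = np.full((h, w), (sig_a + sig_b) / 2)
    sig[mask_a] = sig_a
    sig[mask_b] = sig_b
    data += rng.standard_normal(data.shape) * sig
    return VideoStack(data), mask_a, mask_b


class TestFitCharacteristic:
    def test_noiseless_synchronous_unit_is_a_fixed_point(self):
        cfg = SimulationConfig(height=48, width=48, n_fius=1,
                               velocity_range=(np.inf, np.inf),
                               area_range=(40, 80), seed=5)
        scene = generate_scene(cfg)
        stack = render_video(scene, noise=False)
        model = fit_characteristic(stack, scene.fiu_masks[0],
                                   _flat_init(scene.fiu_masks[0]))
        assert model.converged and model.n_iter <= 3
        assert curve_fidelity(model.curve, scene.true_curves[0]) > 1 - 1e-10

    def test_unit_norm_constraint(self, small_scene):
        scene, stack = small_scene
        zmap = correlation_zscore_map(stack)
        for mask in scene.fiu_masks[:3]:
            model = fit_characteristic(stack, mask, zmap)
            assert np.linalg.norm(model.curve) == pytest.approx(1.0, abs=1e-9)
            assert abs(model.curve.mean()) < 1e-9

    def test_noiseless_split_delay_recovered_exactly(self):
        # half the pixels carry the curve delayed by 3 frames
        n, h, w = 100, 10, 12
        curve = rescale_curve(raw_transient_curve([20, 60], 4.0, n), 2.0)
        data = np.zeros((n, h, w)) + 1.0
        region = np.zeros((h, w), bool)
        region[2:8, 2:10] = True
        delayed = np.zeros((h, w), bool)
        delayed[2:8, 6:10] = True
        idx = np.arange(n)
        data[:, region & ~delayed] = curve[:, None]
        data[:, delayed] = curve[np.clip(idx - 3, 0, n - 1)][:, None]
        model = fit_characteristic(VideoStack(data), region, _flat_init(region))
        tau = model.tau_map
        offs = tau[region & ~delayed]
        offs_d = tau[delayed]
        assert len(np.unique(offs)) == 1
        assert len(np.unique(offs_d)) == 1
        assert offs_d[0] - offs[0] == 3

    def test_noiseless_propagating_lags_constant_offset(self):
        cfg = SimulationConfig(height=64, width=64, n_fius=3, snr_db=5.0,
                               velocity_range=(2.0, 4.0), area_range=(30, 80),
                               seed=9)
        scene = generate_scene(cfg)
        stack = render_video(scene, noise=False)
        zmap = correlation_zscore_map(stack)
        for g, mask in enumerate(scene.fiu_masks):
            model = fit_characteristic(stack, mask, zmap)
            diff = model.tau_map[mask] - scene.delay_maps[g][mask]
            assert len(np.unique(diff)) == 1

    def test_snr10_fidelity_above_095(self):
        fids = []
        for seed in range(6):
            cfg = SimulationConfig(height=48, width=48, n_fius=1, snr_db=10.0,
                                   velocity_range=(1.0, 5.0),
                                   area_range=(60, 120), seed=100 + seed)
            scene = generate_scene(cfg)
            stack = render_video(scene)
            zmap = correlation_zscore_map(stack)
            model = fit_characteristic(stack, scene.fiu_masks[0], zmap)
            fids.append(curve_fidelity(model.curve, scene.true_curves[0],
                                       lag_compensate=True, max_lag=3))
        assert np.mean(fids) > 0.95
        assert min(fids) > 0.9

    def test_single_pixel_region_is_legal(self, small_scene):
        _scene, stack = small_scene
        region = np.zeros(stack.data.shape[1:], bool)
        region[10, 10] = True
        model = fit_characteristic(stack, region, _flat_init(region))
        own = stack.data[:, 10, 10]
        assert abs(curve_fidelity(model.curve, own)) == pytest.approx(1.0, abs=1e-9)

    def test_convergence_at_moderate_snr(self, low_snr_scene):
        scene, stack = low_snr_scene
        zmap = correlation_zscore_map(stack)
        flags = [fit_characteristic(stack, m, zmap).converged
                 for m in scene.fiu_masks]
        assert np.mean(flags) >= 0.95 or sum(flags) >= len(flags) - 1


class TestMembershipScore:
    def test_residual_term_separates_correlated_neighbors(self):
        """Scoring against one unit's curve: the residual-correlation penalty
        keeps a strongly correlated neighbor unit out of the grown mask,
        while the fit-only score merges the two."""
        b_with, b_without = [], []
        for seed in (0, 1, 2):
            stack, mask_a, mask_b = _two_unit_movie(0.6, seed=seed)
            region = mask_a | mask_b
            model = fit_characteristic(stack, mask_a, _flat_init(mask_a))
            for variant, acc in (("with_residual", b_with),
                                 ("without_residual", b_without)):
                fmap = fit_zscore_map(stack, region, model, variant=variant)
                mask, _p = extract_fiu(fmap)
                acc.append((mask & mask_b).sum() / mask_b.sum())
        assert np.mean(b_with) < 0.2
        assert np.mean(b_without) > 0.5

    def test_contrast_grows_as_curves_decorrelate(self):
        gaps = []
        for corr in (0.2, 0.4, 0.6):
            g = []
            for seed in (0, 1, 2):
                stack, mask_a, mask_b = _two_unit_movie(corr, seed=seed)
                model = fit_characteristic(stack, mask_a, _flat_init(mask_a))
                fmap = fit_zscore_map(stack, mask_a | mask_b, model)
                za, zb = fmap.values[mask_a], fmap.values[mask_b]
                g.append((za.mean() - zb.mean())
                         / np.sqrt(0.5 * (za.var() + zb.var())))
            gaps.append(np.mean(g))
        assert gaps[0] > gaps[1] > gaps[2]

    def test_scores_defined_only_on_region(self, small_scene):
        scene, stack = small_scene
        mask = scene.fiu_masks[0]
        model = fit_characteristic(stack, mask, _flat_init(mask))
        fmap = fit_zscore_map(stack, mask, model)
        assert np.all(np.isfinite(fmap.values[mask]))
        assert np.all(np.isnan(fmap.values[~mask]))


class TestExtractRefine:
    def test_uniformly_high_map_extracts_whole_region(self, small_scene):
        scene, stack = small_scene
        mask = scene.fiu_masks[0]
        model = fit_characteristic(stack, mask, _flat_init(mask))
        fmap = fit_zscore_map(stack, mask, model)
        fmap.values[mask] = 8.0 + 0.01 * np.arange(mask.sum())
        out, p = extract_fiu(fmap)
        assert (out == mask).all()
        assert p < 1e-10

    def test_refine_single_pixel_recovers_raw_curve(self, small_scene):
        _scene, stack = small_scene
        region = np.zeros(stack.data.shape[1:], bool)
        region[20, 20] = True
        model = fit_characteristic(stack, region, _flat_init(region))
        model.mask = region
        model.beta_map[20, 20] = 1.0
        model.sigma2_map[20, 20] = 1.0
        model.tau_map[20, 20] = 0
        refined = refine_curve(stack, model)
        np.testing.assert_allclose(refined, stack.data[:, 20, 20])

    def test_refine_equal_weights_equals_scaled_mean(self, small_scene):
        _scene, stack = small_scene
        region = np.zeros(stack.data.shape[1:], bool)
        region[5:8, 5:8] = True
        model = fit_characteristic(stack, region, _flat_init(region))
        model.mask = region
        model.beta_map[region] = 2.0
        model.sigma2_map[region] = 0.5
        model.tau_map[region] = 0
        refined = refine_curve(stack, model)
        mean_curve = stack.data[:, region].mean(axis=1)
        np.testing.assert_allclose(refined, 9 * (2.0 / 0.5) * mean_curve)

    def test_refine_empty_mask_rejected(self, small_scene):
        scene, stack = small_scene
        mask = scene.fiu_masks[0]
        model = fit_characteristic(stack, mask, _flat_init(mask))
        with pytest.raises(ValueError):
            refine_curve(stack, model, mask=np.zeros_like(mask))


class TestDetector:
    def test_pure_noise_yields_no_units(self):
        hits = 0
        for seed in range(12):
            rng = np.random.default_rng(3000 + seed)
            det = FIUDetector().fit(rng.standard_normal((60, 48, 48)))
            hits += det.n_fius_ > 0
        assert hits <= 1  # ~alpha-level family-wise rate

    def test_five_disjoint_units_all_detected(self):
        cfg = SimulationConfig(height=96, width=96, n_fius=5, snr_db=10.0,
                               area_range=(60, 150), seed=12)
        scene = generate_scene(cfg)
        det = FIUDetector().fit(render_video(scene))
        rep = detection_metrics([f.mask for f in det.fius_], scene.fiu_masks)
        assert rep.recall == 1.0
        assert rep.precision == 1.0
        attach_fidelities(rep, [f.refined_curve for f in det.fius_],
                          scene.true_curves)
        assert rep.mean_fidelity > 0.9

    def test_three_connected_units_resolved(self):
        """One active region containing three touching units with distinct
        curves is split into three separate units."""
        rng = np.random.default_rng(42)
        n, h, w = 100, 26, 20
        masks = []
        data = np.zeros((n, h, w)) + 0.2
        curves = []
        onset_sets = [(8, 50), (25, 70), (40, 88)]
        for k in range(3):
            m = np.zeros((h, w), bool)
            m[2 + 8 * k: 10 + 8 * k, 4:16] = True
            masks.append(m)
            c = rescale_curve(raw_transient_curve(onset_sets[k], 3.0, n), 2.0)
            curves.append(c)
            sig = (c.max() - c.min()) * 10 ** (-10.0 / 20)
            data[:, m] += c[:, None] + 0.0
            data[:, m] += rng.standard_normal((n, m.sum())) * sig
        bg = ~(masks[0] | masks[1] | masks[2])
        data[:, bg] += rng.standard_normal((n, bg.sum())) * 0.5
        det = FIUDetector().fit(VideoStack(data))
        rep = detection_metrics([f.mask for f in det.fius_], masks)
        assert rep.recall == 1.0
        assert rep.n_correct == 3

    def test_output_masks_disjoint_connected_normed(self, small_scene):
        from scipy import ndimage
        scene, stack = small_scene
        det = FIUDetector().fit(stack)
        assert det.n_fius_ > 0
        acc = np.zeros(det.labels_.shape, dtype=int)
        for f in det.fius_:
            acc += f.mask
            _, ncomp = ndimage.label(f.mask, structure=np.ones((3, 3)))
            assert ncomp == 1
            assert np.linalg.norm(f.curve) == pytest.approx(1.0, abs=1e-9)
            assert f.p_value <= det.alpha
        assert acc.max() <= 1  # each pixel in at most one unit

    def test_velocity_has_little_impact(self):
        """Detection quality at slow, medium and fast propagation differs by
        less than 0.05 (pooled over movies)."""
        rates = {}
        for vel in (1.0, 5.0, 30.0):
            nd = nt = nc = nr = 0
            for seed in (61, 62, 63, 64, 65):
                cfg = SimulationConfig(height=96, width=96, n_fius=12,
                                       snr_db=10.0, velocity_range=(vel, vel),
                                       area_range=(30, 120), seed=seed)
                scene = generate_scene(cfg)
                det = FIUDetector().fit(render_video(scene))
                rep = detection_metrics([f.mask for f in det.fius_],
                                        scene.fiu_masks)
                nd += rep.n_detected
                nt += rep.n_truth
                nc += rep.n_correct
                nr += rep.n_reported
            rates[vel] = (nd / nt, nc / nr)
        recalls = [r[0] for r in rates.values()]
        precisions = [r[1] for r in rates.values()]
        assert max(recalls) - min(recalls) < 0.05 + 1e-9
        assert max(precisions) - min(precisions) < 0.05 + 1e-9

    def test_performance_monotone_in_snr(self):
        f_scores = []
        for snr in (0.0, 5.0, 10.0, 15.0):
            nd = nt = nc = nr = 0
            for seed in (71, 72):
                cfg = SimulationConfig(height=64, width=64, n_fius=6,
                                       snr_db=snr, area_range=(30, 150),
                                       seed=seed)
                scene = generate_scene(cfg)
                det = FIUDetector().fit(render_video(scene))
                rep = detection_metrics([f.mask for f in det.fius_],
                                        scene.fiu_masks)
                nd += rep.n_detected
                nt += rep.n_truth
                nc += rep.n_correct
                nr += rep.n_reported
            recall = nd / nt
            precision = nc / nr if nr else 0.0
            f_scores.append(2 * recall * precision / (recall + precision)
                            if recall + precision else 0.0)
        assert all(b >= a - 0.05 for a, b in zip(f_scores, f_scores[1:]))
        assert f_scores[-1] > f_scores[0]

    def test_sklearn_protocol(self):
        from sklearn.base import clone
        det = FIUDetector(alpha=0.01, u_tau=3)
        cloned = clone(det)
        assert cloned.get_params()["alpha"] == 0.01
        assert cloned.get_params()["u_tau"] == 3
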