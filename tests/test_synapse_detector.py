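import numpy as np
import pytest

from i2g.core_model import synapse_from_mask
from i2g.synapse_detector import (
    FEATURE_NAMES,
    DetectorConfig,
    compute_features,
    predict_probability,
    score_detections,
    threshold_and_group,
    train_classifier,
    vesicle_correlation,
    _disc_template,
)
from i2g.synthetic_data import SceneParams, generate_scene


class TestVesicleCorrelation:
    def test_exact_template_copy_peaks_at_one(self):
        tpl = _disc_template(2)
        image = np.full((40, 40), 0.75)
        image[10 : 10 + tpl.shape[0], 15 : 15 + tpl.shape[1]] = tpl
        cc = vesicle_correlation(image, template_radius=2)
        cz = 10 + tpl.shape[0] // 2
        cx = 15 + tpl.shape[1] // 2
        assert cc[cz, cx] == pytest.approx(1.0, abs=1e-10)
        assert cc.max() <= 1.0 + 1e-12

    def test_constant_image_yields_zeros(self):
        cc = vesicle_correlation(np.full((3, 30, 30), 0.4), template_radius=2)
        assert np.all(cc == 0.0)

    def test_template_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="template"):
            vesicle_correlation(np.zeros((2, 5, 5)), template_radius=4)

    def test_planted_vesicles_score_above_map_percentile(self, default_scene):
        scene = default_scene
        cc = vesicle_correlation(scene.image, template_radius=2)
        vc = scene.vesicle_centers
        at_centers = cc[vc[:, 0], vc[:, 1], vc[:, 2]]
        assert np.median(at_centers) > np.percentile(cc, 95)


class TestComputeFeatures:
    def test_constant_image_has_zero_gradient_channel(self):
        img = np.full((2, 20, 20), 0.5)
        stack = compute_features(img, np.zeros_like(img), np.zeros_like(img))
        grad = stack.channels[stack.names.index("gradient_magnitude")]
        assert np.all(grad == 0.0)

    def test_channel_count_and_names_stable(self, default_scene):
        scene = default_scene
        vmap = vesicle_correlation(scene.image, 2)
        s1 = compute_features(scene.image, scene.membrane_prob, vmap)
        s2 = compute_features(scene.image, scene.membrane_prob, vmap)
        assert s1.channels.shape[0] == 10
        assert s1.names == FEATURE_NAMES == s2.names
        assert np.array_equal(s1.channels, s2.channels)

    def test_step_edge_gradient_maximal_on_edge(self):
        img = np.zeros((1, 16, 16))
        img[:, :, 8:] = 1.0
        stack = compute_features(img, np.zeros_like(img), np.zeros_like(img))
        grad = stack.channels[stack.names.index("gradient_magnitude")][0]
        # central-difference oracle on the 1D profile: maximum where the
        # step is, i.e. columns 7 and 8
        oracle = np.abs(np.gradient(img[0, 0]))
        assert set(np.argwhere(grad[5] == grad[5].max()).ravel()) == set(
            np.argwhere(oracle == oracle.max()).ravel()
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            compute_features(np.zeros((2, 8, 8)), np.zeros((2, 8, 9)), np.zeros((2, 8, 8)))


class TestTrainPredict:
    def test_equal_seeds_give_identical_probabilities(self, default_scene, scene_config):
        scene = default_scene
        vmap = vesicle_correlation(scene.image, scene_config.template_radius)
        stack = compute_features(scene.image, scene.membrane_prob, vmap, scene_config)
        p = []
        for _ in range(2):
            det = train_classifier(stack, scene.pixel_truth, scene_config)
            p.append(predict_probability(det, stack, scene.membrane_prob, scene_config))
        assert np.array_equal(p[0], p[1])

    def test_single_class_truth_rejected(self, default_scene, scene_config):
        scene = default_scene
        vmap = vesicle_correlation(scene.image, scene_config.template_radius)
        stack = compute_features(scene.image, scene.membrane_prob, vmap, scene_config)
        with pytest.raises(ValueError, match="both"):
            train_classifier(stack, np.zeros_like(scene.pixel_truth), scene_config)

    def test_noise_free_scene_fits_training_volume(self, scene_config):
        scene = generate_scene(SceneParams(seed=4, noise_sigma=0.0))
        vmap = vesicle_correlation(scene.image, scene_config.template_radius)
        stack = compute_features(scene.image, scene.membrane_prob, vmap, scene_config)
        det = train_classifier(stack, scene.pixel_truth, scene_config)
        prob = predict_probability(det, stack, scene.membrane_prob, scene_config)
        acc = ((prob >= 0.5) == (scene.pixel_truth > 0)).mean()
        assert acc >= 0.99

    def test_full_mask_threshold_zeroes_everything(self, default_scene, scene_config, trained_on_default):
        det, stack = trained_on_default
        cfg = DetectorConfig(**{**scene_config.__dict__, "membrane_mask_threshold": 1.0})
        mem = np.clip(default_scene.membrane_prob, 0, 0.999)
        prob = predict_probability(det, stack, mem, cfg)
        assert np.all(prob == 0.0)

    def test_zero_mask_threshold_equals_unmasked_forest(self, default_scene, scene_config, trained_on_default):
        det, stack = trained_on_default
        cfg = DetectorConfig(**{**scene_config.__dict__, "membrane_mask_threshold": 0.0})
        prob = predict_probability(det, stack, default_scene.membrane_prob, cfg)
        X = stack.as_table()
        pos = int(np.flatnonzero(det.forest.classes_ == True)[0])  # noqa: E712
        raw = det.forest.predict_proba(X)[:, pos].reshape(stack.shape)
        assert np.allclose(prob, raw)

    def test_masked_voxels_are_exactly_zero(self, default_scene, scene_config, trained_on_default):
        det, stack = trained_on_default
        prob = predict_probability(det, stack, default_scene.membrane_prob, scene_config)
        off = default_scene.membrane_prob < scene_config.membrane_mask_threshold
        assert np.all(prob[off] == 0.0)

    def test_vesicle_channels_are_informative(self, trained_on_default):
        det, _ = trained_on_default
        imps = det.importances
        assert imps["vesicle_peak_density"] > 0.01
        assert imps["vesicle_peak_density"] + imps["vesicle_correlation"] > 0.05


def _box(prob, z0, nz, y0, ny, x0, nx, value=1.0):
    prob[z0 : z0 + nz, y0 : y0 + ny, x0 : x0 + nx] = value


class TestThresholdAndGroup:
    def test_paper_scale_size_filters(self):
        """900/1500/2500-voxel components under the full-scale thresholds:
        the 900-voxel one falls below the 1000-voxel 3D minimum."""
        prob = np.zeros((30, 120, 120))
        _box(prob, 0, 9, 0, 10, 0, 10)  # 900 voxels
        _box(prob, 0, 15, 0, 10, 40, 10)  # 1500 voxels
        _box(prob, 0, 25, 0, 10, 100, 10)  # 2500 voxels
        out = threshold_and_group(prob, DetectorConfig())
        assert len(out) == 2
        assert sorted(s.n_voxels for s in out) == [1500, 2500]

    def test_oversized_2d_footprint_removed(self):
        prob = np.zeros((3, 60, 100))
        _box(prob, 1, 1, 0, 60, 0, 100)  # one slice of 6000 px
        assert threshold_and_group(prob, DetectorConfig()) == []

    def test_all_zero_probability_gives_no_objects(self):
        assert threshold_and_group(np.zeros((4, 10, 10)), DetectorConfig()) == []

    def test_confidence_is_component_mean_probability(self):
        prob = np.zeros((4, 20, 20))
        _box(prob, 0, 2, 0, 4, 0, 4, value=0.8)
        cfg = DetectorConfig(prob_threshold=0.5, min_3d_voxels=1, max_2d_pixels=10_000)
        out = threshold_and_group(prob, cfg)
        assert len(out) == 1
        assert out[0].confidence == pytest.approx(0.8)

    def test_raising_threshold_nests_detections(
        self, alt_scene, scene_config, trained_on_default
    ):
        """Raising the probability threshold only shrinks the supra-threshold
        voxel set, so every object found at a higher threshold lies inside
        exactly one object found at a lower threshold."""
        det, _ = trained_on_default
        vmap = vesicle_correlation(alt_scene.image, scene_config.template_radius)
        stack = compute_features(alt_scene.image, alt_scene.membrane_prob, vmap, scene_config)
        prob = predict_probability(det, stack, alt_scene.membrane_prob, scene_config)
        loose = DetectorConfig(**{**scene_config.__dict__, "prob_threshold": 0.3,
                                  "min_3d_voxels": 1, "max_2d_pixels": 10**9})
        prev = threshold_and_group(prob, loose)
        for thr in (0.5, 0.7, 0.9):
            cfg = DetectorConfig(**{**loose.__dict__, "prob_threshold": thr})
            cur = threshold_and_group(prob, cfg)
            prev_sets = [s.voxel_set() for s in prev]
            for obj in cur:
                vs = obj.voxel_set()
                assert sum(1 for p in prev_sets if vs <= p) == 1
            prev = cur

    def test_filter_is_idempotent_on_its_own_output(
        self, alt_scene, scene_config, trained_on_default
    ):
        det, _ = trained_on_default
        vmap = vesicle_correlation(alt_scene.image, scene_config.template_radius)
        stack = compute_features(alt_scene.image, alt_scene.membrane_prob, vmap, scene_config)
        prob = predict_probability(det, stack, alt_scene.membrane_prob, scene_config)
        survivors = threshold_and_group(prob, scene_config)
        rendered = np.zeros_like(prob)
        for s in survivors:
            rendered[s.voxels[:, 0], s.voxels[:, 1], s.voxels[:, 2]] = 1.0
        again = threshold_and_group(rendered, scene_config)
        assert {frozenset(s.voxel_set()) for s in again} == {
            frozenset(s.voxel_set()) for s in survivors
        }


class TestScoreDetections:
    def _syn(self, sid, voxels):
        return synapse_from_mask(sid, voxels, 1.0)

    def test_perfect_detection(self):
        truth = [self._syn(1, {(0, 0, 0), (0, 0, 1)}), self._syn(2, {(0, 5, 5)})]
        sc = score_detections(truth, truth)
        assert (sc.precision, sc.recall, sc.f1) == (1.0, 1.0, 1.0)

    def test_single_detection_cannot_claim_two_truths(self):
        blanket = self._syn(1, {(0, y, x) for y in range(10) for x in range(10)})
        truth = [self._syn(1, {(0, 0, 0)}), self._syn(2, {(0, 9, 9)})]
        sc = score_detections([blanket], truth)
        assert (sc.tp, sc.fn) == (1, 1)
        assert sc.f1 == pytest.approx(2 / 3)

    def test_greedy_matching_prefers_larger_overlap(self):
        t1 = self._syn(1, {(0, 0, x) for x in range(30)})
        t2 = self._syn(2, {(0, 2, x) for x in range(10)})
        d1 = self._syn(1, {(0, 0, x) for x in range(30)} | {(0, 2, x) for x in range(10)})
        sc = score_detections([d1], [t1, t2])
        assert (sc.tp, sc.fp, sc.fn) == (1, 0, 1)
        assert sc.precision == 1.0
        assert sc.recall == 0.5
        assert sc.f1 == pytest.approx(2 / 3)

    def test_no_overlap_scores_zero(self):
        sc = score_detections([self._syn(1, {(0, 0, 0)})], [self._syn(1, {(0, 5, 5)})])
        assert (sc.tp, sc.fp, sc.fn, sc.f1) == (0, 1, 1, 0.0)
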