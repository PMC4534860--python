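"""Shared fixtures: synthetic scenes and a trained detector."""

from __future__ import annotations

import pytest

from i2g.synapse_detector import (
    DetectorConfig,
    compute_features,
    train_classifier,
    vesicle_correlation,
)
from i2g.synthetic_data import SceneParams, generate_scene, spine_demo_scene

# scene-scale detector operating point: small synthetic scenes need size
# thresholds matched to their synapse size (~150 voxels), not full-volume ones
SCENE_DETECTOR = dict(
    prob_threshold=0.5, min_3d_voxels=10, max_2d_pixels=500, n_trees=50, tree_seed=0
)


@pytest.fixture(scope="session")
def default_scene():
    return generate_scene(SceneParams(seed=11))


@pytest.fixture(scope="session")
def alt_scene():
    return generate_scene(SceneParams(seed=12))


@pytest.fixture(scope="session")
def scene_config():
    return DetectorConfig(**SCENE_DETECTOR)


@pytest.fixture(scope="session")
def trained_on_default(default_scene, scene_config):
    """Detector trained on the default scene, with its feature stack."""
    scene = default_scene
    vmap = vesicle_correlation(scene.image, scene_config.template_radius)
    stack = compute_features(scene.image, scene.membrane_prob, vmap, scene_config)
    det = train_classifier(stack, scene.pixel_truth, scene_config)
    return det, stack


make_spine_scene = spine_demo_scene


@pytest.fixture()
def spine_scene():
    return spine_demo_scene()
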