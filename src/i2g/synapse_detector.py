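"""Lightweight, scalable synapse detection.

Vesicle evidence comes from normalized cross-correlation against a small dark
disc template, computed per 2D slice (EM stacks are strongly anisotropic, so
in-plane texture is the reliable signal).  Ten per-voxel feature channels —
intensity, smoothed intensity at two scales, gradient magnitude, local binary
patterns, structure-tensor anisotropy and trace, membrane probability,
vesicle correlation, and local vesicle-peak density — feed a random-forest
pixel classifier.  Prediction is restricted to high-probability membrane
voxels, and detections are formed by probability/size thresholds plus a 3D
connected-component analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import (
    local_binary_pattern,
    match_template,
    structure_tensor,
    structure_tensor_eigenvalues,
)
from sklearn.ensemble import RandomForestClassifier

from .core_model import SynapseAnnotation

__all__ = [
    "DetectorConfig",
    "FeatureStack",
    "TrainedDetector",
    "DetectionScore",
    "vesicle_correlation",
    "compute_features",
    "train_classifier",
    "predict_probability",
    "threshold_and_group",
    "score_detections",
]

FEATURE_NAMES = (
    "intensity",
    "gaussian_s1",
    "gaussian_s2",
    "gradient_magnitude",
    "local_binary_pattern",
    "structure_tensor_ratio",
    "structure_tensor_trace",
    "membrane_probability",
    "vesicle_correlation",
    "vesicle_peak_density",
)


@dataclass
class DetectorConfig:
    """Detector operating point and training hyper-parameters.

    The object-formation defaults (probability threshold 0.95, remove
    components below 1000 voxels in 3D or whose largest 2D slice footprint
    exceeds 5000 pixels) target full-scale EM volumes; scale the size
    thresholds down together with the scene when working on small synthetic
    volumes.
    """

    prob_threshold: float = 0.95
    min_3d_voxels: int = 1000
    max_2d_pixels: int = 5000
    n_trees: int = 100
    tree_seed: int = 0
    template_radius: int = 2
    membrane_mask_threshold: float = 0.5
    # training-time controls
    max_train_per_class: int = 20000
    vesicle_peak_threshold: float = 0.35
    density_sigma: float = 3.0

    def __post_init__(self) -> None:
        for name in ("prob_threshold", "membrane_mask_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]; got {v}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class FeatureStack:
    """Exactly ten named per-voxel feature planes sharing the image shape."""

    channels: np.ndarray  # (10, z, y, x)
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        if self.channels.shape[0] != len(self.names) or len(self.names) != 10:
            raise ValueError("feature stack must hold exactly 10 named channels")

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(self.channels.shape[1:])

    def as_table(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Flatten to an (n_voxels, 10) design matrix, optionally masked."""
        flat = self.channels.reshape(10, -1).T
        if mask is None:
            return flat
        return flat[mask.reshape(-1)]


@dataclass
class TrainedDetector:
    forest: RandomForestClassifier
    feature_names: tuple[str, ...]
    importances: dict[str, float]


def _disc_template(radius: int) -> np.ndarray:
    """Dark disc on a light background — the vesicle appearance model."""
    size = 2 * radius + 3
    yy, xx = np.mgrid[:size, :size] - (size - 1) / 2
    tpl = np.full((size, size), 0.75)
    tpl[yy**2 + xx**2 <= radius**2] = 0.30
    return tpl


def vesicle_correlation(image: np.ndarray, template_radius: int = 2) -> np.ndarray:
    """Normalized cross-correlation of a disc vesicle template, per 2D slice.

    Values are clipped to [-1, 1]; zero-variance (constant) regions are
    defined as correlation 0.  A 2D input is treated as a single slice.
    """
    tpl = _disc_template(template_radius)
    img = np.asarray(image, dtype=np.float64)
    squeeze = img.ndim == 2
    if squeeze:
        img = img[None]
    if img.shape[1] < tpl.shape[0] or img.shape[2] < tpl.shape[1]:
        raise ValueError(
            f"template {tpl.shape} larger than image plane {img.shape[1:]}"
        )
    out = np.empty_like(img)
    for z in range(img.shape[0]):
        with np.errstate(invalid="ignore", divide="ignore"):
            cc = match_template(img[z], tpl, pad_input=True)
        cc = np.clip(np.nan_to_num(cc, nan=0.0, posinf=0.0, neginf=0.0), -1.0, 1.0)
        # correlation is undefined over zero-variance windows; define it as 0
        local_mean = ndi.uniform_filter(img[z], size=tpl.shape)
        local_sq = ndi.uniform_filter(img[z] ** 2, size=tpl.shape)
        flat = (local_sq - local_mean**2) < 1e-12
        cc[flat] = 0.0
        out[z] = cc
    return out[0] if squeeze else out


def compute_features(
    image: np.ndarray,
    membrane_prob: np.ndarray,
    vesicle_map: np.ndarray,
    config: DetectorConfig | None = None,
) -> FeatureStack:
    """Assemble the ten-channel feature stack.

    Texture channels (smoothing, gradients, LBP, structure tensor) are
    computed per 2D slice; the two context channels are the membrane
    probability and the vesicle correlation, plus a smoothed density of
    high-correlation vesicle peaks that captures vesicle *clusters* rather
    than isolated matches.
    """
    config = config or DetectorConfig()
    img = np.asarray(image, dtype=np.float64)
    if img.shape != np.asarray(membrane_prob).shape or img.shape != np.asarray(vesicle_map).shape:
        raise ValueError(
            f"shape mismatch: image {img.shape}, membrane {np.shape(membrane_prob)}, "
            f"vesicle {np.shape(vesicle_map)}"
        )
    nz = img.shape[0]
    g1 = ndi.gaussian_filter(img, sigma=(0.0, 1.0, 1.0))
    g2 = ndi.gaussian_filter(img, sigma=(0.0, 2.0, 2.0))
    gy = np.gradient(img, axis=1)
    gx = np.gradient(img, axis=2)
    grad_mag = np.hypot(gy, gx)

    lbp = np.empty_like(img)
    st_ratio = np.empty_like(img)
    st_trace = np.empty_like(img)
    eps = 1e-12
    img_u8 = np.clip(img * 255, 0, 255).astype(np.uint8)
    for z in range(nz):
        lbp[z] = local_binary_pattern(img_u8[z], P=8, R=1.0, method="uniform")
        A = structure_tensor(img[z], sigma=1.0, order="rc")
        l1, l2 = structure_tensor_eigenvalues(A)
        st_ratio[z] = l2 / (l1 + eps)
        st_trace[z] = A[0] + A[2]  # Arr + Acc

    # vesicle clusters span neighboring slices, so the peak density integrates
    # a little across z even though all texture channels are per-slice
    peaks = (np.asarray(vesicle_map) >= config.vesicle_peak_threshold).astype(np.float64)
    density = ndi.gaussian_filter(
        peaks, sigma=(1.0, config.density_sigma, config.density_sigma)
    )

    channels = np.stack(
        [
            img,
            g1,
            g2,
            grad_mag,
            lbp,
            st_ratio,
            st_trace,
            np.asarray(membrane_prob, dtype=np.float64),
            np.asarray(vesicle_map, dtype=np.float64),
            density,
        ]
    )
    return FeatureStack(channels=channels)


def train_classifier(
    stack: FeatureStack,
    pixel_truth: np.ndarray,
    config: DetectorConfig,
) -> TrainedDetector:
    """Fit the random-forest pixel classifier on per-voxel feature vectors.

    Training voxels are restricted to the membrane search region (membrane
    probability at or above ``membrane_mask_threshold``, read from the
    membrane channel of the stack) — the same restriction prediction applies.
    This keeps the classifier focused on the hard synapse-vs-membrane
    distinction instead of the easy membrane-vs-cytoplasm one.  Both classes
    are subsampled to at most ``max_train_per_class`` voxels (seeded).
    Feature importances (Gini) are reported per channel name.
    """
    truth = np.asarray(pixel_truth).astype(bool)
    if truth.shape != stack.shape:
        raise ValueError(f"truth shape {truth.shape} != stack shape {stack.shape}")
    y = truth.reshape(-1)
    membrane = stack.channels[stack.names.index("membrane_probability")]
    region = (membrane >= config.membrane_mask_threshold).reshape(-1)
    if not (y & region).any() or not (~y & region).any():
        raise ValueError("training requires both synapse and background voxels")
    X = stack.as_table()
    rng = np.random.default_rng(config.tree_seed)
    idx_parts = []
    for cls in (True, False):
        idx = np.flatnonzero((y == cls) & region)
        if idx.size > config.max_train_per_class:
            idx = rng.choice(idx, size=config.max_train_per_class, replace=False)
        idx_parts.append(np.sort(idx))
    sel = np.concatenate(idx_parts)
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        random_state=config.tree_seed,
        n_jobs=1,
        oob_score=False,
    )
    forest.fit(X[sel], y[sel])
    importances = dict(zip(stack.names, forest.feature_importances_.tolist()))
    return TrainedDetector(forest=forest, feature_names=stack.names, importances=importances)


def predict_probability(
    classifier: TrainedDetector,
    stack: FeatureStack,
    membrane_prob: np.ndarray,
    config: DetectorConfig,
) -> np.ndarray:
    """Per-voxel synapse probability, restricted to membrane voxels.

    Voxels with ``membrane_prob < membrane_mask_threshold`` are forced to
    probability 0; this search restriction is what makes the detector fast
    and precise on large volumes.  Elsewhere the value is the forest's vote
    fraction for the synapse class.
    """
    if stack.channels.shape[0] != classifier.forest.n_features_in_:
        raise ValueError(
            f"stack has {stack.channels.shape[0]} channels; classifier was trained "
            f"on {classifier.forest.n_features_in_}"
        )
    mp = np.asarray(membrane_prob)
    if mp.shape != stack.shape:
        raise ValueError(f"membrane shape {mp.shape} != stack shape {stack.shape}")
    mask = mp >= config.membrane_mask_threshold
    prob = np.zeros(stack.shape, dtype=np.float64)
    if mask.any():
        X = stack.as_table(mask)
        p = classifier.forest.predict_proba(X)
        pos_col = int(np.flatnonzero(classifier.forest.classes_ == True)[0])  # noqa: E712
        prob[mask] = p[:, pos_col]
    return prob


def threshold_and_group(prob: np.ndarray, config: DetectorConfig) -> list[SynapseAnnotation]:
    """Group thresholded probabilities into synapse objects.

    Binarize at ``prob_threshold``, take 26-connected 3D components, drop
    components smaller than ``min_3d_voxels`` or whose largest single-slice
    footprint exceeds ``max_2d_pixels``, and return the survivors with
    confidence equal to the component's mean probability.
    """
    prob = np.asarray(prob)
    binary = prob >= config.prob_threshold
    struct = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    comp, n = ndi.label(binary, structure=struct)
    out: list[SynapseAnnotation] = []
    next_id = 1
    for lab in range(1, n + 1):
        vox = np.argwhere(comp == lab)
        if vox.shape[0] < config.min_3d_voxels:
            continue
        slice_counts = np.bincount(vox[:, 0])
        if slice_counts.max() > config.max_2d_pixels:
            continue
        conf = float(prob[vox[:, 0], vox[:, 1], vox[:, 2]].mean())
        out.append(
            SynapseAnnotation(id=next_id, voxels=vox, confidence=min(conf, 1.0))
        )
        next_id += 1
    return out


@dataclass
class DetectionScore:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


def _greedy_match(
    a_list: list[SynapseAnnotation], b_list: list[SynapseAnnotation]
) -> list[tuple[int, int, int]]:
    """One-to-one greedy matching by descending voxel overlap.

    Ties break by (smaller first-list id, smaller second-list id).  Returns
    ``(a_id, b_id, overlap)`` triples.  Any positive overlap qualifies.
    """
    a_sets = {s.id: s.voxel_set() for s in a_list}
    b_sets = {s.id: s.voxel_set() for s in b_list}
    cands = []
    for aid, av in sorted(a_sets.items()):
        for bid, bv in sorted(b_sets.items()):
            ov = len(av & bv)
            if ov > 0:
                cands.append((-ov, aid, bid))
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for neg_ov, aid, bid in cands:
        if aid in used_a or bid in used_b:
            continue
        used_a.add(aid)
        used_b.add(bid)
        pairs.append((aid, bid, -neg_ov))
    return pairs


def score_detections(
    detected: list[SynapseAnnotation], truth: list[SynapseAnnotation]
) -> DetectionScore:
    """Object-level detection score under one-to-one matching.

    A detection may count for at most one true synapse and vice versa; this
    forbids a single blanket detection from claiming every truth object.
    """
    pairs = _greedy_match(truth, detected)
    tp = len(pairs)
    fp = len(detected) - tp
    fn = len(truth) - tp
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall)
        else 0.0
    )
    return DetectionScore(tp, fp, fn, precision, recall, f1)
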