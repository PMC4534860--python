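"""Seeded synthetic EM-like scenes for end-to-end pipeline testing.

Generates a densely labeled neuron volume (Voronoi-style regions separated by
membrane sheets), synapse objects straddling neuron-pair boundaries, vesicle
blob clusters on the presynaptic side, an EM-like grayscale rendering with
noise, and a membrane probability map.  Controlled corruption operators
reproduce the error modes that matter for graph estimation: neuron splits at
thin processes (spine-neck fragmentation), neuron merges, and synapse false
positives / negatives.

All randomness flows through one :func:`numpy.random.default_rng` generator
per call, seeded from the parameter objects; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .core_model import LabelVolume, SynapseAnnotation

__all__ = [
    "SceneParams",
    "CorruptionParams",
    "Scene",
    "generate_scene",
    "corrupt_segmentation",
    "corrupt_synapses",
    "split_neuron",
    "spine_demo_scene",
    "adjacent_label_pairs",
]


@dataclass
class SceneParams:
    """Parameters of a synthetic scene.

    Defaults produce a small, low-noise cortex-like volume: a handful of
    neuron regions separated by 2-voxel membrane sheets, compact synapses on
    shared boundaries, and vesicle clusters whose diameter (~2 px radius)
    roughly matches small neurotransmitter vesicles at a few nm/px.
    """

    shape: tuple[int, int, int] = (12, 96, 96)
    n_neurons: int = 8
    n_synapses: int = 6
    membrane_width: float = 2.0
    vesicle_density: int = 6  # vesicle blobs rendered per synapse
    noise_sigma: float = 0.02
    seed: int = 0
    # geometry knobs with documented defaults
    synapse_radius: tuple[int, int, int] = (1, 3, 3)  # ellipsoid semi-axes (z,y,x)
    vesicle_radius: int = 2  # in-plane disc radius, voxels
    cluster_radius: int = 5  # vesicle cluster spread around the synapse
    spine_rate: float = 0.5  # fraction of neurons given a thin spine-neck process

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape):
            raise ValueError(f"all extents must be positive; got {self.shape}")
        if self.n_synapses >= 1 and self.n_neurons < 2:
            raise ValueError("need at least 2 neurons to place a synapse")


@dataclass
class CorruptionParams:
    """Controlled degradation of a ground-truth scene.

    ``split_rate`` fragments that fraction of neurons at their thinnest
    cross-section (the spine-neck failure mode); ``merge_rate`` fuses that
    fraction of adjacent neuron pairs; ``syn_fn_rate`` deletes true synapses
    independently; ``syn_fp_count`` adds spurious blobs on membranes;
    ``jitter`` displaces surviving synapse masks.
    """

    split_rate: float = 0.0
    merge_rate: float = 0.0
    syn_fn_rate: float = 0.0
    syn_fp_count: int = 0
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("split_rate", "merge_rate", "syn_fn_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]; got {v}")
        if self.syn_fp_count < 0:
            raise ValueError("syn_fp_count must be non-negative")


@dataclass
class Scene:
    """Everything :func:`generate_scene` knows about a synthetic volume."""

    truth_labels: LabelVolume
    synapses: list[SynapseAnnotation]
    image: np.ndarray
    membrane_prob: np.ndarray
    pixel_truth: np.ndarray
    vesicle_centers: np.ndarray  # (M, 3) planted vesicle centers, for tests
    params: SceneParams


def _ellipsoid_offsets(radii: tuple[int, int, int]) -> np.ndarray:
    rz, ry, rx = radii
    zz, yy, xx = np.mgrid[-rz : rz + 1, -ry : ry + 1, -rx : rx + 1]
    inside = (
        (zz / max(rz, 1e-9)) ** 2
        + (yy / max(ry, 1e-9)) ** 2
        + (xx / max(rx, 1e-9)) ** 2
    ) <= 1.0
    return np.stack([zz[inside], yy[inside], xx[inside]], axis=1)


def adjacent_label_pairs(labels: np.ndarray) -> dict[tuple[int, int], np.ndarray]:
    """Find neuron pairs separated only by background, with boundary sites.

    For every background voxel the nearest non-zero label is computed by a
    Euclidean distance transform; wherever two 6-neighboring background voxels
    disagree on their nearest label, the two labels form an adjacent pair.
    Returns ``{(a, b): (K, 3) boundary voxel coordinates}`` with ``a < b``.
    """
    bg = labels == 0
    if not bg.any() or (labels != 0).sum() == 0:
        return {}
    _, (iz, iy, ix) = ndi.distance_transform_edt(bg, return_indices=True)
    nearest = labels[iz, iy, ix]
    sites: dict[tuple[int, int], list] = {}

    def record(mask: np.ndarray, a: np.ndarray, b: np.ndarray) -> None:
        for z, y, x in np.argwhere(mask):
            pair = (int(a[z, y, x]), int(b[z, y, x]))
            sites.setdefault((min(pair), max(pair)), []).append((z, y, x))

    for axis in range(3):
        # wide membranes: neighboring background voxels with different
        # nearest regions sit on the Voronoi boundary between them
        a = nearest
        b = np.roll(nearest, -1, axis=axis)
        both_bg = bg & np.roll(bg, -1, axis=axis)
        sl = [slice(None)] * 3
        sl[axis] = slice(0, labels.shape[axis] - 1)  # drop the wrap-around face
        valid = np.zeros_like(both_bg)
        valid[tuple(sl)] = True
        record(both_bg & valid & (a != b), a, b)

        # 1-voxel membranes: a background voxel directly between two
        # different foreground labels
        prev = np.roll(labels, 1, axis=axis)
        nxt = np.roll(labels, -1, axis=axis)
        interior = np.zeros_like(bg)
        sl = [slice(None)] * 3
        sl[axis] = slice(1, labels.shape[axis] - 1)
        interior[tuple(sl)] = True
        record(bg & interior & (prev > 0) & (nxt > 0) & (prev != nxt), prev, nxt)

    dedup = {
        k: np.unique(np.asarray(v, dtype=np.int64), axis=0)
        for k, v in sorted(sites.items())
    }
    return dedup


def _grow_spine(labels: np.ndarray, owner: int, start: np.ndarray,
                direction: np.ndarray, rng: np.random.Generator) -> None:
    """Carve a thin neck plus a small head of ``owner``'s label from ``start``.

    The neck is 1 voxel thick in-plane, which makes it the thinnest
    cross-section of the neuron — the natural target for the split operator.
    """
    shape = labels.shape
    d = direction.astype(float)
    n = np.linalg.norm(d[1:])
    if n < 1e-9:
        return
    d[0] = 0.0
    d /= np.linalg.norm(d)
    length = int(rng.integers(4, 8))
    pos = start.astype(float)
    for step in range(length):
        pos = pos + d
        p = np.round(pos).astype(int)
        if not all(0 <= p[i] < shape[i] for i in range(3)):
            return
        labels[p[0], p[1], p[2]] = owner
    # spine head: a small ball at the tip
    for off in _ellipsoid_offsets((1, 2, 2)):
        q = np.round(pos).astype(int) + off
        if all(0 <= q[i] < shape[i] for i in range(3)):
            labels[q[0], q[1], q[2]] = owner


def generate_scene(params: SceneParams) -> Scene:
    """Render a complete synthetic scene from seeded parameters.

    Neurons tile the volume as Voronoi regions around random seed points,
    separated by membrane sheets of label 0.  Each synapse is an ellipsoidal
    voxel set centered on a two-neuron boundary, overlapping both partner
    regions; its true partners are recorded on the annotation.  Vesicle discs
    are rendered on one (presynaptic) side of each synapse.
    """
    shape = params.shape
    n_vox = int(np.prod(shape))
    if params.n_neurons > n_vox // 27:
        raise ValueError(
            f"cannot pack {params.n_neurons} neurons into shape {shape}"
        )
    rng = np.random.default_rng(params.seed)

    # --- Voronoi neuron regions with a membrane gap -------------------------
    seeds = np.stack(
        [rng.integers(0, s, size=params.n_neurons) for s in shape], axis=1
    ).astype(float)
    grid = np.stack(np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]], axis=-1)
    # distances to every seed; scenes are small enough to hold this densely
    d = np.linalg.norm(grid[None] - seeds[:, None, None, None, :], axis=-1)
    order = np.argsort(d, axis=0)
    d_sorted = np.take_along_axis(d, order, axis=0)
    labels = (order[0] + 1).astype(np.int32)
    if params.n_neurons > 1:
        membrane = (d_sorted[1] - d_sorted[0]) <= params.membrane_width
        labels[membrane] = 0

    # thin spine-neck processes so the split operator has realistic targets
    n_spines = int(round(params.spine_rate * params.n_neurons))
    if n_spines and params.n_neurons > 1:
        spined = rng.choice(
            np.arange(1, params.n_neurons + 1), size=n_spines, replace=False
        )
        for lab in spined:
            own = np.argwhere(labels == lab)
            if own.shape[0] < 10:
                continue
            start = own[rng.integers(own.shape[0])]
            direction = rng.normal(size=3)
            _grow_spine(labels, int(lab), start, direction, rng)

    # --- synapses on neuron-pair boundaries ---------------------------------
    pair_sites = adjacent_label_pairs(labels)
    synapses: list[SynapseAnnotation] = []
    pixel_truth = np.zeros(shape, dtype=np.uint8)
    vesicle_centers: list[tuple[int, int, int]] = []
    offsets = _ellipsoid_offsets(params.synapse_radius)
    if params.n_synapses > 0:
        if not pair_sites:
            raise ValueError("no adjacent neuron pairs available for synapses")
        pair_list = list(pair_sites)
        for sid in range(1, params.n_synapses + 1):
            placed = False
            for _attempt in range(50):
                pair = pair_list[rng.integers(len(pair_list))]
                sites = pair_sites[pair]
                center = sites[rng.integers(sites.shape[0])]
                cand = center[None, :] + offsets
                inb = np.all((cand >= 0) & (cand < np.asarray(shape)), axis=1)
                cand = cand[inb]
                lab_at = labels[cand[:, 0], cand[:, 1], cand[:, 2]]
                keep = (lab_at == 0) | (lab_at == pair[0]) | (lab_at == pair[1])
                cand = cand[keep]
                lab_at = lab_at[keep]
                if (
                    (lab_at == pair[0]).any()
                    and (lab_at == pair[1]).any()
                    and not pixel_truth[cand[:, 0], cand[:, 1], cand[:, 2]].any()
                ):
                    pixel_truth[cand[:, 0], cand[:, 1], cand[:, 2]] = 1
                    synapses.append(
                        SynapseAnnotation(
                            id=sid, voxels=cand, confidence=1.0, partners=pair
                        )
                    )
                    # vesicle cluster on the first partner's side; centers are
                    # kept apart so individual discs stay template-like
                    side = np.argwhere(labels == pair[0])
                    near = side[
                        np.linalg.norm(side - center, axis=1) <= params.cluster_radius
                    ]
                    placed_centers: list[np.ndarray] = []
                    attempts = 0
                    while (
                        near.shape[0]
                        and len(placed_centers) < params.vesicle_density
                        and attempts < 20 * params.vesicle_density
                    ):
                        attempts += 1
                        c = near[rng.integers(near.shape[0])]
                        if all(
                            np.linalg.norm(c - q) >= 2 * params.vesicle_radius + 1
                            for q in placed_centers
                        ):
                            placed_centers.append(c)
                    vesicle_centers.extend(
                        tuple(c.tolist()) for c in placed_centers
                    )
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"could not place synapse {sid}; volume too crowded"
                )

    # --- grayscale rendering ------------------------------------------------
    image = np.full(shape, 0.75, dtype=np.float64)
    image[labels == 0] = 0.15
    disc = _ellipsoid_offsets((0, params.vesicle_radius, params.vesicle_radius))
    for c in vesicle_centers:
        pts = np.asarray(c)[None, :] + disc
        inb = np.all((pts >= 0) & (pts < np.asarray(shape)), axis=1)
        pts = pts[inb]
        image[pts[:, 0], pts[:, 1], pts[:, 2]] = 0.30
    # the cleft renders slightly darker than plain membrane (postsynaptic
    # density); with default noise that is not separable voxel-wise, so the
    # detector must combine local texture with nearby vesicle evidence
    image[pixel_truth.astype(bool)] = 0.10
    image = np.clip(image + rng.normal(0.0, params.noise_sigma, size=shape), 0.0, 1.0)

    # --- membrane probability map -------------------------------------------
    # synaptic clefts are membrane as far as a membrane detector is concerned,
    # so the probability map is high on membrane sheets and on synapse voxels
    membrane_prob = ndi.gaussian_filter(
        ((labels == 0) | pixel_truth.astype(bool)).astype(np.float64),
        sigma=(0.0, 1.0, 1.0),
    )
    mx = membrane_prob.max()
    if mx > 0:
        membrane_prob = np.clip(membrane_prob / mx, 0.0, 1.0)

    return Scene(
        truth_labels=LabelVolume(labels),
        synapses=synapses,
        image=image,
        membrane_prob=membrane_prob,
        pixel_truth=pixel_truth,
        vesicle_centers=np.asarray(sorted(set(vesicle_centers)), dtype=np.int64).reshape(-1, 3),
        params=params,
    )


def _split_at_thinnest(data: np.ndarray, lab: int, new_label: int) -> bool:
    """Cut one region in two at its thinnest cross-section along its
    principal axis.  Returns False when the region is too small to split."""
    coords = np.argwhere(data == lab).astype(float)
    if coords.shape[0] < 4:
        return False
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / coords.shape[0]
    w, v = np.linalg.eigh(cov)
    axis = v[:, np.argmax(w)]
    t = centered @ axis
    lo, hi = t.min(), t.max()
    if hi - lo < 2.0:
        return False
    # candidate cut planes strictly inside the region (central 20-80% band)
    edges = np.linspace(lo, hi, max(8, int(hi - lo) + 1))
    counts, _ = np.histogram(t, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    k0 = max(1, int(0.2 * len(counts)))
    k1 = min(len(counts) - 1, int(0.8 * len(counts)) + 1)
    band = slice(k0, k1)
    if counts[band].size == 0:
        return False
    k = k0 + int(np.argmin(counts[band]))
    thr = centers[k]
    upper = t > thr
    if not upper.any() or upper.all():
        return False
    sel = coords[upper].astype(int)
    data[sel[:, 0], sel[:, 1], sel[:, 2]] = new_label
    return True


def split_neuron(vol: LabelVolume, label: int) -> LabelVolume:
    """Split one chosen neuron at its thinnest cross-section.

    The cut plane is placed where the voxel count per unit length along the
    region's principal axis is smallest — on a neuron with a dendritic-spine
    neck this severs the neck, detaching the spine head (and any synapse on
    it) from the parent shaft while moving only a handful of voxels.  Raises
    when the region is too small to split.
    """
    out = vol.data.copy()
    if not _split_at_thinnest(out, int(label), int(out.max()) + 1):
        raise ValueError(f"label {label} is too small or too round to split")
    return LabelVolume(out, tuple(vol.resolution), tuple(vol.offset))


def corrupt_segmentation(truth: LabelVolume, params: CorruptionParams) -> LabelVolume:
    """Apply seeded split and merge errors to a ground-truth segmentation.

    Splits come first: a ``split_rate`` fraction of neurons is cut at the
    thinnest cross-section along the principal axis (mimicking spine-neck
    fragmentation), the far part receiving a fresh label.  Then a
    ``merge_rate`` fraction of adjacent label pairs is fused onto the smaller
    id.  The set of foreground voxels is conserved exactly; labels of
    untouched neurons are preserved.
    """
    rng = np.random.default_rng(params.seed)
    out = truth.data.copy()
    labs = np.unique(out)
    labs = labs[labs != 0]

    n_split = int(round(params.split_rate * labs.size))
    if n_split:
        chosen = rng.choice(labs, size=min(n_split, labs.size), replace=False)
        next_label = int(out.max()) + 1
        for lab in sorted(int(x) for x in chosen):
            if _split_at_thinnest(out, lab, next_label):
                next_label += 1

    if params.merge_rate > 0:
        pairs = sorted(adjacent_label_pairs(out))
        n_merge = int(round(params.merge_rate * len(pairs)))
        if n_merge:
            idx = rng.choice(len(pairs), size=min(n_merge, len(pairs)), replace=False)
            remap: dict[int, int] = {}

            def resolve(x: int) -> int:
                while x in remap:
                    x = remap[x]
                return x

            for i in sorted(int(j) for j in idx):
                a, b = (resolve(v) for v in pairs[i])
                if a == b:
                    continue
                lo, hi = min(a, b), max(a, b)
                remap[hi] = lo
                out[out == hi] = lo

    return LabelVolume(out, tuple(truth.resolution), tuple(truth.offset))


def spine_demo_scene() -> tuple[LabelVolume, list[SynapseAnnotation]]:
    """Deterministic volume demonstrating spine-neck fragmentation.

    Five slab neurons (labels 1, 2, 3, 5, 6) separated by 1-voxel membranes.
    Neuron 2 is a dendritic shaft with a 1-voxel-thick neck leading to a
    small spine head; synapse 2 sits between the head and neuron 3, so
    :func:`split_neuron` applied to neuron 2 cuts the neck, moving only a
    few dozen voxels (negligible segmentation error) while disconnecting the
    spine-head synapse from the shaft (large graph error).  Neurons 5 and 6
    carry no synapses.
    """
    z, y, x = 4, 40, 22
    lab = np.zeros((z, y, x), dtype=np.int32)
    lab[:, :, 0:3] = 1  # neuron A
    lab[:, :, 4:7] = 2  # neuron B shaft spans all y initially
    lab[:, 30:, 4:7] = 0  # ...but only up to y=30
    lab[1, 30:34, 5] = 2  # thin neck
    lab[1:3, 34:39, 4:7] = 2  # spine head
    lab[:, :, 8:12] = 3  # neuron C
    lab[:, :, 13:17] = 5  # neuron D (no synapses)
    lab[:, :, 18:22] = 6  # neuron E (no synapses)

    def blob(zr, yr, xr):
        return [
            (zi, yi, xi)
            for zi in range(*zr)
            for yi in range(*yr)
            for xi in range(*xr)
        ]

    synapses = [
        SynapseAnnotation(1, np.asarray(blob((1, 3), (9, 12), (2, 5)))),  # A|B shaft
        SynapseAnnotation(2, np.asarray(blob((1, 3), (35, 38), (5, 9)))),  # head|C
        SynapseAnnotation(3, np.asarray(blob((1, 3), (19, 22), (2, 5)))),  # A|B shaft
        SynapseAnnotation(4, np.asarray(blob((1, 3), (15, 18), (11, 14)))),  # C|D
        SynapseAnnotation(5, np.asarray(blob((1, 3), (25, 28), (2, 5)))),  # A|B shaft
    ]
    return LabelVolume(lab), synapses


def corrupt_synapses(
    synapses: list[SynapseAnnotation],
    labels: LabelVolume,
    params: CorruptionParams,
) -> list[SynapseAnnotation]:
    """Delete, jitter, and add spurious synapses.

    Every true synapse survives independently with probability
    ``1 - syn_fn_rate``; survivors are displaced by a rounded Gaussian offset
    of scale ``jitter`` (clipped to the volume); ``syn_fp_count`` spurious
    ellipsoidal blobs are dropped at random membrane locations.  Output
    partners are unset — association is the graph builder's job.
    """
    rng = np.random.default_rng(params.seed)
    shape = np.asarray(labels.shape)
    out: list[SynapseAnnotation] = []
    keep = rng.random(len(synapses)) >= params.syn_fn_rate
    next_id = 1
    for syn, k in zip(synapses, keep):
        if not k:
            continue
        vox = syn.voxels.copy()
        if params.jitter > 0:
            shift = np.round(rng.normal(0.0, params.jitter, size=3)).astype(int)
            vox = np.clip(vox + shift, 0, shape - 1)
        out.append(
            SynapseAnnotation(
                id=next_id, voxels=vox, confidence=syn.confidence, partners=None
            )
        )
        next_id += 1
    if params.syn_fp_count:
        bg = np.argwhere(labels.data == 0)
        offsets = _ellipsoid_offsets((1, 2, 2))
        for _ in range(params.syn_fp_count):
            center = bg[rng.integers(bg.shape[0])]
            cand = center[None, :] + offsets
            inb = np.all((cand >= 0) & (cand < shape), axis=1)
            out.append(
                SynapseAnnotation(
                    id=next_id,
                    voxels=cand[inb],
                    confidence=float(rng.uniform(0.5, 1.0)),
                    partners=None,
                )
            )
            next_id += 1
    return out
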