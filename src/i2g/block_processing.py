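"""Block-wise volume processing: dicing, per-cuboid processing, seam merging.

Large volumes are diced into *cuboids*: disjoint inscribed regions that tile
the volume, each extended by padding into an overlapped region so that
per-block computation sees enough context.  Blocks are processed
independently, their outputs cropped to the inscribed regions and offset into
disjoint global label ranges.  Objects cut by block boundaries are then
reconciled by serially walking the seams: for every pair of touching objects
across a seam face, a similarity (Jaccard by default) is computed within the
shared padded context, and pairs above threshold are relabeled to one id
immediately — later seams see already-merged ids, so no global transitive
closure pass is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .core_model import LabelVolume

__all__ = [
    "CuboidSpec",
    "SeamMergeConfig",
    "BlockResult",
    "dice_volume",
    "process_blocks",
    "merge_seams",
    "canonical_relabel",
]

Range3 = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class CuboidSpec:
    """One processing block: a disjoint inscribed region inside a padded one.

    Both are half-open ``((z0, z1), (y0, y1), (x0, x1))`` ranges in global
    coordinates; ``padded`` extends ``inscribed`` by the dicing padding,
    clipped to the volume bounds.
    """

    inscribed: Range3
    padded: Range3

    def __post_init__(self) -> None:
        for (i0, i1), (p0, p1) in zip(self.inscribed, self.padded):
            if not (p0 <= i0 < i1 <= p1):
                raise ValueError(
                    f"inscribed {self.inscribed} not contained in padded {self.padded}"
                )

    def slices(self, which: str = "inscribed") -> tuple[slice, slice, slice]:
        r = self.inscribed if which == "inscribed" else self.padded
        return tuple(slice(a, b) for a, b in r)  # type: ignore[return-value]


@dataclass
class SeamMergeConfig:
    """How object pairs across a seam are compared and merged."""

    similarity: str = "jaccard"
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.similarity not in ("jaccard", "overlap_fraction"):
            raise ValueError(f"unknown similarity {self.similarity!r}")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must lie in [0, 1]")


def dice_volume(
    shape: Sequence[int],
    block_size: Sequence[int],
    padding: Sequence[int] | int,
) -> list[CuboidSpec]:
    """Dice a volume into cuboids in row-major (z, y, x) order.

    Inscribed regions tile the volume exactly (the last block per axis may be
    smaller); padded regions extend each inscribed region by ``padding`` on
    every side, clipped to the volume.  A ``block_size`` exceeding the shape
    yields a single block.
    """
    shape = tuple(int(s) for s in shape)
    block = tuple(int(b) for b in block_size)
    if isinstance(padding, int):
        pad = (padding,) * 3
    else:
        pad = tuple(int(p) for p in padding)
    if any(b <= 0 for b in block):
        raise ValueError(f"block_size must be positive per axis; got {block}")
    if any(p < 0 for p in pad):
        raise ValueError(f"padding must be non-negative; got {pad}")

    starts = [list(range(0, s, b)) for s, b in zip(shape, block)]
    specs = []
    for z0 in starts[0]:
        for y0 in starts[1]:
            for x0 in starts[2]:
                ins = tuple(
                    (o, min(o + b, s))
                    for o, b, s in zip((z0, y0, x0), block, shape)
                )
                padded = tuple(
                    (max(0, a - p), min(s, b + p))
                    for (a, b), p, s in zip(ins, pad, shape)
                )
                specs.append(CuboidSpec(inscribed=ins, padded=padded))
    return specs


@dataclass
class BlockResult:
    """Output of one processed block, with globally offset labels.

    ``inscribed`` is the crop that gets assembled into the stitched volume;
    ``padded`` keeps the full overlapped-context labeling that seam merging
    compares across block boundaries.
    """

    spec: CuboidSpec
    inscribed: np.ndarray
    padded: np.ndarray


def process_blocks(
    fn: Callable[[np.ndarray], np.ndarray],
    volume: np.ndarray | LabelVolume,
    specs: list[CuboidSpec],
) -> list[BlockResult]:
    """Run a pure per-cuboid labeling function over every padded block.

    ``fn`` maps a padded subvolume to an integer label array of the same
    shape (0 = background) and must not carry state across blocks.  Each
    block's non-zero labels are offset by ``block_index * stride`` with one
    stride above every per-block maximum, so global id ranges are disjoint.
    """
    data = volume.data if isinstance(volume, LabelVolume) else np.asarray(volume)
    raw: list[np.ndarray] = []
    for bi, spec in enumerate(specs):
        try:
            out = np.asarray(fn(data[spec.slices("padded")]))
        except Exception as exc:  # noqa: BLE001 - reraise with block context
            raise RuntimeError(f"processing failed on block {bi} ({spec.inscribed})") from exc
        if out.shape != data[spec.slices("padded")].shape:
            raise RuntimeError(
                f"block {bi}: fn returned shape {out.shape}, expected padded shape"
            )
        raw.append(out.astype(np.int64))
    stride = int(max((r.max() for r in raw), default=0)) + 1
    results = []
    for bi, (spec, out) in enumerate(zip(specs, raw)):
        shifted = np.where(out > 0, out + bi * stride, 0)
        ins = tuple(
            slice(i0 - p0, i1 - p0)
            for (i0, i1), (p0, _) in zip(spec.inscribed, spec.padded)
        )
        results.append(
            BlockResult(spec=spec, inscribed=shifted[ins], padded=shifted)
        )
    return results


def _similarity(inter: int, na: int, nb: int, config: SeamMergeConfig) -> float:
    if config.similarity == "jaccard":
        union = na + nb - inter
        return inter / union if union else 0.0
    return inter / min(na, nb) if min(na, nb) else 0.0


def _box_intersection(a: Range3, b: Range3) -> Range3 | None:
    out = []
    for (a0, a1), (b0, b1) in zip(a, b):
        lo, hi = max(a0, b0), min(a1, b1)
        if lo >= hi:
            return None
        out.append((lo, hi))
    return tuple(out)  # type: ignore[return-value]


def merge_seams(
    blocks: list[BlockResult],
    specs: list[CuboidSpec],
    config: SeamMergeConfig | None = None,
) -> LabelVolume:
    """Stitch processed blocks into one volume with globally consistent ids.

    Seam faces (pairs of blocks whose inscribed regions abut along an axis)
    are visited in a fixed serial order.  For each pair of objects that
    co-occupy voxels of the shared padded slab, the configured similarity is
    computed over the two objects' voxels within that slab; pairs at or above
    threshold are merged onto the smaller id immediately, so later seams
    operate on already-merged labels.
    """
    config = config or SeamMergeConfig()
    if len(blocks) != len(specs) or any(
        b.spec != s for b, s in zip(blocks, specs)
    ):
        raise ValueError("blocks and specs are inconsistent")

    shape = tuple(max(s.inscribed[ax][1] for s in specs) for ax in range(3))
    covered = np.zeros(shape, dtype=bool)
    out = np.zeros(shape, dtype=np.int64)
    for b in blocks:
        sl = b.spec.slices("inscribed")
        out[sl] = b.inscribed
        covered[sl] = True
    if not covered.all():
        raise ValueError("blocks do not cover the volume")

    remap: dict[int, int] = {}

    def resolve(x: int) -> int:
        while x in remap:
            x = remap[x]
        return x

    # serial seam order: axis-major, then block order
    faces = []
    for axis in range(3):
        for ia, a in enumerate(specs):
            for ib, b in enumerate(specs):
                if ib == ia:
                    continue
                if b.inscribed[axis][0] != a.inscribed[axis][1]:
                    continue
                other = [ax for ax in range(3) if ax != axis]
                if all(
                    a.inscribed[ax][0] < b.inscribed[ax][1]
                    and b.inscribed[ax][0] < a.inscribed[ax][1]
                    for ax in other
                ):
                    faces.append((axis, ia, ib))
    faces.sort()

    for axis, ia, ib in faces:
        a, b = blocks[ia], blocks[ib]
        slab = _box_intersection(a.spec.padded, b.spec.padded)
        if slab is None:
            continue

        def crop(blk: BlockResult) -> np.ndarray:
            sl = tuple(
                slice(lo - p0, hi - p0)
                for (lo, hi), (p0, _) in zip(slab, blk.spec.padded)
            )
            return blk.padded[sl]

        la, lb = crop(a), crop(b)
        both = (la > 0) & (lb > 0)
        if not both.any():
            continue
        pairs, counts = np.unique(
            np.stack([la[both], lb[both]]), axis=1, return_counts=True
        )
        sizes_a = dict(zip(*np.unique(la[la > 0], return_counts=True)))
        sizes_b = dict(zip(*np.unique(lb[lb > 0], return_counts=True)))
        for (ida, idb), inter in sorted(
            zip(map(tuple, pairs.T.tolist()), counts.tolist())
        ):
            sim = _similarity(int(inter), int(sizes_a[ida]), int(sizes_b[idb]), config)
            if sim >= config.threshold:
                ra, rb = resolve(int(ida)), resolve(int(idb))
                if ra != rb:
                    lo, hi = min(ra, rb), max(ra, rb)
                    remap[hi] = lo

    if remap:
        ids = np.unique(out)
        lut = {int(i): resolve(int(i)) for i in ids}
        flat = np.vectorize(lambda v: lut[v] if v else 0, otypes=[np.int64])
        out = flat(out)
    return LabelVolume(out)


def canonical_relabel(vol: LabelVolume) -> LabelVolume:
    """Relabel objects 1..k by first occurrence in C-order scan.

    Two segmentations induce the same voxel partition iff their canonical
    relabelings are identical arrays — used to compare monolithic against
    diced-and-merged processing.
    """
    data = vol.data
    flat = data.reshape(-1)
    out = np.zeros_like(flat)
    mapping: dict[int, int] = {}
    nxt = 1
    nz = np.flatnonzero(flat)
    for i in nz:
        v = int(flat[i])
        m = mapping.get(v)
        if m is None:
            m = mapping[v] = nxt
            nxt += 1
        out[i] = m
    return LabelVolume(out.reshape(data.shape), tuple(vol.resolution), tuple(vol.offset))
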