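"""From synapse annotations and a segmentation to neuron and line graphs.

Each synapse is associated with the neuron labels its (optionally dilated)
voxel mask overlaps most frequently; the two strongest labels become the
synapse's partners.  Neurons become nodes, synapses become edges (a
multigraph — parallel synapses between the same pair are distinct edges).
The line graph is the dual: synapses are nodes, linked whenever they are
coincident on a common neuron.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .core_model import LabelVolume, LineGraph, NeuronGraph, SynapseAnnotation

__all__ = [
    "SynapsePartners",
    "AssociationResult",
    "associate_synapses",
    "build_neuron_graph",
    "build_line_graph",
]


@dataclass
class SynapsePartners:
    """Association of one synapse with neuron labels."""

    partners: tuple[int, ...]  # 1 or 2 non-zero labels, strongest first pair
    overlaps: dict[int, int]  # non-zero label -> overlapping voxel count
    dangling: bool

    @property
    def partner_set(self) -> frozenset[int]:
        return frozenset(self.partners)


AssociationResult = dict[int, SynapsePartners]


def _dilated_mask_coords(
    syn: SynapseAnnotation, shape: tuple[int, ...], radius: int
) -> np.ndarray:
    """Voxel coordinates of the synapse mask dilated by a Euclidean ball."""
    vox = syn.voxels
    if radius <= 0:
        return vox
    lo = np.maximum(vox.min(axis=0) - radius, 0)
    hi = np.minimum(vox.max(axis=0) + radius + 1, np.asarray(shape))
    local = np.zeros(tuple(hi - lo), dtype=bool)
    rel = vox - lo
    local[rel[:, 0], rel[:, 1], rel[:, 2]] = True
    r = radius
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    ball = zz**2 + yy**2 + xx**2 <= r**2
    local = ndi.binary_dilation(local, structure=ball)
    return np.argwhere(local) + lo


def associate_synapses(
    synapses: list[SynapseAnnotation],
    labels: LabelVolume,
    dilation_radius: int = 1,
) -> AssociationResult:
    """Find the neuron labels overlapping each synapse most frequently.

    The synapse mask (dilated by ``dilation_radius`` so masks lying in the
    membrane gap reach both neighboring neurons; 0 disables) is intersected
    with the segmentation; non-zero labels are ranked by overlap count, ties
    broken toward the smaller label id.  The top two labels become the
    partners; a single overlapping label marks the synapse *dangling*.
    Partners are also written back onto each annotation (``partners`` field
    and ``kv["partners"]``), giving the bidirectional linkage between
    synapse and segment metadata.

    Synapses overlapping no neuron at all are recorded with empty partners
    and ``dangling=True``.
    """
    data = labels.data
    shape = data.shape
    result: AssociationResult = {}
    for syn in synapses:
        vox = syn.voxels
        if (vox < 0).any() or (vox >= np.asarray(shape)).any():
            raise ValueError(f"synapse {syn.id} has voxels outside the volume")
        coords = _dilated_mask_coords(syn, shape, dilation_radius)
        labs = data[coords[:, 0], coords[:, 1], coords[:, 2]]
        labs = labs[labs != 0]
        counts = np.bincount(labs) if labs.size else np.zeros(1, dtype=int)
        present = np.flatnonzero(counts)
        ranked = sorted(present, key=lambda l: (-counts[l], l))
        partners = tuple(int(l) for l in ranked[:2])
        sp = SynapsePartners(
            partners=partners,
            overlaps={int(l): int(counts[l]) for l in present},
            dangling=len(partners) < 2,
        )
        result[syn.id] = sp
        syn.partners = partners if partners else None
        syn.kv["partners"] = ",".join(str(p) for p in partners)
    return result


def build_neuron_graph(assoc: AssociationResult) -> NeuronGraph:
    """Assemble the neuron multigraph from synapse associations.

    Every partner neuron becomes a node.  Each non-dangling synapse adds one
    undirected edge between its two partners; dangling synapses contribute
    their single neuron as an isolated node (no edge).
    """
    nodes: set[int] = set()
    edges: list[tuple[int, int, int, dict]] = []
    for sid in sorted(assoc):
        sp = assoc[sid]
        nodes.update(sp.partners)
        if not sp.dangling:
            a, b = sp.partners
            edges.append((a, b, sid, {"overlaps": dict(sp.overlaps)}))
    return NeuronGraph(nodes=nodes, edges=edges)


def build_line_graph(assoc: AssociationResult, index: list[int]) -> LineGraph:
    """Construct the line graph over an ordered synapse index.

    ``l[i, j] = 1`` iff ``i != j`` and the partner sets of synapses ``i`` and
    ``j`` intersect; dangling synapses participate through their single
    partner.  Synapse ids in ``index`` that are absent from ``assoc`` get
    all-zero rows, which is what graph augmentation relies on.
    """
    if len(set(index)) != len(index):
        raise ValueError("duplicate synapse ids in line-graph index")
    n = len(index)
    matrix = np.zeros((n, n), dtype=np.uint8)
    partner_sets = [
        assoc[sid].partner_set if sid in assoc else frozenset() for sid in index
    ]
    for i in range(n):
        if not partner_sets[i]:
            continue
        for j in range(i + 1, n):
            if partner_sets[i] & partner_sets[j]:
                matrix[i, j] = matrix[j, i] = 1
    return LineGraph(index=list(index), matrix=matrix)
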