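"""Domain types shared across the images-to-graphs pipeline.

The annotation model follows the RAMON philosophy: a small set of typed
annotations (segments/neurons, synapses) whose metadata is extensible through
user-defined key-value pairs, rather than a closed ontology.

Conventions used throughout the package:

* axis order is ``(z, y, x)`` everywhere, matching slice-stacked EM volumes;
* coordinates are 0-based and ranges half-open;
* label ``0`` is reserved for background / unlabeled voxels (membranes in the
  synthetic scenes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LabelVolume",
    "SynapseAnnotation",
    "NeuronGraph",
    "LineGraph",
    "validate_label_volume",
    "synapse_from_mask",
]


@dataclass
class LabelVolume:
    """A dense 3D segmentation: integer neuron/object ids over a voxel grid.

    Parameters
    ----------
    data
        3D array of non-negative integer labels, axis order ``(z, y, x)``.
        Label 0 is background.
    resolution
        Physical voxel size per axis in nm, ``(z, y, x)``. Informational.
    offset
        Global coordinate of voxel ``(0, 0, 0)``, for volumes cut out of a
        larger dataset.
    """

    data: np.ndarray
    resolution: tuple[float, float, float] = (1.0, 1.0, 1.0)
    offset: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(self.data.shape)

    def labels(self) -> np.ndarray:
        """Sorted array of distinct non-zero labels present in the volume."""
        u = np.unique(self.data)
        return u[u != 0]

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.data.copy(), tuple(self.resolution), tuple(self.offset))


def validate_label_volume(vol: LabelVolume) -> list[str]:
    """Check a :class:`LabelVolume` against its invariants.

    Returns a list of human-readable violation descriptions; an empty list
    means the volume is valid.  Never raises on invalid data.
    """
    violations: list[str] = []
    data = np.asarray(vol.data)
    if data.ndim != 3:
        violations.append(f"data must be 3-dimensional (z,y,x); got ndim={data.ndim}")
    else:
        if any(s <= 0 for s in data.shape):
            violations.append(f"all extents must be positive; got shape={data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        violations.append(f"labels must be integers; got dtype={data.dtype}")
    elif data.size and data.min() < 0:
        violations.append(f"labels must be non-negative; found minimum {data.min()}")
    if len(vol.resolution) != 3:
        violations.append("resolution must have three components (z,y,x)")
    if len(vol.offset) != 3:
        violations.append("offset must have three components (z,y,x)")
    return violations


@dataclass
class SynapseAnnotation:
    """One synapse: a voxel set plus detection confidence and neuron partners.

    ``partners`` is ``None`` until synapse-neuron association has run; after
    association it holds one neuron id (a *dangling* synapse touching a single
    segment) or the two distinct neuron ids the synapse connects.  ``kv``
    carries arbitrary string metadata in the spirit of extensible annotation
    key-value pairs.
    """

    id: int
    voxels: np.ndarray  # (N, 3) int array of (z, y, x) coordinates
    confidence: float = 1.0
    partners: tuple[int, ...] | None = None
    kv: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=np.int64)
        if vox.size == 0:
            raise ValueError(f"empty synapse (id={self.id})")
        vox = vox.reshape(-1, 3)
        # canonical order makes voxel sets comparable and serialization stable
        order = np.lexsort((vox[:, 2], vox[:, 1], vox[:, 0]))
        self.voxels = np.unique(vox[order], axis=0)
        if self.id <= 0:
            raise ValueError(f"synapse id must be a positive integer; got {self.id}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(
                f"confidence must lie in [0, 1]; got {self.confidence} (id={self.id})"
            )
        if self.partners is not None:
            p = tuple(int(x) for x in self.partners)
            if not (1 <= len(p) <= 2) or len(set(p)) != len(p) or any(x <= 0 for x in p):
                raise ValueError(
                    f"partners must be 1 or 2 distinct positive neuron ids; got {p}"
                )
            self.partners = p

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.shape[0])

    @property
    def is_dangling(self) -> bool:
        """True when the synapse does not join two distinct neurons."""
        return self.partners is None or len(self.partners) < 2

    def voxel_set(self) -> set[tuple[int, int, int]]:
        return {tuple(v) for v in self.voxels.tolist()}

    def centroid(self) -> np.ndarray:
        return self.voxels.mean(axis=0)


def synapse_from_mask(
    id: int,
    mask_voxels: Iterable[tuple[int, int, int]] | np.ndarray,
    confidence: float,
) -> SynapseAnnotation:
    """Build a dangling :class:`SynapseAnnotation` from a voxel coordinate set."""
    vox = np.asarray(sorted(tuple(v) for v in mask_voxels), dtype=np.int64)
    if vox.size == 0:
        raise ValueError(f"empty synapse (id={id})")
    return SynapseAnnotation(id=id, voxels=vox, confidence=float(confidence))


@dataclass
class NeuronGraph:
    """Undirected multigraph of neurons (nodes) connected by synapses (edges).

    Parallel edges between a neuron pair are preserved, one per synapse.
    """

    nodes: set[int] = field(default_factory=set)
    edges: list[tuple[int, int, int, dict]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for a, b, sid, _ in self.edges:
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a},{b}) has an endpoint outside nodes")
            if sid in seen:
                raise ValueError(f"synapse id {sid} used by more than one edge")
            seen.add(sid)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        """Export as a :class:`networkx.MultiGraph` with per-edge attributes."""
        import networkx as nx

        g = nx.MultiGraph()
        g.add_nodes_from(sorted(self.nodes))
        for a, b, sid, attrs in self.edges:
            g.add_edge(a, b, key=sid, synapse_id=sid, **attrs)
        return g


class LineGraph:
    """The dual graph: synapses as nodes, linked when coincident on a neuron.

    Stored as a square symmetric binary matrix over an ordered synapse-id
    index.  Entry ``l[i, j] == 1`` means synapses ``index[i]`` and
    ``index[j]`` share a neuron.  Symmetry and a zero diagonal are enforced at
    construction.
    """

    def __init__(self, index: Sequence, matrix: np.ndarray):
        self.index = list(index)
        m = np.asarray(matrix, dtype=np.uint8)
        n = len(self.index)
        if m.shape != (n, n):
            raise ValueError(
                f"matrix shape {m.shape} does not match index length {n}"
            )
        if len(set(self.index)) != n:
            raise ValueError("line-graph index contains duplicate synapse ids")
        if n and not np.array_equal(m, m.T):
            raise ValueError("line-graph matrix must be symmetric")
        if n and np.any(np.diagonal(m) != 0):
            raise ValueError("line-graph matrix must have a zero diagonal")
        self.matrix = m

    def __len__(self) -> int:
        return len(self.index)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LineGraph)
            and self.index == other.index
            and np.array_equal(self.matrix, other.matrix)
        )

    def n_edges(self) -> int:
        """Number of line-graph edges, counted over unordered node pairs."""
        return int(np.triu(self.matrix, k=1).sum())

    def density(self) -> float:
        """Off-diagonal edge density: edges / possible unordered pairs."""
        n = len(self)
        if n < 2:
            return 0.0
        return self.n_edges() / (n * (n - 1) / 2)

    def edge_pairs(self) -> set[tuple]:
        """Set of unordered connected index-label pairs."""
        out = set()
        ii, jj = np.nonzero(np.triu(self.matrix, k=1))
        for i, j in zip(ii.tolist(), jj.tolist()):
            out.add((self.index[i], self.index[j]))
        return out

    @classmethod
    def empty(cls) -> "LineGraph":
        return cls([], np.zeros((0, 0), dtype=np.uint8))
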