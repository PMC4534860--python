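"""Operating-point grid evaluation.

A set of segmentation operating points (candidate label volumes) is crossed
with a set of synapse operating points (candidate annotation sets); for every
combination a graph is estimated, scored against the gold-standard graph
(line-graph F1 and Frobenius error), and tested for significance against the
density-matched permutation null.  Rows of the resulting matrix are ordered
by intermediate synapse-detection F1 and columns by segmentation adjusted
Rand index, so the interaction between subtask quality and graph quality is
visible at a glance — the best graph need not sit at the best-ARI column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .core_model import LabelVolume, SynapseAnnotation
from .graph_builder import associate_synapses, build_line_graph
from .graph_metrics import (
    augment_line_graphs,
    frobenius_error,
    graph_f1,
    match_synapses,
    permutation_pvalue,
)
from .synapse_detector import score_detections

__all__ = [
    "OperatingPoint",
    "ErrorRecord",
    "ErrorMatrix",
    "adjusted_rand",
    "sweep",
    "select_operating_point",
]


@dataclass
class OperatingPoint:
    """One concrete configuration of a pipeline stage and its output payload.

    ``kind`` is ``"segmentation"`` (payload: a :class:`LabelVolume`) or
    ``"synapse"`` (payload: a list of :class:`SynapseAnnotation`).  ``params``
    records provenance — e.g. corruption rates, probability thresholds, or an
    upstream agglomeration threshold — but is never interpreted here: the
    sweep is agnostic to the algorithms that produced the payloads.
    """

    kind: str
    label: str
    params: dict[str, Any] = field(default_factory=dict)
    payload: Any = None

    def __post_init__(self) -> None:
        if self.kind not in ("segmentation", "synapse"):
            raise ValueError(f"unknown operating-point kind {self.kind!r}")


@dataclass
class ErrorRecord:
    """One cell of the evaluation matrix."""

    seg_label: str
    syn_label: str
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    frobenius: float
    p_value: float
    significant: bool

    def to_dict(self) -> dict:
        return {
            "seg_label": self.seg_label,
            "syn_label": self.syn_label,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "frobenius": self.frobenius,
            "p_value": self.p_value,
            "significant": self.significant,
        }


@dataclass
class ErrorMatrix:
    """The full grid: rows = synapse points, cols = segmentation points.

    ``rows``/``cols`` hold operating-point labels in display order (rows by
    descending synapse-detection F1, columns by descending ARI); the ordering
    keys are stored alongside.  ``cells`` maps ``(syn_label, seg_label)`` to
    its :class:`ErrorRecord`.
    """

    rows: list[str]
    cols: list[str]
    cells: dict[tuple[str, str], ErrorRecord]
    row_key: dict[str, float]  # synapse-detection F1 per row
    col_key: dict[str, float]  # segmentation ARI per column
    alpha: float
    B: int
    seed: int

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def record(self, syn_label: str, seg_label: str) -> ErrorRecord:
        return self.cells[(syn_label, seg_label)]

    def to_records(self) -> list[dict]:
        out = []
        for syn_label in self.rows:
            for seg_label in self.cols:
                rec = self.cells[(syn_label, seg_label)].to_dict()
                rec["syn_f1"] = self.row_key[syn_label]
                rec["seg_ari"] = self.col_key[seg_label]
                out.append(rec)
        return out


def adjusted_rand(seg: LabelVolume, truth: LabelVolume) -> float:
    """Adjusted Rand index between two segmentations over foreground voxels.

    Background (label 0) is excluded from both partitions; the index is
    computed on voxels that are foreground in both volumes.  Returns 1.0 for
    two volumes with no common foreground (vacuous agreement).
    """
    if seg.shape != truth.shape:
        raise ValueError(f"shape mismatch: {seg.shape} vs {truth.shape}")
    mask = (seg.data != 0) & (truth.data != 0)
    if not mask.any():
        return 1.0
    return float(adjusted_rand_score(truth.data[mask], seg.data[mask]))


def _cell_seed(base: int, i: int, j: int) -> int:
    # deterministic, distinct per cell, kept under 2**31
    return int((base * 1_000_003 + i * 10_007 + j * 101) % (2**31 - 1))


def sweep(
    seg_points: list[OperatingPoint],
    syn_points: list[OperatingPoint],
    truth_labels: LabelVolume,
    truth_synapses: list[SynapseAnnotation],
    B: int = 1000,
    alpha: float = 0.001,
    seed: int = 0,
    dilation_radius: int = 1,
    statistic: str = "f1_deficit",
) -> ErrorMatrix:
    """Score every (synapse point x segmentation point) graph against truth.

    For each cell the estimated synapses are associated with the candidate
    segmentation, the line graph is built, matched and augmented against the
    gold-standard line graph, and scored (F1, Frobenius, permutation
    p-value).  Cells with ``p >= alpha`` are flagged non-significant.  The
    default ``B`` of 1000 is a desk-scale setting; raise it to 10,000 for a
    full-fidelity significance map.  Deterministic under a fixed ``seed``.
    """
    if not seg_points or not syn_points:
        raise ValueError("need at least one operating point on each axis")

    truth_assoc = associate_synapses(
        [s for s in truth_synapses], truth_labels, dilation_radius
    )
    truth_index = sorted(truth_assoc)
    truth_lg = build_line_graph(truth_assoc, truth_index)

    col_key = {p.label: adjusted_rand(p.payload, truth_labels) for p in seg_points}
    row_key = {
        p.label: score_detections(p.payload, truth_synapses).f1 for p in syn_points
    }

    cells: dict[tuple[str, str], ErrorRecord] = {}
    for i, syn_pt in enumerate(syn_points):
        est_synapses: list[SynapseAnnotation] = syn_pt.payload
        corr = match_synapses(truth_synapses, est_synapses)
        for j, seg_pt in enumerate(seg_points):
            est_assoc = associate_synapses(
                est_synapses, seg_pt.payload, dilation_radius
            )
            est_lg = build_line_graph(est_assoc, sorted(est_assoc))
            ta, ea = augment_line_graphs(truth_lg, est_lg, corr)
            gs = graph_f1(ta, ea)
            frob = frobenius_error(ta, ea)
            p_value, _ = permutation_pvalue(
                ta, ea, B=B, statistic=statistic, seed=_cell_seed(seed, i, j)
            )
            cells[(syn_pt.label, seg_pt.label)] = ErrorRecord(
                seg_label=seg_pt.label,
                syn_label=syn_pt.label,
                tp=gs.tp,
                fp=gs.fp,
                fn=gs.fn,
                precision=gs.precision,
                recall=gs.recall,
                f1=gs.f1,
                frobenius=frob,
                p_value=p_value,
                significant=p_value < alpha,
            )

    rows = sorted(row_key, key=lambda l: (-row_key[l], l))
    cols = sorted(col_key, key=lambda l: (-col_key[l], l))
    return ErrorMatrix(
        rows=rows,
        cols=cols,
        cells=cells,
        row_key=row_key,
        col_key=col_key,
        alpha=alpha,
        B=B,
        seed=seed,
    )


def select_operating_point(
    matrix: ErrorMatrix, criterion: str = "max_f1"
) -> tuple[str, str, ErrorRecord]:
    """Pick the best significant cell of the evaluation matrix.

    ``max_f1`` maximizes graph F1 (the default selection objective);
    ``min_frobenius`` minimizes the Frobenius error.  Ties break by higher
    precision, then lower Frobenius, then first in row-major display order.
    Raises when no cell is significant.
    """
    if criterion not in ("max_f1", "min_frobenius"):
        raise ValueError(f"unknown criterion {criterion!r}")
    best = None
    best_key = None
    pos = 0
    for syn_label in matrix.rows:
        for seg_label in matrix.cols:
            rec = matrix.cells[(syn_label, seg_label)]
            if not rec.significant:
                pos += 1
                continue
            primary = -rec.f1 if criterion == "max_f1" else rec.frobenius
            key = (primary, -rec.precision, rec.frobenius, pos)
            if best_key is None or key < best_key:
                best_key = key
                best = (syn_label, seg_label, rec)
            pos += 1
    if best is None:
        raise ValueError("no significant operating point")
    return best
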