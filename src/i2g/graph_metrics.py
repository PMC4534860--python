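"""Graph-error assessment: correspondence, augmentation, error metrics, and
the permutation significance test.

The estimated and true connectomes are compared through their line graphs.
Synapse correspondence is found by spatial overlap (synapses are small,
compact objects, so this is far easier than matching neuron fragments); both
line graphs are then *augmented* with the synapses absent from the other
until they share one node index of equal size.  Two errors are computed on
the augmented pair: the Frobenius norm of the matrix difference

    G_err = || L{G_true} - L{G_est} ||_F,   ||A||_F = sqrt(sum_ij |a_ij|^2)

and an edge-detection F1: TP edges occur in both graphs, FP only in the test
graph, FN only in the true graph, with

    precision = TP / (TP + FP),  recall = TP / (TP + FN),
    F1 = 2 * precision * recall / (precision + recall).

F1 lies on [0, 1] and is robust to sparsity — true negatives never enter it.
Significance of an observed error is assessed against a density-matched null:
random symmetric graphs with the observed line-graph edge density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import LineGraph, SynapseAnnotation
from .synapse_detector import _greedy_match

__all__ = [
    "Correspondence",
    "GraphScore",
    "GraphErrorReport",
    "NullSummary",
    "match_synapses",
    "augment_line_graphs",
    "frobenius_error",
    "graph_f1",
    "permutation_pvalue",
]


@dataclass
class Correspondence:
    """One-to-one spatial matching between true and estimated synapses."""

    pairs: list[tuple[int, int, int]]  # (true_id, est_id, overlap voxels)
    unmatched_true: list[int]
    unmatched_est: list[int]

    def __post_init__(self) -> None:
        t = [p[0] for p in self.pairs]
        e = [p[1] for p in self.pairs]
        if len(set(t)) != len(t) or len(set(e)) != len(e):
            raise ValueError("correspondence must be one-to-one")


def match_synapses(
    true_synapses: list[SynapseAnnotation],
    est_synapses: list[SynapseAnnotation],
) -> Correspondence:
    """Match synapses across volumes by greedy descending voxel overlap.

    Any positive overlap qualifies a candidate pair; ties break by (smaller
    true id, smaller estimated id).  Unmatched ids on either side are
    reported for augmentation.
    """
    pairs = _greedy_match(true_synapses, est_synapses)
    mt = {p[0] for p in pairs}
    me = {p[1] for p in pairs}
    return Correspondence(
        pairs=pairs,
        unmatched_true=sorted(s.id for s in true_synapses if s.id not in mt),
        unmatched_est=sorted(s.id for s in est_synapses if s.id not in me),
    )


def augment_line_graphs(
    true_lg: LineGraph, est_lg: LineGraph, corr: Correspondence
) -> tuple[LineGraph, LineGraph]:
    """Pad both line graphs onto one shared, equal-sized node index.

    The shared index lists matched synapse pairs first (ordered by true id,
    labeled ``("m", true_id)``), then unmatched true synapses
    (``("t", id)``), then unmatched estimated synapses (``("e", id)``).  Rows
    and columns for synapses absent from a graph are all-zero in that graph,
    so both outputs have corresponding nodes and edges.
    """
    true_pos = {sid: i for i, sid in enumerate(true_lg.index)}
    est_pos = {sid: i for i, sid in enumerate(est_lg.index)}
    for tid, eid, _ in corr.pairs:
        if tid not in true_pos:
            raise ValueError(f"correspondence references unknown true id {tid}")
        if eid not in est_pos:
            raise ValueError(f"correspondence references unknown est id {eid}")
    for tid in corr.unmatched_true:
        if tid not in true_pos:
            raise ValueError(f"correspondence references unknown true id {tid}")
    for eid in corr.unmatched_est:
        if eid not in est_pos:
            raise ValueError(f"correspondence references unknown est id {eid}")

    pairs = sorted(corr.pairs, key=lambda p: p[0])
    shared: list[tuple] = [("m", tid) for tid, _, _ in pairs]
    shared += [("t", tid) for tid in sorted(corr.unmatched_true)]
    shared += [("e", eid) for eid in sorted(corr.unmatched_est)]
    n = len(shared)

    # source position of each shared node in either original graph (or None)
    est_of_true = {tid: eid for tid, eid, _ in pairs}
    src_true: list[int | None] = []
    src_est: list[int | None] = []
    for kind, sid in shared:
        if kind == "m":
            src_true.append(true_pos[sid])
            src_est.append(est_pos[est_of_true[sid]])
        elif kind == "t":
            src_true.append(true_pos.get(sid))
            src_est.append(None)
        else:
            src_true.append(None)
            src_est.append(est_pos.get(sid))

    def project(lg: LineGraph, src: list[int | None]) -> np.ndarray:
        m = np.zeros((n, n), dtype=np.uint8)
        for i in range(n):
            if src[i] is None:
                continue
            for j in range(i + 1, n):
                if src[j] is None:
                    continue
                v = lg.matrix[src[i], src[j]]
                m[i, j] = m[j, i] = v
        return m

    return (
        LineGraph(index=shared, matrix=project(true_lg, src_true)),
        LineGraph(index=shared, matrix=project(est_lg, src_est)),
    )


def _check_aligned(a: LineGraph, b: LineGraph) -> None:
    if len(a) != len(b):
        raise ValueError(f"line graphs differ in size: {len(a)} vs {len(b)}")
    if a.index != b.index:
        raise ValueError("line graphs must share one node index")


def frobenius_error(a: LineGraph, b: LineGraph) -> float:
    """Frobenius norm of the difference of the full symmetric matrices."""
    _check_aligned(a, b)
    d = a.matrix.astype(np.float64) - b.matrix.astype(np.float64)
    return float(np.sqrt((d * d).sum()))


@dataclass
class GraphScore:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


def graph_f1(true_lg: LineGraph, est_lg: LineGraph) -> GraphScore:
    """Edge-detection precision/recall/F1 over unordered line-graph pairs.

    Conventions: precision is 0 when the test graph has no edges, recall is 0
    when the true graph has no edges, and F1 is 0 when both are 0.
    """
    _check_aligned(true_lg, est_lg)
    iu = np.triu_indices(len(true_lg), k=1)
    t = true_lg.matrix[iu].astype(bool)
    e = est_lg.matrix[iu].astype(bool)
    tp = int((t & e).sum())
    fp = int((~t & e).sum())
    fn = int((t & ~e).sum())
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    )
    return GraphScore(tp, fp, fn, precision, recall, f1)


@dataclass
class NullSummary:
    """Summary of the permutation null distribution."""

    observed: float
    null_errors: np.ndarray
    density: float
    statistic: str

    @property
    def mean(self) -> float:
        return float(self.null_errors.mean()) if self.null_errors.size else float("nan")

    @property
    def std(self) -> float:
        return float(self.null_errors.std()) if self.null_errors.size else float("nan")


def _null_errors_against(
    true_upper: np.ndarray, p: float, B: int, statistic: str, rng: np.random.Generator
) -> np.ndarray:
    """Score B density-p random symmetric graphs against a fixed truth.

    Works on the flattened upper triangle; the Frobenius norm of the full
    symmetric difference is sqrt(2 * Hamming distance on unordered pairs).
    """
    m = true_upper.size
    null = rng.random((B, m)) < p
    t = true_upper.astype(bool)[None, :]
    if statistic == "frobenius":
        diff = (null ^ t).sum(axis=1)
        return np.sqrt(2.0 * diff)
    tp = (null & t).sum(axis=1)
    fp = (null & ~t).sum(axis=1)
    fn = (~null & t).sum(axis=1)
    denom = 2 * tp + fp + fn
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2 * tp / np.where(denom > 0, denom, 1), 0.0)
    return 1.0 - f1


def permutation_pvalue(
    true_lg: LineGraph,
    est_lg: LineGraph,
    B: int = 10_000,
    statistic: str = "f1_deficit",
    seed: int | None = None,
    density_from: str = "est",
    smoothed: bool = True,
) -> tuple[float, NullSummary]:
    """Significance of the observed graph error against a density-matched null.

    ``B`` random symmetric graphs on the same nodes are drawn with each
    unordered pair an independent Bernoulli(p) edge, p being the observed
    line-graph density (of the estimated graph by default, or of the truth
    with ``density_from="true"``).  Each is scored against the true graph
    with the chosen statistic (``f1_deficit`` = 1 - F1, or ``frobenius``),
    and the p-value is the null CDF evaluated at the observed error:
    by default add-one smoothed, ``(1 + #{null <= observed}) / (B + 1)``, so
    it is never exactly 0; ``smoothed=False`` gives the raw empirical CDF.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if statistic not in ("f1_deficit", "frobenius"):
        raise ValueError(f"unknown statistic {statistic!r}")
    _check_aligned(true_lg, est_lg)
    if statistic == "frobenius":
        observed = frobenius_error(true_lg, est_lg)
    else:
        observed = 1.0 - graph_f1(true_lg, est_lg).f1
    p = est_lg.density() if density_from == "est" else true_lg.density()
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(len(true_lg), k=1)
    true_upper = true_lg.matrix[iu]
    null = _null_errors_against(true_upper, p, B, statistic, rng)
    k = int((null <= observed + 1e-12).sum())
    p_value = (1 + k) / (B + 1) if smoothed else k / B
    return p_value, NullSummary(
        observed=observed, null_errors=null, density=p, statistic=statistic
    )


@dataclass
class GraphErrorReport:
    """Every metric computed for one true-vs-test graph comparison."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    frobenius: float
    p_value: float
    B: int

    def __post_init__(self) -> None:
        pr = self.precision + self.recall
        expect = 2 * self.precision * self.recall / pr if pr else 0.0
        if abs(self.f1 - expect) > 1e-9:
            raise ValueError("f1 must be the harmonic mean of precision and recall")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must lie in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "frobenius": self.frobenius,
            "p_value": self.p_value,
            "B": self.B,
        }


def score_graphs(
    true_lg: LineGraph,
    est_lg: LineGraph,
    corr: Correspondence,
    B: int = 10_000,
    statistic: str = "f1_deficit",
    seed: int | None = None,
) -> GraphErrorReport:
    """Convenience wrapper: augment, score, and test one graph pair."""
    ta, ea = augment_line_graphs(true_lg, est_lg, corr)
    gs = graph_f1(ta, ea)
    frob = frobenius_error(ta, ea)
    p_value, _ = permutation_pvalue(ta, ea, B=B, statistic=statistic, seed=seed)
    return GraphErrorReport(
        tp=gs.tp,
        fp=gs.fp,
        fn=gs.fn,
        precision=gs.precision,
        recall=gs.recall,
        f1=gs.f1,
        frobenius=frob,
        p_value=p_value,
        B=B,
    )
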