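"""Readers and writers: volumes (HDF5/TIFF), synapse sets, graphs, reports.

HDF5 is the canonical volume container; multipage TIFF (slices along z) is
supported for small fixtures.  Graphs are written as GraphML (node id =
neuron id, one edge element per synapse with its attributes) and as an
attributed edge-list TSV with columns
``neuron_a  neuron_b  synapse_id  confidence  centroid_z  centroid_y
centroid_x``.  Reports carry provenance (seed, config hash, software
version) so any run can be reproduced bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import h5py
import networkx as nx
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .core_model import LabelVolume, NeuronGraph, SynapseAnnotation
from .evaluation import ErrorMatrix
from .graph_metrics import GraphErrorReport

__all__ = [
    "read_volume",
    "write_volume",
    "read_synapses",
    "write_synapses",
    "write_graphml",
    "read_graphml",
    "write_edgelist",
    "write_report",
    "read_report",
    "PipelineConfig",
]

_H5_SUFFIXES = {".h5", ".hdf5", ".hdf"}
_TIFF_SUFFIXES = {".tif", ".tiff"}


def read_volume(path: str | Path, dataset: str = "data"):
    """Read a 3D volume; integer data becomes a :class:`LabelVolume`.

    HDF5 files are read from the named dataset (``resolution`` and
    ``offset`` attributes are honored when present); TIFF files stack pages
    along z.  Floating-point data is returned as a bare array (grayscale or
    probability volume), axis order (z, y, x).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    suffix = path.suffix.lower()
    if suffix in _H5_SUFFIXES:
        with h5py.File(path, "r") as f:
            if dataset not in f:
                raise KeyError(f"dataset {dataset!r} not found in {path}")
            ds = f[dataset]
            arr = ds[()]
            resolution = tuple(ds.attrs.get("resolution", (1.0, 1.0, 1.0)))
            offset = tuple(int(v) for v in ds.attrs.get("offset", (0, 0, 0)))
    elif suffix in _TIFF_SUFFIXES:
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        resolution, offset = (1.0, 1.0, 1.0), (0, 0, 0)
    else:
        raise ValueError(f"unknown volume format {suffix!r} ({path})")
    if np.issubdtype(arr.dtype, np.integer):
        return LabelVolume(arr, resolution, offset)
    return arr


def write_volume(path: str | Path, volume, dataset: str = "data") -> Path:
    """Write a :class:`LabelVolume` or bare array to HDF5 or TIFF."""
    path = Path(path)
    arr = volume.data if isinstance(volume, LabelVolume) else np.asarray(volume)
    suffix = path.suffix.lower()
    if suffix in _H5_SUFFIXES:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset(dataset, data=arr, compression="gzip")
            if isinstance(volume, LabelVolume):
                ds.attrs["resolution"] = tuple(volume.resolution)
                ds.attrs["offset"] = tuple(volume.offset)
    elif suffix in _TIFF_SUFFIXES:
        tifffile.imwrite(path, arr)
    else:
        raise ValueError(f"unknown volume format {suffix!r} ({path})")
    return path


def write_synapses(path: str | Path, synapses: list[SynapseAnnotation]) -> Path:
    """Write a synapse annotation set to HDF5, one group per synapse."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for syn in synapses:
            g = f.create_group(f"synapse_{syn.id}")
            g.create_dataset("voxels", data=syn.voxels)
            g.attrs["id"] = syn.id
            g.attrs["confidence"] = syn.confidence
            g.attrs["partners"] = list(syn.partners) if syn.partners else []
            for k, v in syn.kv.items():
                g.attrs[f"kv_{k}"] = str(v)
    return path


def read_synapses(path: str | Path) -> list[SynapseAnnotation]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such synapse file: {path}")
    out = []
    with h5py.File(path, "r") as f:
        for name in f:
            g = f[name]
            partners = tuple(int(p) for p in g.attrs["partners"])
            kv = {
                k[3:]: str(g.attrs[k]) for k in g.attrs if k.startswith("kv_")
            }
            out.append(
                SynapseAnnotation(
                    id=int(g.attrs["id"]),
                    voxels=g["voxels"][()],
                    confidence=float(g.attrs["confidence"]),
                    partners=partners or None,
                    kv=kv,
                )
            )
    out.sort(key=lambda s: s.id)
    return out


def _centroid_attrs(attrs: dict) -> dict:
    out = {}
    for k, v in attrs.items():
        if k == "overlaps":
            out[k] = json.dumps(v)
        else:
            out[k] = v
    return out


def write_graphml(
    graph: NeuronGraph,
    path: str | Path,
    synapses: list[SynapseAnnotation] | None = None,
) -> Path:
    """Write the neuron multigraph as GraphML.

    Node ids are neuron ids; each synapse contributes one edge element with
    ``synapse_id`` and, when the annotation set is supplied, its confidence
    and centroid coordinates.  Parallel edges are preserved.
    """
    by_id = {s.id: s for s in synapses} if synapses else {}
    g = nx.MultiGraph()
    g.add_nodes_from(sorted(graph.nodes))
    for a, b, sid, attrs in graph.edges:
        edge_attrs: dict[str, Any] = {"synapse_id": sid}
        syn = by_id.get(sid)
        if syn is not None:
            cz, cy, cx = syn.centroid()
            edge_attrs.update(
                confidence=float(syn.confidence),
                centroid_z=float(cz),
                centroid_y=float(cy),
                centroid_x=float(cx),
            )
        edge_attrs.update(_centroid_attrs(attrs))
        g.add_edge(a, b, key=sid, **edge_attrs)
    nx.write_graphml(g, str(path))
    return Path(path)


def read_graphml(path: str | Path) -> "nx.MultiGraph":
    return nx.read_graphml(str(path), node_type=int, force_multigraph=True)


def write_edgelist(
    graph: NeuronGraph,
    path: str | Path,
    synapses: list[SynapseAnnotation] | None = None,
) -> Path:
    """Attributed edge list, one TSV row per synapse edge."""
    by_id = {s.id: s for s in synapses} if synapses else {}
    rows = []
    for a, b, sid, _ in graph.edges:
        syn = by_id.get(sid)
        if syn is not None:
            cz, cy, cx = syn.centroid()
            conf = syn.confidence
        else:
            cz = cy = cx = float("nan")
            conf = float("nan")
        rows.append(
            {
                "neuron_a": a,
                "neuron_b": b,
                "synapse_id": sid,
                "confidence": conf,
                "centroid_z": cz,
                "centroid_y": cy,
                "centroid_x": cx,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "neuron_a",
            "neuron_b",
            "synapse_id",
            "confidence",
            "centroid_z",
            "centroid_y",
            "centroid_x",
        ],
    ).to_csv(path, sep="\t", index=False)
    return Path(path)


def _provenance(seed: int | None, config: dict | None) -> dict:
    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    return {
        "software_version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "config": config or {},
    }


def write_report(
    report: GraphErrorReport | ErrorMatrix,
    path: str | Path,
    seed: int | None = None,
    config: dict | None = None,
) -> Path:
    """Serialize a graph-error report or a full evaluation matrix.

    Reports become JSON with every metric field plus provenance.  An
    :class:`ErrorMatrix` is additionally flattened to a CSV table next to
    the JSON file (same stem, ``.csv`` suffix).
    """
    path = Path(path)
    payload: dict[str, Any] = {"provenance": _provenance(seed, config)}
    if isinstance(report, GraphErrorReport):
        payload["kind"] = "graph_error_report"
        payload["report"] = report.to_dict()
    elif isinstance(report, ErrorMatrix):
        payload["kind"] = "error_matrix"
        payload["alpha"] = report.alpha
        payload["B"] = report.B
        payload["seed"] = report.seed
        payload["rows"] = report.rows
        payload["cols"] = report.cols
        payload["row_key"] = report.row_key
        payload["col_key"] = report.col_key
        payload["records"] = report.to_records()
        pd.DataFrame(report.to_records()).to_csv(
            path.with_suffix(".csv"), index=False
        )
    else:
        raise TypeError(f"cannot serialize report of type {type(report)}")
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


@dataclass
class PipelineConfig:
    """Paths, detector settings, grid definition, and seeds for a full run."""

    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    detector: dict[str, Any] = field(default_factory=dict)
    sweep: dict[str, Any] = field(default_factory=dict)
    B: int = 1000
    alpha: float = 0.001
    seed: int = 0
    block: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(
            inputs=raw.get("inputs", {}),
            outputs=raw.get("outputs", {}),
            detector=raw.get("detector", {}),
            sweep=raw.get("sweep", {}),
            B=int(raw.get("B", 1000)),
            alpha=float(raw.get("alpha", 0.001)),
            seed=int(raw.get("seed", 0)),
            block=raw.get("block", {}),
        )
        for name, p in cfg.inputs.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"input {name!r} does not exist: {p}")
        return cfg
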