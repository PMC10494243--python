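"""Reading and writing recordings, ground truth, networks and configs.

Formats: HDF5 for trace matrices (dataset ``F`` with ``fs_hz``/``t0``/
``islet_id`` attributes, datasets ``positions`` and ``cell_ids``, the
protocol embedded as JSON), tidy CSV (``time_s, cell_id, F``) for
interchange, JSON for ground truth, GraphML + edge-list CSV for networks,
YAML for configurations.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .funcnet import CorrelationMatrix, FunctionalNetwork
from .pipeline import StudyConfig
from .protocol import Protocol, Segment, glucose_control_protocol, glucose_forskolin_protocol
from .synth import GroundTruth, IsletConfig
from .traces import TraceSet


# ------------------------------------------------------------------ traces

def save_traceset_h5(traces: TraceSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("F", data=traces.F)
        d.attrs["fs_hz"] = traces.fs
        d.attrs["t0"] = traces.t0
        d.attrs["islet_id"] = traces.islet_id
        f.create_dataset("positions", data=traces.positions)
        f.create_dataset(
            "cell_ids", data=np.array(traces.cell_ids, dtype="S")
        )
        f.attrs["protocol"] = traces.protocol.to_json()


def load_traceset_h5(path: str | Path) -> TraceSet:
    with h5py.File(path, "r") as f:
        d = f["F"]
        return TraceSet(
            F=d[...],
            fs=float(d.attrs["fs_hz"]),
            t0=float(d.attrs["t0"]),
            islet_id=str(d.attrs["islet_id"]),
            positions=f["positions"][...],
            cell_ids=[s.decode() for s in f["cell_ids"][...]],
            protocol=Protocol.from_json(f.attrs["protocol"]),
        )


def traceset_to_csv(traces: TraceSet, path: str | Path) -> None:
    """Tidy long-format export: one row per (time, cell)."""
    t = traces.time
    frames = []
    for j, cid in enumerate(traces.cell_ids):
        frames.append(
            pd.DataFrame({"time_s": t, "cell_id": cid, "F": traces.F[:, j]})
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def save_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json())


def load_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())


# ---------------------------------------------------------------- networks

def export_network(
    net: FunctionalNetwork,
    corr: CorrelationMatrix,
    edge_csv: str | Path | None = None,
    graphml: str | Path | None = None,
) -> None:
    """Edge list CSV (cell_i, cell_j, r) and/or GraphML with positions."""
    g = net.graph.copy()
    for i, j in g.edges:
        g.edges[i, j]["r"] = float(corr.R[i, j])
    if edge_csv is not None:
        rows = [
            {
                "cell_i": net.cell_ids[i],
                "cell_j": net.cell_ids[j],
                "r": g.edges[i, j]["r"],
            }
            for i, j in g.edges
        ]
        pd.DataFrame(rows, columns=["cell_i", "cell_j", "r"]).to_csv(
            edge_csv, index=False
        )
    if graphml is not None:
        nx.write_graphml(g, graphml)


# ------------------------------------------------------------------ config

def protocol_from_dict(d: dict) -> Protocol:
    """Build a protocol from a config mapping.

    Either ``{"kind": "control"|"forskolin", **overrides}`` using the stock
    protocols, or ``{"segments": [{name,start,end,...}, ...]}``.
    """
    d = dict(d)
    if "segments" in d:
        return Protocol([Segment(**s) for s in d["segments"]])
    kind = d.pop("kind", "control")
    if kind == "control":
        return glucose_control_protocol(**d)
    if kind == "forskolin":
        return glucose_forskolin_protocol(**d)
    raise ValueError(f"unknown protocol kind {kind!r}")


def load_islet_config(path: str | Path) -> tuple[IsletConfig, Protocol]:
    """YAML with top-level ``islet:`` (IsletConfig fields) and
    ``protocol:`` mappings."""
    d = yaml.safe_load(Path(path).read_text()) or {}
    islet = d.get("islet", {})
    if "pacemaker_xy" in islet:
        islet["pacemaker_xy"] = tuple(islet["pacemaker_xy"])
    cfg = IsletConfig(**islet)
    prot = protocol_from_dict(d.get("protocol", {}))
    return cfg, prot


def load_study_config(path: str | Path) -> StudyConfig:
    d = yaml.safe_load(Path(path).read_text()) or {}
    return StudyConfig.from_dict(d.get("study", d))
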