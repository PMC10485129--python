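"""CSV/JSON input and output for tissues, kernels, states and results."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import SweepResult, TissueState
from .pcf import PCFResult
from .signaling import SignalKernel
from .tissue import CellGraph, Tissue, _graph_from_adjacency

__all__ = [
    "save_tissue",
    "load_tissue",
    "save_state",
    "load_labels",
    "save_sweep",
    "save_pcf",
    "save_kernel",
    "write_metadata",
]


def save_tissue(directory: str | Path, tissue: Tissue, graph: CellGraph) -> None:
    """Write ``positions.csv`` (id,x,y,radius) and ``edges.csv`` (id_i,id_j)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "id": np.arange(tissue.n),
            "x": tissue.positions[:, 0],
            "y": tissue.positions[:, 1],
            "radius": tissue.radius,
        }
    ).to_csv(directory / "positions.csv", index=False)
    ii, jj = np.nonzero(np.triu(graph.adjacency))
    pd.DataFrame({"id_i": ii, "id_j": jj}).to_csv(directory / "edges.csv", index=False)


def load_tissue(directory: str | Path) -> tuple[Tissue, CellGraph]:
    """Inverse of :func:`save_tissue`; distances are rebuilt by BFS."""
    directory = Path(directory)
    pos = pd.read_csv(directory / "positions.csv").sort_values("id")
    edges = pd.read_csv(directory / "edges.csv")
    tissue = Tissue(
        positions=pos[["x", "y"]].to_numpy(float),
        radius=float(pos["radius"].iloc[0]),
    )
    adj = np.zeros((tissue.n, tissue.n), dtype=bool)
    i = edges["id_i"].to_numpy(int)
    j = edges["id_j"].to_numpy(int)
    adj[i, j] = adj[j, i] = True
    return tissue, _graph_from_adjacency(adj)


def save_state(path: str | Path, tissue: Tissue, state: TissueState) -> None:
    """Per-cell state CSV: id,x,y,u,v,s,label."""
    labels = state.labels if state.labels is not None else [""] * state.n
    pd.DataFrame(
        {
            "id": np.arange(state.n),
            "x": tissue.positions[:, 0],
            "y": tissue.positions[:, 1],
            "u": state.u,
            "v": state.v,
            "s": state.s,
            "label": labels,
        }
    ).to_csv(path, index=False)


def load_labels(path: str | Path) -> np.ndarray:
    """Labels column of a per-cell state CSV, ordered by cell id."""
    df = pd.read_csv(path).sort_values("id")
    return df["label"].to_numpy(object)


def save_sweep(path: str | Path, sweep: SweepResult) -> None:
    pd.DataFrame(
        {
            "delta_eps_u": sweep.delta_eps_values,
            "prop_upos": sweep.prop_u,
            "prop_vpos": sweep.prop_v,
            "converged": sweep.converged,
            "steps": sweep.steps,
        }
    ).to_csv(path, index=False)


def save_pcf(path: str | Path, result: PCFResult) -> None:
    pd.DataFrame(
        {
            "k": result.k,
            "S_k": result.s_k,
            "Su_k": result.su_k,
            "Sv_k": result.sv_k,
            "rho_u": result.rho_u,
            "rho_v": result.rho_v,
        }
    ).to_csv(path, index=False)


def save_kernel(path: str | Path, kernel: SignalKernel, *, dense: bool = False) -> None:
    """Kernel weights as coordinate-list CSV (i,j,weight), or dense CSV."""
    if dense:
        pd.DataFrame(kernel.weights).to_csv(path, index=False, header=False)
        return
    ii, jj = np.nonzero(kernel.weights)
    pd.DataFrame({"i": ii, "j": jj, "weight": kernel.weights[ii, jj]}).to_csv(
        path, index=False
    )


def write_metadata(path: str | Path, payload: dict) -> None:
    """JSON metadata record; includes package and library versions."""
    from . import __version__

    record = {
        "fatepattern_version": __version__,
        "numpy_version": np.__version__,
        **payload,
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
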