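"""End-to-end run orchestration: tissue → kernel → dynamics → outputs.

Every run writes a ``run.json`` metadata record with the effective
configuration, the global seed and its per-stage substreams, and library
versions — enough to reproduce the run bit for bit.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import io
from .config import RunConfig
from .dynamics import (
    bisect_ratio,
    classify,
    proportion_sweep,
    random_initial_state,
    simulate,
)
from .pcf import pcf
from .signaling import dispersion_kernel, neighbor_mean_kernel
from .tissue import CellGraph, Tissue, contact_graph, generate_disc_tissue, hex_lattice, line_graph

__all__ = ["run", "stage_seed", "EXIT_OK", "EXIT_VALIDATION", "EXIT_NOT_CONVERGED"]

logger = logging.getLogger("fatepattern")

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_NOT_CONVERGED = 3

#: Stage codes for expanding the global seed into independent substreams.
_STAGES = {"tissue": 0, "init": 1, "null": 2}


def stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Named, reproducible substream of the global seed for one stage."""
    return np.random.SeedSequence([int(seed), _STAGES[stage]])


def _build_tissue(cfg: RunConfig) -> tuple[Tissue | None, CellGraph]:
    tissue_seed = stage_seed(cfg.seed, "tissue").generate_state(1)[0] >> 1
    if cfg.tissue_kind == "disc":
        tissue = generate_disc_tissue(cfg.n, int(tissue_seed))
        return tissue, contact_graph(tissue)
    if cfg.tissue_kind == "hex":
        return hex_lattice(cfg.rows, cfg.cols, cfg.periodic)
    if cfg.tissue_kind == "line":
        graph = line_graph(cfg.n)
        positions = np.column_stack([np.arange(cfg.n, dtype=float), np.zeros(cfg.n)])
        return Tissue(positions=positions, radius=0.525), graph
    raise ValueError(f"unknown tissue kind {cfg.tissue_kind!r}")


def _build_kernel(cfg: RunConfig, graph: CellGraph):
    if cfg.signal_kind == "neighbor-mean":
        return neighbor_mean_kernel(graph)
    return dispersion_kernel(graph, cfg.q)


def run(cfg: RunConfig, out_dir: str | Path) -> int:
    """Execute the configured experiment; returns a process exit status."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tissue, graph = _build_tissue(cfg)
    kernel = _build_kernel(cfg, graph)
    io.save_tissue(out, tissue, graph)
    metadata = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "stage_seeds": {k: [cfg.seed, v] for k, v in _STAGES.items()},
        "experiment": cfg.experiment,
    }
    status = EXIT_OK

    if cfg.experiment in ("simulate", "pcf"):
        init_rng = np.random.default_rng(stage_seed(cfg.seed, "init"))
        init = random_initial_state(graph.n, cfg.params, init_rng)
        state = simulate(
            graph,
            kernel,
            cfg.params,
            init=init,
            dt=cfg.dt,
            tol=cfg.tol,
            max_steps=cfg.max_steps,
        )
        logger.info("simulate: %d steps, converged=%s", state.steps, state.converged)
        if state.converged:
            classify(state, cfg.ratio_threshold)
        else:
            status = EXIT_NOT_CONVERGED
        io.save_state(out / "state.csv", tissue, state)
        metadata["converged"] = state.converged
        metadata["steps"] = state.steps
        if cfg.experiment == "pcf" and state.converged:
            result = pcf(state.labels, graph.distances)
            io.save_pcf(out / "pcf.csv", result)
    elif cfg.experiment == "sweep":
        sweep = proportion_sweep(
            graph,
            kernel,
            cfg.params,
            n_grid=cfg.n_grid,
            seed=cfg.seed,
            dt=cfg.dt,
            tol=cfg.tol,
            max_steps=cfg.max_steps,
        )
        logger.info(
            "sweep: %d grid points, %d converged", cfg.n_grid, int(sweep.converged.sum())
        )
        io.save_sweep(out / "sweep.csv", sweep)
        metadata["converged"] = bool(sweep.converged.all())
        if not sweep.converged.all():
            status = EXIT_NOT_CONVERGED
    elif cfg.experiment == "bisect":
        target = cfg.target_counts
        if target is None:
            target = (graph.n // 2 + graph.n % 2, graph.n // 2)
        result = bisect_ratio(
            graph,
            kernel,
            cfg.params,
            target,
            seed=cfg.seed,
            dt=cfg.dt,
            tol=cfg.tol,
            max_steps=cfg.max_steps,
        )
        logger.info(
            "bisect: -delta_eps_u=%.6f counts=%s exact=%s",
            result.delta_eps_u,
            result.counts,
            result.exact,
        )
        io.save_state(out / "state.csv", tissue, result.state)
        metadata["bisect"] = {
            "delta_eps_u": result.delta_eps_u,
            "counts": list(result.counts),
            "target": list(result.target),
            "exact": result.exact,
            "iterations": result.iterations,
        }
    io.write_metadata(out / "run.json", metadata)
    return status
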