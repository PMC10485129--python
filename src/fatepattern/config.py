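"""Run configuration: schema, validation, and parameter construction.

A run is described by a small YAML (or JSON) document with five sections::

    model:        r_u, r_v, gamma_u, gamma_v, eta_u | delta_eps_u,
                  eta_v | delta_eps_v, eta_s, eta_vs
                  [eta_uv, eta_us, eta_uvs]
    tissue:       kind (disc|hex|line), n, rows, cols, periodic, seed
    signal:       kind (neighbor-mean|dispersion), q
    integration:  dt, tol, max_steps
    experiment:   kind (simulate|sweep|bisect|pcf), n_grid, target_counts,
                  ratio_threshold

Omitted model keys fall back to the package defaults; unknown keys anywhere
are rejected with a report naming every offending key.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .params import ModelParams, default_params

__all__ = ["ConfigError", "RunConfig"]

_MODEL_KEYS = {
    "r_u",
    "r_v",
    "gamma_u",
    "gamma_v",
    "eta_u",
    "eta_v",
    "eta_s",
    "eta_vs",
    "eta_uv",
    "eta_us",
    "eta_uvs",
    "delta_eps_u",
    "delta_eps_v",
    "delta_eps_s",
    "delta_eps_vs",
}
_TISSUE_KEYS = {"kind", "n", "rows", "cols", "periodic", "seed"}
_SIGNAL_KEYS = {"kind", "q"}
_INTEGRATION_KEYS = {"dt", "tol", "max_steps"}
_EXPERIMENT_KEYS = {"kind", "n_grid", "target_counts", "ratio_threshold"}


class ConfigError(ValueError):
    """Invalid configuration; ``errors`` lists every offending key."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


@dataclass
class RunConfig:
    params: ModelParams
    tissue_kind: str = "disc"
    n: int = 177
    rows: int = 12
    cols: int = 12
    periodic: bool = False
    seed: int = 0
    signal_kind: str = "neighbor-mean"
    q: float = 0.5
    dt: float | None = None
    tol: float = 1e-8
    max_steps: int = 10_000_000
    experiment: str = "simulate"
    n_grid: int = 20
    target_counts: tuple[int, int] | None = None
    ratio_threshold: float = 1.0
    raw: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        errors: list[str] = []
        doc = dict(doc or {})
        sections = {"model", "tissue", "signal", "integration", "experiment"}
        for key in doc:
            if key not in sections:
                errors.append(f"unknown section {key!r}")
        model = doc.get("model") or {}
        tissue = doc.get("tissue") or {}
        signal = doc.get("signal") or {}
        integ = doc.get("integration") or {}
        exp = doc.get("experiment") or {}
        for name, section, allowed in (
            ("model", model, _MODEL_KEYS),
            ("tissue", tissue, _TISSUE_KEYS),
            ("signal", signal, _SIGNAL_KEYS),
            ("integration", integ, _INTEGRATION_KEYS),
            ("experiment", exp, _EXPERIMENT_KEYS),
        ):
            if not isinstance(section, dict):
                errors.append(f"section {name!r} must be a mapping")
                continue
            for key in section:
                if key not in allowed:
                    errors.append(f"unknown key {name}.{key}")
        if errors:
            raise ConfigError(errors)

        params, param_errors = _build_params(model)
        errors.extend(param_errors)

        cfg = cls(params=params or default_params(), raw=doc)
        cfg.tissue_kind = tissue.get("kind", cfg.tissue_kind)
        if cfg.tissue_kind not in ("disc", "hex", "line"):
            errors.append(f"tissue.kind must be disc|hex|line, got {cfg.tissue_kind!r}")
        cfg.n = int(tissue.get("n", cfg.n))
        cfg.rows = int(tissue.get("rows", cfg.rows))
        cfg.cols = int(tissue.get("cols", cfg.cols))
        cfg.periodic = bool(tissue.get("periodic", cfg.periodic))
        cfg.seed = int(tissue.get("seed", cfg.seed))
        cfg.signal_kind = signal.get("kind", cfg.signal_kind)
        if cfg.signal_kind not in ("neighbor-mean", "dispersion"):
            errors.append(
                f"signal.kind must be neighbor-mean|dispersion, got {cfg.signal_kind!r}"
            )
        cfg.q = float(signal.get("q", cfg.q))
        if not 0.0 <= cfg.q <= 1.0:
            errors.append(f"signal.q must be in [0, 1], got {cfg.q}")
        if integ.get("dt") is not None:
            cfg.dt = float(integ["dt"])
            if cfg.dt <= 0:
                errors.append("integration.dt must be positive")
        cfg.tol = float(integ.get("tol", cfg.tol))
        cfg.max_steps = int(integ.get("max_steps", cfg.max_steps))
        cfg.experiment = exp.get("kind", cfg.experiment)
        if cfg.experiment not in ("simulate", "sweep", "bisect", "pcf"):
            errors.append(
                f"experiment.kind must be simulate|sweep|bisect|pcf, got {cfg.experiment!r}"
            )
        cfg.n_grid = int(exp.get("n_grid", cfg.n_grid))
        if "target_counts" in exp:
            tc = exp["target_counts"]
            try:
                cfg.target_counts = (int(tc[0]), int(tc[1]))
            except (TypeError, ValueError, IndexError):
                errors.append(f"experiment.target_counts must be a pair of ints, got {tc!r}")
        cfg.ratio_threshold = float(exp.get("ratio_threshold", cfg.ratio_threshold))
        if errors:
            raise ConfigError(errors)
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if doc is None:
            doc = {}
        if not isinstance(doc, dict):
            raise ConfigError([f"config root must be a mapping, got {type(doc).__name__}"])
        return cls.from_dict(doc)

    def to_dict(self) -> dict:
        """Full echo of the effective configuration (round-trips through
        :meth:`from_dict` to an equivalent config)."""
        return {
            "model": self.params.to_dict(),
            "tissue": {
                "kind": self.tissue_kind,
                "n": self.n,
                "rows": self.rows,
                "cols": self.cols,
                "periodic": self.periodic,
                "seed": self.seed,
            },
            "signal": {"kind": self.signal_kind, "q": self.q},
            "integration": {
                "dt": self.dt,
                "tol": self.tol,
                "max_steps": self.max_steps,
            },
            "experiment": {
                "kind": self.experiment,
                "n_grid": self.n_grid,
                **(
                    {"target_counts": list(self.target_counts)}
                    if self.target_counts is not None
                    else {}
                ),
                "ratio_threshold": self.ratio_threshold,
            },
        }


def _build_params(model: dict) -> tuple[ModelParams | None, list[str]]:
    errors: list[str] = []
    base = default_params().to_dict()
    for eta_key, eps_key in (
        ("eta_u", "delta_eps_u"),
        ("eta_v", "delta_eps_v"),
        ("eta_s", "delta_eps_s"),
        ("eta_vs", "delta_eps_vs"),
    ):
        if eta_key in model and eps_key in model:
            errors.append(f"model: give either {eta_key} or {eps_key}, not both")
        elif eps_key in model:
            base[eta_key] = math.exp(-float(model[eps_key]))
        elif eta_key in model:
            base[eta_key] = float(model[eta_key])
    for key in ("r_u", "r_v", "gamma_u", "gamma_v", "eta_uv", "eta_us", "eta_uvs"):
        if key in model:
            base[key] = float(model[key])
    if errors:
        return None, errors
    try:
        return ModelParams(**base), []
    except ValueError as exc:
        return None, [f"model: {exc}"]
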