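"""Signal kernels: how secreted u reaches other cells.

Both kernels are linear maps ``s = A @ u`` from the per-cell u levels to the
per-cell received signal.

* ``neighbor-mean``: each cell receives the arithmetic mean of its contact
  neighbors' u (slowly diffusing paracrine signal).
* ``dispersion``: each cell receives a weighted sum over all other cells,
  with weight ``q**(d_ij - 1)`` falling off per graph hop and a global
  normalization so that the best-connected cell's weights sum to 1.  The
  dispersion parameter ``q`` interpolates from contact-only signaling
  (q=0, weights become the adjacency indicator) to a uniform all-to-all
  signal (q=1).

Under either kernel the received signal at a heterogeneous steady state is
bounded by ``0 <= s_i < r_u/gamma_u``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .params import ModelParams
from .tissue import CellGraph

__all__ = ["SignalKernel", "neighbor_mean_kernel", "dispersion_kernel", "signal_bounds"]


@dataclass(frozen=True)
class SignalKernel:
    """Nonnegative weight matrix mapping u levels to received signals."""

    weights: np.ndarray  # (N, N), zero diagonal
    kind: str  # "neighbor-mean" | "dispersion"
    q: float | None = None  # dispersion parameter (dispersion kind only)
    normalization: float | None = None  # scalar a (dispersion kind only)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if np.any(w < 0) or np.any(np.diag(w) != 0):
            raise ValueError("weights must be nonnegative with zero diagonal")

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def apply(self, u: np.ndarray) -> np.ndarray:
        """Received signal ``s = A @ u``; broadcasts over leading axes."""
        u = np.asarray(u, dtype=float)
        return u @ self.weights.T


def neighbor_mean_kernel(graph: CellGraph) -> SignalKernel:
    """Averaged nearest-neighbor kernel, ``A_ij = 1/deg(i)`` for contacts.

    Isolated cells receive 0 by convention (their row is all zeros); a
    warning is emitted since the tissue generators normally exclude them.
    """
    adj = graph.adjacency.astype(float)
    deg = adj.sum(axis=1)
    isolated = deg == 0
    if np.any(isolated):
        warnings.warn(
            f"{int(isolated.sum())} isolated cell(s) receive zero signal",
            stacklevel=2,
        )
    weights = adj / np.where(isolated, 1.0, deg)[:, None]
    return SignalKernel(weights=weights, kind="neighbor-mean")


def dispersion_kernel(graph: CellGraph, q: float) -> SignalKernel:
    """Distance-based kernel ``A_ij = a * q**(d_ij - 1)`` for ``i != j``.

    The normalization ``a`` is the reciprocal of the largest row sum of the
    unnormalized weights, so the best-connected cell (in a round tissue, the
    central one) has total incoming weight 1.  Convention ``0**0 = 1``: at
    q=0 the weights reduce to the adjacency indicator times ``a``; at q=1
    every off-diagonal weight equals ``a = 1/(N-1)`` (requires a connected
    graph).  Infinite distances get zero weight for ``q < 1``.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"dispersion q must be in [0, 1], got {q}")
    d = graph.distances
    n = graph.n
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d)
    if q == 1.0 and not finite.all():
        raise ValueError("q=1 on a disconnected graph is ill-posed")
    raw = np.zeros((n, n))
    mask = off & finite
    with np.errstate(divide="ignore"):
        # 0**0 == 1 under numpy power, which is the convention needed at d=1
        raw[mask] = np.power(q, d[mask] - 1.0)
    a = 1.0 / raw.sum(axis=1).max()
    return SignalKernel(weights=a * raw, kind="dispersion", q=q, normalization=a)


def signal_bounds(params: ModelParams) -> tuple[float, float]:
    """Extreme received signals ``(0, r_u/gamma_u)`` over heterogeneous
    steady states, for either kernel kind.

    The upper bound is the steady-state u level up to the correction
    ``(1 + eta_s * r_u/gamma_u) / eta_u``; a warning is emitted when that
    correction is not small compared to ``r_u/gamma_u`` (the bounds then
    overestimate the maximal signal).
    """
    ratio = params.r_u / params.gamma_u
    correction = (1.0 + params.eta_s * ratio) / params.eta_u
    if correction > 0.1 * ratio:
        warnings.warn(
            f"steady-state correction {correction:.3g} is not small relative to "
            f"r_u/gamma_u = {ratio:.3g}; signal ceiling is a loose bound",
            stacklevel=2,
        )
    return 0.0, ratio
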