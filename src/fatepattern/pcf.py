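"""Graph-distance pair correlation functions for two-type labeled tissues.

For each graph distance ``k`` the PCF relates the frequency of same-type
cell pairs at that distance to the probability of drawing two cells of that
type at random (without replacement).  Values above 1 mean the type
accumulates at that distance, below 1 that it avoids it; uniformly random
labels give 1 in expectation at every distance.

Ordered-pair counting is used throughout: every unordered pair enters the
numerator and denominator sets twice, which leaves all ratios unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import FATE_U, FATE_V, UNDECIDED

__all__ = ["PCFResult", "pair_counts", "pcf"]


@dataclass(frozen=True)
class PCFResult:
    """Per-distance pair counts and normalized correlations.

    ``k`` holds the observed finite distances (those with at least one
    pair); ``rho_u``/``rho_v`` are NaN until computed by :func:`pcf`.
    """

    k: np.ndarray  # observed distances, ascending
    s_k: np.ndarray  # ordered pairs at distance k
    su_k: np.ndarray  # ordered u+v- same-type pairs at distance k
    sv_k: np.ndarray  # ordered u-v+ same-type pairs at distance k
    t_u: int  # total u+v- cells
    t_v: int  # total u-v+ cells
    rho_u: np.ndarray | None = None
    rho_v: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.t_u + self.t_v


def _as_label_array(labels) -> np.ndarray:
    labels = np.asarray(labels, dtype=object)
    bad = ~np.isin(labels, (FATE_U, FATE_V))
    if bad.any():
        offenders = np.nonzero(bad)[0]
        if np.any(labels[offenders] == UNDECIDED):
            raise ValueError(
                f"undecided labels for cells {offenders.tolist()}; "
                "pair correlations need a complete two-type labeling"
            )
        raise ValueError(f"unknown labels for cells {offenders.tolist()}")
    return labels


def pair_counts(labels, distances) -> PCFResult:
    """Count ordered cell pairs per graph distance, overall and same-type.

    ``distances`` is the square hop-count matrix; all pairwise distances
    must be finite.  Distances with no pairs are omitted.
    """
    labels = _as_label_array(labels)
    d = np.asarray(distances, dtype=float)
    n = labels.shape[0]
    if d.shape != (n, n):
        raise ValueError(f"distance matrix {d.shape} does not match {n} labels")
    if not np.all(np.isfinite(d)):
        raise ValueError("pair correlations require a connected tissue")
    off = ~np.eye(n, dtype=bool)
    dk = d[off].astype(np.int64)
    is_u = labels == FATE_U
    same_u = (is_u[:, None] & is_u[None, :])[off]
    same_v = (~is_u[:, None] & ~is_u[None, :])[off]
    k_max = dk.max()
    s_k = np.bincount(dk, minlength=k_max + 1)
    su_k = np.bincount(dk, weights=same_u, minlength=k_max + 1)
    sv_k = np.bincount(dk, weights=same_v, minlength=k_max + 1)
    observed = np.nonzero(s_k)[0]
    observed = observed[observed > 0]
    return PCFResult(
        k=observed,
        s_k=s_k[observed],
        su_k=su_k[observed].astype(np.int64),
        sv_k=sv_k[observed].astype(np.int64),
        t_u=int(is_u.sum()),
        t_v=int((~is_u).sum()),
    )


def pcf(labels, distances) -> PCFResult:
    """Pair correlation functions ``rho_u(k)`` and ``rho_v(k)``.

    ``rho_u(k) = (|S_u_k| / |S_k|) / p_uu`` with
    ``p_uu = T_u (T_u - 1) / (N (N - 1))``, and analogously for v.  Both
    types must have at least two cells for the normalization to exist.
    """
    counts = pair_counts(labels, distances)
    if counts.t_u < 2 or counts.t_v < 2:
        raise ValueError(
            f"PCF normalization undefined: need >= 2 cells of each type, "
            f"got {counts.t_u} u+v- and {counts.t_v} u-v+"
        )
    n = counts.n
    p_uu = counts.t_u * (counts.t_u - 1) / (n * (n - 1))
    p_vv = counts.t_v * (counts.t_v - 1) / (n * (n - 1))
    r_uu = counts.su_k / counts.s_k
    r_vv = counts.sv_k / counts.s_k
    return PCFResult(
        k=counts.k,
        s_k=counts.s_k,
        su_k=counts.su_k,
        sv_k=counts.sv_k,
        t_u=counts.t_u,
        t_v=counts.t_v,
        rho_u=r_uu / p_uu,
        rho_v=r_vv / p_vv,
    )
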