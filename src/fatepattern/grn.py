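"""Thermodynamic binding model and steady-state analysis of the fate switch.

Transcription of each factor is proportional to the probability that the
factor is bound near its own promoter.  The probabilities follow from
Boltzmann statistics over the binding microstates of ``u``, ``v`` and the
signal ``s``: every bound configuration contributes a summand given by the
product of the participating weights, and a probability is the ratio of the
productive summands to the full partition sum.  With blocking mutual
inhibition (``eta_uv = eta_us = eta_uvs = 0``) and cooperative signal/v
activation (``eta_vs >= 1``) the probabilities reduce to

    p_u = eta_u*u / D,   p_v = eta_v*v*(1 + eta_s*eta_vs*s) / D,
    D   = 1 + eta_v*v*(1 + eta_s*eta_vs*s) + eta_u*u + eta_s*s,

and each cell's concentrations obey ``du/dt = r_u*p_u - gamma_u*u`` (and
analogously for v), coupled across the tissue only through ``s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .params import ModelParams, StabilityInterval

__all__ = [
    "binding_prob_general",
    "binding_probs",
    "rhs",
    "critical_signal",
    "SteadyStates",
    "steady_states",
    "stability_interval",
    "exclusion_condition",
    "l_max",
    "jacobian",
]


def _check_nonnegative(name: str, x) -> None:
    if np.any(np.asarray(x) < 0):
        raise ValueError(f"{name} must be nonnegative")


def binding_prob_general(u, v, s, params: ModelParams):
    """Binding probabilities ``(p_u, p_v)`` for the full interaction model.

    The partition sum runs over the empty state (weight 1) and the seven
    bound configurations: u, v, s alone; the pairs (u,v), (u,s), (v,s); and
    the triple (u,v,s).  ``p_u`` collects the configurations with u bound,
    ``p_v`` those with v bound.  Scalar or array inputs broadcast.

    With ``eta_uv = 1`` (and the other interactions consistent) the u
    probability factorizes back to the non-interacting single-species form
    ``eta_u*u/(1 + eta_u*u)``.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    s = np.asarray(s, dtype=float)
    _check_nonnegative("u", u)
    _check_nonnegative("v", v)
    _check_nonnegative("s", s)
    p = params
    w_u = p.eta_u * u
    w_v = p.eta_v * v
    w_s = p.eta_s * s
    w_uv = p.eta_u * p.eta_v * p.eta_uv * u * v
    w_us = p.eta_u * p.eta_s * p.eta_us * u * s
    w_vs = p.eta_v * p.eta_s * p.eta_vs * v * s
    w_uvs = p.eta_u * p.eta_v * p.eta_s * p.eta_uvs * u * v * s
    denom = 1.0 + w_u + w_v + w_s + w_uv + w_us + w_vs + w_uvs
    p_u = (w_u + w_uv + w_us + w_uvs) / denom
    p_v = (w_v + w_uv + w_vs + w_uvs) / denom
    if u.ndim == 0 and v.ndim == 0 and s.ndim == 0:
        return float(p_u), float(p_v)
    return p_u, p_v


def _denominator(u, v, s, p: ModelParams):
    return 1.0 + p.eta_v * v * (1.0 + p.eta_s * p.eta_vs * s) + p.eta_u * u + p.eta_s * s


def binding_probs(u, v, s, params: ModelParams):
    """Specialized probabilities for blocking inhibition (fast path).

    Equal to :func:`binding_prob_general` with
    ``eta_uv = eta_us = eta_uvs = 0``.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    s = np.asarray(s, dtype=float)
    d = _denominator(u, v, s, params)
    return params.eta_u * u / d, params.eta_v * v * (1.0 + params.eta_s * params.eta_vs * s) / d


def rhs(u, v, s, params: ModelParams):
    """Per-cell time derivatives ``(du/dt, dv/dt)`` of the coupled system.

    Cells interact only through the received signal vector ``s``; the caller
    supplies ``s`` (typically ``s = A @ u`` for a signal kernel ``A``).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    s = np.asarray(s, dtype=float)
    if not (u.shape == v.shape == s.shape):
        raise ValueError(
            f"shape mismatch: u {u.shape}, v {v.shape}, s {s.shape}"
        )
    _check_nonnegative("u", u)
    _check_nonnegative("v", v)
    _check_nonnegative("s", s)
    p_u, p_v = binding_probs(u, v, s, params)
    return params.r_u * p_u - params.gamma_u * u, params.r_v * p_v - params.gamma_v * v


def critical_signal(params: ModelParams) -> float:
    """Signal value ``s*`` at which a single cell's fate tips.

    Below ``s*`` the cell converges to the u+v- state, above it to u-v+.
    May be negative, in which case every nonnegative signal selects u-v+.
    """
    denom = params.r_v * params.gamma_u * params.eta_v * params.eta_s * params.eta_vs
    if denom == 0.0:
        raise ValueError("critical signal undefined: eta_s * eta_vs must be > 0")
    num = params.r_u * params.gamma_v * params.eta_u - params.r_v * params.gamma_u * params.eta_v
    return num / denom


@dataclass(frozen=True)
class SteadyStates:
    """Closed-form single-cell steady states at a given received signal.

    ``u_on``/``v_on`` are the nonzero one-hot states ``(u+, 0)`` and
    ``(0, v+)``; either is ``None`` when its closed form is negative (the
    state does not exist as a concentration at this signal).  ``degenerate``
    flags the measure-zero signal at which the two nonzero branches merge
    into a line of steady states.
    """

    off: tuple
    u_on: tuple | None
    v_on: tuple | None
    degenerate: bool


def steady_states(params: ModelParams, s: float, *, degeneracy_rtol: float = 1e-9) -> SteadyStates:
    """All fate steady states of a single cell at constant signal ``s``."""
    if s < 0:
        raise ValueError("signal must be nonnegative")
    p = params
    u_plus = p.r_u / p.gamma_u - (1.0 + p.eta_s * s) / p.eta_u
    v_plus = p.r_v / p.gamma_v - (1.0 + p.eta_s * s) / (p.eta_v * (1.0 + p.eta_s * p.eta_vs * s))
    s_star = critical_signal(p)
    degenerate = abs(s - s_star) / max(abs(s_star), 1e-300) < degeneracy_rtol
    return SteadyStates(
        off=(0.0, 0.0),
        u_on=(u_plus, 0.0) if u_plus >= 0 else None,
        v_on=(0.0, v_plus) if v_plus >= 0 else None,
        degenerate=degenerate,
    )


def stability_interval(
    params: ModelParams,
    s_min: float | None = None,
    s_max: float | None = None,
) -> StabilityInterval:
    """Interval of ``-delta_eps_u`` guaranteeing a heterogeneous pattern.

    The endpoints derive from the instability conditions of the two
    homogeneous tissue states evaluated at the extreme received signals:

        delta_eps_min = -delta_eps_v + ln(1 + eta_s*eta_vs*s_min) + ln(r_v*gamma_u/(r_u*gamma_v))
        delta_eps_max = -delta_eps_v + ln(1 + eta_s*eta_vs*s_max) + ln(r_v*gamma_u/(r_u*gamma_v))

    Called without explicit signals, the signal bounds ``(0, r_u/gamma_u)``
    of the tissue kernels are used (valid when the steady-state correction
    is small, i.e. ``r_u/gamma_u >> (1 + eta_s*r_u/gamma_u)/eta_u``).
    """
    if s_min is None and s_max is None:
        s_min, s_max = 0.0, params.r_u / params.gamma_u
    if s_min is None or s_max is None:
        raise ValueError("provide both s_min and s_max, or neither")
    if not (0.0 <= s_min <= s_max):
        raise ValueError(f"need 0 <= s_min <= s_max, got ({s_min}, {s_max})")
    p = params
    shift = -p.delta_eps_v + math.log(p.r_v * p.gamma_u / (p.r_u * p.gamma_v))
    c = p.eta_s * p.eta_vs
    return StabilityInterval(
        delta_eps_min=shift + math.log1p(c * s_min),
        delta_eps_max=shift + math.log1p(c * s_max),
        s_min=s_min,
        s_max=s_max,
    )


def exclusion_condition(params: ModelParams) -> bool:
    """True iff the double-negative (0,0) state is unstable at every
    nonnegative signal, i.e. ``eta_v > gamma_v / r_v`` (strict)."""
    return params.eta_v > params.gamma_v / params.r_v


def l_max(params: ModelParams, degree: int) -> int:
    """Largest number of u+v- neighbors a cell tolerates while keeping the
    u+v- fate under averaged nearest-neighbor signaling.

    Obtained by equating the received signal ``(l/degree)*(r_u/gamma_u)`` of
    a cell with ``l`` u+v- neighbors to the critical signal and taking the
    floor; clamped at 0 when ``eta_u < eta_v``.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    p = params
    x = degree * (p.gamma_v / p.r_v) * (p.eta_u - p.eta_v) / (p.eta_v * p.eta_s * p.eta_vs)
    return max(0, math.floor(x))


def jacobian(u, v, kernel, params: ModelParams):
    """Analytic linearization of the coupled system and its leading eigenvalue.

    Assembles the ``2N x 2N`` block matrix

        L = [[ r_u*A_uu - gamma_u*I ,  r_u*A_uv ],
             [ r_v*A_vu             ,  r_v*A_vv - gamma_v*I ]]

    where each block combines the in-cell partial derivatives of the binding
    probabilities with the chain-rule coupling through the signal,
    ``ds/du = A`` (the kernel weight matrix) and ``ds/dv = 0``.

    Parameters
    ----------
    u, v : array (N,)
        State about which to linearize.
    kernel : SignalKernel or array (N, N)
        Signal kernel; its weight matrix supplies ``ds/du``.

    Returns
    -------
    L : ndarray (2N, 2N)
    leading_eigenvalue : complex
        Eigenvalue with largest real part.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    A = np.asarray(getattr(kernel, "weights", kernel), dtype=float)
    n = u.shape[0]
    if v.shape != (n,) or A.shape != (n, n):
        raise ValueError(f"dimension mismatch: u {u.shape}, v {v.shape}, kernel {A.shape}")
    p = params
    s = A @ u
    c = p.eta_s * p.eta_vs
    act = 1.0 + c * s
    d = _denominator(u, v, s, p)
    d2 = d * d
    dpu_du = p.eta_u * (1.0 + p.eta_v * v * act + p.eta_s * s) / d2
    dpu_dv = -p.eta_u * u * p.eta_v * act / d2
    dpv_du = -p.eta_v * v * act * p.eta_u / d2
    dpv_dv = p.eta_v * act * (1.0 + p.eta_u * u + p.eta_s * s) / d2
    dpu_ds = -p.eta_u * p.eta_s * u * (1.0 + p.eta_v * p.eta_vs * v) / d2
    dpv_ds = p.eta_v * p.eta_s * v * (p.eta_vs + p.eta_u * p.eta_vs * u - 1.0) / d2

    A_uu = np.diag(dpu_du) + dpu_ds[:, None] * A
    A_uv = np.diag(dpu_dv)
    A_vu = np.diag(dpv_du) + dpv_ds[:, None] * A
    A_vv = np.diag(dpv_dv)

    eye = np.eye(n)
    L = np.block(
        [
            [p.r_u * A_uu - p.gamma_u * eye, p.r_u * A_uv],
            [p.r_v * A_vu, p.r_v * A_vv - p.gamma_v * eye],
        ]
    )
    eigvals = np.linalg.eigvals(L)
    leading = eigvals[np.argmax(eigvals.real)]
    return L, leading
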