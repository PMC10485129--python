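"""Steady-state simulation of the coupled fate-switch ODEs on a tissue.

The reference integrator is the explicit Euler method with the received
signal recomputed from the current u field at every step (instantaneous
signal response).  A run counts as converged when the max-norm of the
derivative vector drops below a tolerance.  Fates are then read off by
dominance of u over v.

Sweeps and bisections integrate many independent runs; the inner loop is
compiled with numba when available (a pure-numpy implementation with
identical update order serves as fallback and cross-check).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from .grn import stability_interval
from .params import ModelParams, StabilityInterval
from .signaling import SignalKernel
from .tissue import CellGraph

try:  # optional acceleration
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

__all__ = [
    "FATE_U",
    "FATE_V",
    "UNDECIDED",
    "IntegrationError",
    "TissueState",
    "SweepResult",
    "BisectionResult",
    "random_initial_state",
    "simulate",
    "classify",
    "proportion_sweep",
    "bisect_ratio",
]

FATE_U = "u+v-"
FATE_V = "u-v+"
UNDECIDED = "undecided"


class IntegrationError(RuntimeError):
    pass


@dataclass
class TissueState:
    """Per-cell state of a (possibly converged) simulation."""

    u: np.ndarray
    v: np.ndarray
    s: np.ndarray
    t: float
    converged: bool
    steps: int = 0
    n_clipped: int = 0
    labels: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.u.shape[0]


@dataclass
class SweepResult:
    """Fate proportions along an equidistant grid of ``-delta_eps_u``."""

    delta_eps_values: np.ndarray
    prop_u: np.ndarray
    prop_v: np.ndarray
    converged: np.ndarray
    steps: np.ndarray
    seed: int
    interval: StabilityInterval
    states: list[TissueState] = field(repr=False, default_factory=list)


@dataclass
class BisectionResult:
    """Outcome of bisecting ``-delta_eps_u`` for a target fate split."""

    delta_eps_u: float
    state: TissueState
    counts: tuple[int, int]  # (u+v-, u-v+)
    target: tuple[int, int]
    exact: bool
    iterations: int
    trace: list[tuple[float, int]] = field(repr=False, default_factory=list)


def default_dt(params: ModelParams) -> float:
    """Default Euler step, one hundredth of the fastest decay time."""
    return 0.01 * min(1.0 / params.gamma_u, 1.0 / params.gamma_v)


def random_initial_state(
    n: int, params: ModelParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Independent per-cell uniform draws in ``[0.9, 1.1] * c0`` for u and v,
    with ``c0 = 1e-3 * r_u/gamma_u``.

    The all-zero state is a fixed point, so strictly positive symmetric
    noise far below the steady-state scale lets the pattern self-organize.
    """
    c0 = 1e-3 * params.r_u / params.gamma_u
    u0 = rng.uniform(0.9 * c0, 1.1 * c0, size=n)
    v0 = rng.uniform(0.9 * c0, 1.1 * c0, size=n)
    return u0, v0


# --------------------------------------------------------------------------
# integration backends: independent runs (rows), per-run eta_u


def _integrate_numpy(weights, p, eta_u_rows, u, v, dt, tol, max_steps):
    c = p.eta_s * p.eta_vs
    n_runs = u.shape[0]
    eta_u = eta_u_rows[:, None]
    steps = np.zeros(n_runs, dtype=np.int64)
    converged = np.zeros(n_runs, dtype=bool)
    active = np.arange(n_runs)
    ua, va, ea = u[active], v[active], eta_u[active]
    n_clipped = 0
    step = 0
    wt = weights.T.copy()
    while step < max_steps and active.size:
        s = ua @ wt
        act = 1.0 + c * s
        den = 1.0 + p.eta_v * va * act + ea * ua + p.eta_s * s
        du = p.r_u * (ea * ua) / den - p.gamma_u * ua
        dv = p.r_v * (p.eta_v * va * act) / den - p.gamma_v * va
        ua += dt * du
        va += dt * dv
        neg = (ua < 0.0) | (va < 0.0)
        if neg.any():
            n_clipped += int(neg.sum())
            np.maximum(ua, 0.0, out=ua)
            np.maximum(va, 0.0, out=va)
        # flush to zero above the subnormal range (see numba kernel)
        ua[ua < 1e-30] = 0.0
        va[va < 1e-30] = 0.0
        step += 1
        resid = np.maximum(np.abs(du).max(axis=1), np.abs(dv).max(axis=1))
        if not np.all(np.isfinite(resid)):
            raise IntegrationError(f"non-finite state at step {step}")
        done = resid < tol
        if done.any():
            idx = active[done]
            u[idx], v[idx] = ua[done], va[done]
            steps[idx] = step
            converged[idx] = True
            keep = ~done
            active, ua, va, ea = active[keep], ua[keep], va[keep], ea[keep]
    if active.size:
        u[active], v[active] = ua, va
        steps[active] = step
    return u, v, steps, converged, n_clipped


if HAVE_NUMBA:

    @njit(cache=True)
    def _euler_runs_dense(
        weights,
        eta_u_rows,
        r_u,
        gamma_u,
        r_v,
        gamma_v,
        eta_v,
        eta_s,
        c,
        dt,
        tol,
        max_steps,
        u,
        v,
        steps,
        converged,
        clips,
    ):  # pragma: no cover - exercised via _integrate_runs
        n_runs, n = u.shape
        du = np.empty(n)
        dv = np.empty(n)
        for b in range(n_runs):
            eu = eta_u_rows[b]
            ub = u[b].copy()
            vb = v[b].copy()
            step = 0
            ok = False
            bad = False
            while step < max_steps:
                s = np.dot(weights, ub)
                maxres = 0.0
                for i in range(n):
                    act = 1.0 + c * s[i]
                    den = 1.0 + eta_v * vb[i] * act + eu * ub[i] + eta_s * s[i]
                    dui = r_u * eu * ub[i] / den - gamma_u * ub[i]
                    dvi = r_v * eta_v * vb[i] * act / den - gamma_v * vb[i]
                    du[i] = dui
                    dv[i] = dvi
                    a = abs(dui)
                    if a > maxres:
                        maxres = a
                    a = abs(dvi)
                    if a > maxres:
                        maxres = a
                for i in range(n):
                    un = ub[i] + dt * du[i]
                    vn = vb[i] + dt * dv[i]
                    if un < 0.0:
                        un = 0.0
                        clips[b] += 1
                    if vn < 0.0:
                        vn = 0.0
                        clips[b] += 1
                    # flush decaying concentrations to zero well above the
                    # subnormal range: arithmetic on subnormals is 10-100x
                    # slower and values this small are physically void
                    if un < 1e-30:
                        un = 0.0
                    if vn < 1e-30:
                        vn = 0.0
                    ub[i] = un
                    vb[i] = vn
                step += 1
                if not np.isfinite(maxres):
                    bad = True
                    break
                if maxres < tol:
                    ok = True
                    break
            u[b] = ub
            v[b] = vb
            steps[b] = step
            converged[b] = ok
            if bad:
                steps[b] = -step
        return


def _integrate_runs(
    weights: np.ndarray,
    params: ModelParams,
    eta_u_rows: np.ndarray,
    u0: np.ndarray,
    v0: np.ndarray,
    dt: float,
    tol: float,
    max_steps: int,
    use_numba: bool | None = None,
):
    """Euler-integrate independent runs (rows of ``u0``/``v0``) to steady
    state, run ``b`` using ``eta_u_rows[b]`` as its u auto-activation weight.

    Each run stops (is frozen) the step it first meets the convergence
    criterion, so its trajectory equals a solo integration.  Returns final
    (u, v), per-run step counts, convergence flags, and the number of
    clipped (negative-undershoot) cell updates.
    """
    u = np.array(u0, dtype=float)
    v = np.array(v0, dtype=float)
    eta_u_rows = np.asarray(eta_u_rows, dtype=float)
    p = params
    if use_numba is None:
        use_numba = HAVE_NUMBA
    if not use_numba:
        return _integrate_numpy(weights, p, eta_u_rows, u, v, dt, tol, max_steps)
    n_runs = u.shape[0]
    steps = np.zeros(n_runs, dtype=np.int64)
    converged = np.zeros(n_runs, dtype=bool)
    clips = np.zeros(n_runs, dtype=np.int64)
    common = (
        eta_u_rows,
        p.r_u,
        p.gamma_u,
        p.r_v,
        p.gamma_v,
        p.eta_v,
        p.eta_s,
        p.eta_s * p.eta_vs,
        dt,
        tol,
        max_steps,
        u,
        v,
        steps,
        converged,
        clips,
    )
    _euler_runs_dense(np.ascontiguousarray(weights, dtype=np.float64), *common)
    if np.any(steps < 0):
        bad = np.nonzero(steps < 0)[0]
        raise IntegrationError(
            f"non-finite state at step {int(-steps[bad[0]])} (runs {bad.tolist()})"
        )
    return u, v, steps, converged, int(clips.sum())


def simulate(
    graph: CellGraph,
    kernel: SignalKernel,
    params: ModelParams,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    dt: float | None = None,
    tol: float = 1e-8,
    max_steps: int = 10_000_000,
    seed: int = 0,
) -> TissueState:
    """Integrate the tissue to steady state with explicit Euler.

    ``init`` is a pair of nonnegative (N,) arrays ``(u0, v0)``; when omitted
    it is drawn from :func:`random_initial_state` with ``seed``.  The signal
    ``s = A u`` is recomputed from the current u field at every step.  If
    ``max_steps`` is exhausted the state is returned with
    ``converged=False`` rather than raising.
    """
    n = graph.n
    if kernel.n != n:
        raise ValueError(f"kernel dimension {kernel.n} != graph dimension {n}")
    if dt is None:
        dt = default_dt(params)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if init is None:
        init = random_initial_state(n, params, np.random.default_rng(seed))
    u0, v0 = (np.asarray(x, dtype=float) for x in init)
    if u0.shape != (n,) or v0.shape != (n,):
        raise ValueError("init arrays must have shape (N,)")
    if np.any(u0 < 0) or np.any(v0 < 0):
        raise ValueError("initial concentrations must be nonnegative")
    u, v, steps, converged, n_clipped = _integrate_runs(
        kernel.weights, params, np.array([params.eta_u]), u0[None, :], v0[None, :],
        dt, tol, max_steps,
    )
    if n_clipped:
        warnings.warn(f"{n_clipped} negative undershoots clipped to 0", stacklevel=2)
    return TissueState(
        u=u[0],
        v=v[0],
        s=kernel.apply(u[0]),
        t=float(steps[0]) * dt,
        converged=bool(converged[0]),
        steps=int(steps[0]),
        n_clipped=n_clipped,
    )


def classify(state: TissueState, ratio_threshold: float = 1.0) -> np.ndarray:
    """Label each cell by fate dominance: u+v- iff ``u > v * ratio_threshold``.

    Near-ties (relative difference below 1e-6) are labeled undecided.
    Refuses non-converged states; stores the labels on ``state``.
    """
    if not state.converged:
        raise ValueError("refusing to classify a non-converged state")
    lhs = state.u
    rhs = state.v * ratio_threshold
    scale = np.maximum(np.maximum(np.abs(lhs), np.abs(rhs)), 1e-300)
    tie = np.abs(lhs - rhs) / scale < 1e-6
    labels = np.where(lhs > rhs, FATE_U, FATE_V).astype(object)
    labels[tie] = UNDECIDED
    state.labels = labels
    return labels


def _count_fate_u(labels: np.ndarray) -> int:
    return int(np.sum(labels == FATE_U))


def proportion_sweep(
    graph: CellGraph,
    kernel: SignalKernel,
    params: ModelParams,
    n_grid: int = 20,
    seed: int = 0,
    *,
    interval: StabilityInterval | None = None,
    dt: float | None = None,
    tol: float = 1e-8,
    max_steps: int = 10_000_000,
) -> SweepResult:
    """Fate proportions over ``n_grid`` equidistant ``-delta_eps_u`` values
    spanning the heterogeneity interval (endpoints included).

    Each grid point is a fresh simulation from its own seeded initial
    condition; all runs are integrated as one batch.  Non-converged runs
    are reported through the ``converged`` array, never dropped.
    """
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    if interval is None:
        interval = stability_interval(params)
    grid = interval.grid(n_grid)
    n = graph.n
    u0 = np.empty((n_grid, n))
    v0 = np.empty((n_grid, n))
    for k in range(n_grid):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), k]))
        u0[k], v0[k] = random_initial_state(n, params, rng)
    if dt is None:
        dt = default_dt(params)
    u, v, steps, converged, _ = _integrate_runs(
        kernel.weights, params, np.exp(grid), u0, v0, dt, tol, max_steps
    )
    prop_u = np.empty(n_grid)
    prop_v = np.empty(n_grid)
    states: list[TissueState] = []
    for k in range(n_grid):
        st = TissueState(
            u=u[k],
            v=v[k],
            s=kernel.apply(u[k]),
            t=float(steps[k]) * dt,
            converged=bool(converged[k]),
            steps=int(steps[k]),
        )
        if st.converged:
            labels = classify(st)
            prop_u[k] = _count_fate_u(labels) / n
            prop_v[k] = int(np.sum(labels == FATE_V)) / n
        else:
            prop_u[k] = prop_v[k] = np.nan
        states.append(st)
    return SweepResult(
        delta_eps_values=grid,
        prop_u=prop_u,
        prop_v=prop_v,
        converged=converged,
        steps=steps,
        seed=seed,
        interval=interval,
        states=states,
    )


def bisect_ratio(
    graph: CellGraph,
    kernel: SignalKernel,
    params: ModelParams,
    target_counts: tuple[int, int],
    max_iter: int = 40,
    seed: int = 0,
    *,
    interval: StabilityInterval | None = None,
    dt: float | None = None,
    tol: float = 1e-8,
    max_steps: int = 2_000_000,
) -> BisectionResult:
    """Bisect ``-delta_eps_u`` over the heterogeneity interval for a target
    fate split ``(count_u, count_v)``.

    Every evaluation is a full steady-state simulation from the same seeded
    initial condition; the u+v- count is (up to discrete jumps) increasing
    in ``-delta_eps_u``, which bisection exploits.  Stops when the counts
    match the target exactly or the bracket falls below resolution; in the
    latter case the nearest achieved split is returned with ``exact=False``.
    """
    n = graph.n
    target_u, target_v = target_counts
    if target_u + target_v != n:
        raise ValueError(f"target counts {target_counts} must sum to N={n}")
    if interval is None:
        interval = stability_interval(params)
    init = random_initial_state(n, params, np.random.default_rng(seed))

    def evaluate(x: float) -> tuple[int, TissueState]:
        st = simulate(
            graph,
            kernel,
            params.with_delta_eps_u(x),
            init=init,
            dt=dt,
            tol=tol,
            max_steps=max_steps,
        )
        if st.converged:
            return _count_fate_u(classify(st)), st
        # near a count transition the slowest cell relaxes arbitrarily
        # slowly; steer the bracket by raw dominance, but never return the
        # unconverged state as a result
        return int(np.sum(st.u > st.v)), st

    lo, hi = interval.delta_eps_min, interval.delta_eps_max
    trace: list[tuple[float, int]] = []
    best: tuple[int, float, TissueState] | None = None
    iterations = 0
    for iterations in range(1, max_iter + 1):
        mid = 0.5 * (lo + hi)
        count, st = evaluate(mid)
        trace.append((mid, count))
        miss = abs(count - target_u)
        if st.converged and (best is None or miss < best[0]):
            best = (miss, mid, st)
        if count == target_u and st.converged:
            break
        if count < target_u:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12 * interval.width:
            break
    if best is None:
        raise IntegrationError(
            "no bisection evaluation converged; raise max_steps or loosen tol"
        )
    miss, x_best, st_best = best
    return BisectionResult(
        delta_eps_u=x_best,
        state=st_best,
        counts=(_count_fate_u(st_best.labels), int(np.sum(st_best.labels == FATE_V))),
        target=(target_u, target_v),
        exact=miss == 0,
        iterations=iterations,
        trace=trace,
    )
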