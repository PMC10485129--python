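# Methods

## Model

Each cell carries two antagonistic, auto-activating transcription factors
with nondimensional concentrations `u` and `v`, plus a received
extracellular signal `s` that inhibits `u` and activates `v`.  Production
is proportional to the probability that the factor is bound near its own
promoter; that probability follows from Boltzmann statistics over the
binding microstates of `u`, `v` and `s`.  Each microstate's weight is the
product of the energy coefficients of its constituents, with
`eta = exp(-delta_eps)` for binding energy difference `delta_eps` (in
thermal units).  Three interaction assumptions specialize the general
eight-state partition sum:

* blocking mutual inhibition — `u` and `v` cannot be bound together
  (`eta_uv = 0`), likewise the `u,s` and `u,v,s` combinations
  (`eta_us = eta_uvs = 0`);
* cooperative activation of `v` by the signal, `eta_vs >= 1`;
* identical energy coefficients on both promoters.

This yields, per cell `i`,

    du_i/dt = r_u * eta_u u_i / D_i                            - gamma_u u_i
    dv_i/dt = r_v * eta_v v_i (1 + eta_s eta_vs s_i) / D_i     - gamma_v v_i
    D_i     = 1 + eta_v v_i (1 + eta_s eta_vs s_i) + eta_u u_i + eta_s s_i

Cells are coupled only through `s = A u`, where the kernel matrix `A` is
either the averaged nearest-neighbor kernel (row-normalized adjacency) or
the dispersion kernel `A_ij = a * q**(d_ij - 1)` with graph distance
`d_ij`, dispersion `q in [0, 1]`, and `a` normalizing the largest row sum
to 1.  `q = 0` reduces to contact-only signaling (`0**0 = 1` convention),
`q = 1` to a uniform all-to-all signal.

### Steady states and stability

A single cell at constant signal has the steady states `(0, 0)`,
`(u+, 0)` and `(0, v+)` with

    u+ = r_u/gamma_u - (1 + eta_s s)/eta_u
    v+ = r_v/gamma_v - (1 + eta_s s)/(eta_v (1 + eta_s eta_vs s))

and a degenerate line of equilibria exactly at the critical signal

    s* = (r_u gamma_v eta_u - r_v gamma_u eta_v) / (r_v gamma_u eta_v eta_s eta_vs),

which separates the u+v- basin (s < s*) from the u-v+ basin (s > s*).
`eta_v > gamma_v/r_v` makes the double-negative state unstable at every
nonnegative signal.  Linearizing the tissue system about the two
homogeneous states and requiring both to be unstable gives the
heterogeneity interval for the u auto-activation strength,

    -delta_eps_v + ln(1 + eta_s eta_vs min_i s_i) + ln(r_v gamma_u / (r_u gamma_v))
        < -delta_eps_u <
    -delta_eps_v + ln(1 + eta_s eta_vs max_i s_i) + ln(r_v gamma_u / (r_u gamma_v)).

Inside this interval every converged tissue carries both fates.  Because
`u` vanishes in u-v+ cells and is bounded by `r_u/gamma_u` in u+v- cells,
both kernels give `min s = 0` and `max s ~ r_u/gamma_u` (to the correction
`(1 + eta_s r_u/gamma_u)/eta_u`), which is how `stability_interval`
evaluates the endpoints when no explicit signal bounds are passed.

The analytic Jacobian assembles the 2N×2N block linearization from the
directly differentiated binding probabilities, chain-ruled through the
kernel matrix (`ds/du = A`, `ds/dv = 0`); a central finite-difference
oracle test pins every entry down to 1e-5 relative error.

## Default parameters

Three anchor constraints fix most of the default set: `r_u/gamma_u =
r_v/gamma_v = 0.1`; lower interval endpoint `-delta_eps_u = 6` (with equal
rate ratios this pins `eta_v = e^6 ≈ 403.43`); upper endpoint `eta_u =
2606.08`, which fixes `eta_s * eta_vs ≈ 54.60`.  We take `r_u = r_v = 1`,
`gamma_u = gamma_v = 10` (so the decay time is 0.1), split the product as
`eta_vs = 20`, `eta_s ≈ 2.73` (only the product is constrained; the split
keeps the steady-state correction `(1 + eta_s r_u/gamma_u)/eta_u <=
0.0043` across the whole interval), and default `eta_u` to the interval
midpoint `exp(6.93)`.  With these values the critical signal is
`s* ≈ 0.028`, inside the attainable signal range `(0, 0.1)`.

## Tissue generation

The disc tissue emulates an organoid cross-section: `n` equal cells packed
irregularly in a disc.  Seeded best-candidate blue-noise sampling is
followed by 80 iterations of Lloyd (centroidal Voronoi) relaxation, with
points mirrored across the disc boundary so every Voronoi region is
bounded.  Contacts are Delaunay edges no longer than `2 * radius`, with
the common radius set to half the median nearest-neighbor spacing times a
contact factor of 1.4.  The generous factor reflects a measured property
of relaxed irregular packings: Delaunay-neighbor center distances spread
up to ~1.3x the median nearest-neighbor spacing, so a factor near 1 would
disconnect genuinely touching cells (measured mean degree 1.6–3.7 at a
1.05 factor).  At the default `n = 177` the calibration reproduces the
target contact statistics: mean degree 5.42 over 20 seeds (target band
5.2–5.8), all convex-hull cells with 3–4 contacts, bulk median 6, and a
connected graph on every seed tried; disconnection triggers regeneration
from a derived seed.

The hexagonal lattice fixture supports the packing-limit analysis
(periodic wrapping requires an even row count; tiny tori are deduplicated
to simple-graph semantics), and the line fixture gives hand-checkable
kernels and distances.

## Numerics

* Integrator: explicit Euler with the signal recomputed from the current
  `u` every step — the signal is an instantaneous response, not a dynamic
  species.  Default step `dt = 1e-2 * min(1/gamma_u, 1/gamma_v)` (1e-3 in
  the default units): two orders below the fastest decay time, and well
  inside the stability region of every decaying mode encountered.
* Convergence: max-norm of the full derivative vector below `tol = 1e-8`.
  Cells whose received signal lands very close to `s*` relax with an
  arbitrarily small rate, so step counts vary from ~1e5 (typical) to a few
  1e6 (runs adjacent to a fate-count transition); `simulate` caps at 1e7
  steps and returns an explicit non-converged flag rather than raising.
* Negative undershoots are clipped at zero and counted; at the default
  step none occur.  Concentrations below 1e-30 are flushed to exact zero:
  exponentially decaying off-fate levels otherwise drift into the
  subnormal floating-point range, where arithmetic is 10–100x slower,
  while values that small are physically void (every relevant scale —
  initial noise 1e-4, tolerance-limited residuals ~1e-9 — is dozens of
  orders of magnitude larger).  Steady states are unchanged.
* Initial conditions: per-cell independent uniform draws in
  `[0.9, 1.1] * c0`, `c0 = 1e-3 * r_u/gamma_u`, for both factors.  The
  origin is a fixed point, so strictly positive symmetric noise far below
  the steady-state scale lets the pattern self-organize without biasing
  either fate.
* Sweeps integrate all grid runs as one batch (runs are independent rows);
  each run is frozen the step it first converges, so its trajectory equals
  a solo integration.  The inner loop is numba-compiled with a dense
  BLAS matrix-vector product; a pure-numpy fallback with identical update
  order exists and is cross-checked in the tests.
* Bisection for a target fate split evaluates each candidate
  `-delta_eps_u` by a fresh steady-state run from one fixed seeded initial
  condition.  Evaluations default to a 2e6-step cap: runs inside a
  fate-count plateau converge well under it, while runs adjacent to a
  count transition (critically slow) are used only to steer the bracket,
  by raw `u > v` dominance, and are never returned as results.  Only a
  converged run that hits the target exactly terminates the search early.

## Pattern quantification

Pair correlation functions are computed over ordered pairs at each graph
distance `k`, normalized by the without-replacement probability of drawing
two cells of the type; the normalization makes uniformly random labelings
average to 1 at every `k` exactly in expectation (the hypergeometric mean
of the same-type pair count at any fixed distance equals
`|S_k| * p_same`).  Distances with no pairs are omitted; both types need
at least two members.  The packing-limit helper computes the exact maximum
independent set by branch-and-bound over vertex bitmasks (exhaustive,
limited to <= 40 cells).

## Classification

Converged cells are labeled by dominance (`u > v`), with relative ties
below 1e-6 flagged undecided.  Converged heterogeneous states are near
one-hot (the off-factor is at most ~`tol`/rate), so labels are insensitive
to the dominance threshold over at least [0.5, 2]; a test asserts this.

## What the synthetic tissues do and do not capture

The generator reproduces the contact statistics of a round epithelial
cross-section (six-ish contacts in the bulk, three to four at the rim) and
the graph-distance structure the signaling kernels consume.  It does not
model cell growth, division, movement, apoptosis, heterogeneous cell
sizes, or three-dimensional geometry; passing tests therefore demonstrate
the signaling-driven patterning mechanism on static, equal-radius 2-D
tissues, not its interaction with tissue remodeling in real embryos or
organoids.

## Problem sizes

The shipped analyses use the 177-cell reference tissue (the scale of an
organoid cross-section), 20-point parameter sweeps over the heterogeneity
interval, 10 tissue seeds for proportion statistics, 1000 random-labeling
replicates for the PCF null (4000 in the per-distance test, where the
sparsest long-range distance dominates the Monte Carlo error), and an
18-cell torus for the exhaustive packing limit.

## Known limitations

* Critical slowing near fate-count transitions makes wall time seed- and
  parameter-dependent; the bisection cap above is the pragmatic answer.
* The dispersion kernel's normalization is recomputed per kernel, not per
  sweep; tissues are static here, so the distinction never bites.
* `q = 1` on a disconnected tissue is rejected (the uniform kernel has no
  consistent normalization there); `q < 1` assigns unreachable pairs zero
  weight.
* The stability interval endpoints computed from the `(0, r_u/gamma_u)`
  signal bounds are approximations; the exact homogeneous-state
  eigenvalues shift the upper endpoint by about the documented correction
  term (tested to a few percent of the interval width).
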