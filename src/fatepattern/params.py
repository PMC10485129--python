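"""Model parameters for the two-factor cell-fate switch.

The gene-regulatory network couples two antagonistic, auto-activating
transcription factors ``u`` and ``v`` to an extracellular signal ``s`` that
inhibits ``u`` and cooperatively activates ``v``.  Binding configurations
carry statistical (Boltzmann) weights: each energy coefficient ``eta`` is
related to a binding energy difference by ``eta = exp(-delta_eps)``, so
activation corresponds to ``delta_eps < 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

__all__ = [
    "ModelParams",
    "StabilityInterval",
    "default_params",
    "DEFAULT_ETA_S_ETA_VS",
]

#: Production/decay ratio shared by both factors in the default parameter set.
DEFAULT_PRODUCTION_DECAY_RATIO = 0.1

#: Product eta_s * eta_vs of the default set.  Calibrated so that, with the
#: maximal signal r_u/gamma_u = 0.1, the heterogeneity interval for the
#: auto-activation weight of u becomes eta_u in (403.43, 2606.08), i.e.
#: -delta_eps_u in (6, 7.87).
DEFAULT_ETA_S_ETA_VS = (2606.08 / math.exp(6.0) - 1.0) / DEFAULT_PRODUCTION_DECAY_RATIO


@dataclass(frozen=True)
class ModelParams:
    """Rate and energy-coefficient parameters of the regulatory network.

    Parameters
    ----------
    r_u, r_v : float
        Production rates (concentration per unit time), strictly positive.
    gamma_u, gamma_v : float
        First-order decay rates (1/time), strictly positive.
    eta_u, eta_v, eta_s : float
        Energy coefficients (dimensionless statistical weights) for binding
        of u, v and the signal; ``eta = exp(-delta_eps)``.
    eta_vs : float
        Cooperative signal/v activation coefficient, >= 1.
    eta_uv, eta_us, eta_uvs : float
        General interaction coefficients.  The specialized fate-switch model
        uses blocking inhibition, i.e. all three equal 0 (the default).
    """

    r_u: float
    r_v: float
    gamma_u: float
    gamma_v: float
    eta_u: float
    eta_v: float
    eta_s: float
    eta_vs: float = 1.0
    eta_uv: float = 0.0
    eta_us: float = 0.0
    eta_uvs: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r_u", "r_v", "gamma_u", "gamma_v"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        for name in ("eta_u", "eta_v", "eta_s"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if not (math.isfinite(self.eta_vs) and self.eta_vs >= 1.0):
            raise ValueError(
                f"eta_vs must be >= 1 (signal activates v), got {self.eta_vs!r}"
            )
        for name in ("eta_uv", "eta_us", "eta_uvs"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value >= 0):
                raise ValueError(f"{name} must be nonnegative, got {value!r}")

    # -- energy-difference view -------------------------------------------
    @property
    def delta_eps_u(self) -> float:
        """Binding energy difference for u, ``-ln(eta_u)``."""
        return -math.log(self.eta_u)

    @property
    def delta_eps_v(self) -> float:
        return -math.log(self.eta_v)

    @property
    def delta_eps_s(self) -> float:
        return -math.log(self.eta_s)

    @property
    def delta_eps_vs(self) -> float:
        return -math.log(self.eta_vs)

    @classmethod
    def from_energies(
        cls,
        *,
        r_u: float,
        r_v: float,
        gamma_u: float,
        gamma_v: float,
        delta_eps_u: float,
        delta_eps_v: float,
        delta_eps_s: float,
        delta_eps_vs: float = 0.0,
        eta_uv: float = 0.0,
        eta_us: float = 0.0,
        eta_uvs: float = 0.0,
    ) -> "ModelParams":
        """Construct from binding energy differences, ``eta = exp(-delta_eps)``."""
        return cls(
            r_u=r_u,
            r_v=r_v,
            gamma_u=gamma_u,
            gamma_v=gamma_v,
            eta_u=math.exp(-delta_eps_u),
            eta_v=math.exp(-delta_eps_v),
            eta_s=math.exp(-delta_eps_s),
            eta_vs=math.exp(-delta_eps_vs),
            eta_uv=eta_uv,
            eta_us=eta_us,
            eta_uvs=eta_uvs,
        )

    def with_delta_eps_u(self, minus_delta_eps_u: float) -> "ModelParams":
        """Copy with the u auto-activation strength set via ``-delta_eps_u``."""
        return replace(self, eta_u=math.exp(minus_delta_eps_u))

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class StabilityInterval:
    """Interval of ``-delta_eps_u`` in which both homogeneous tissue states
    are linearly unstable, guaranteeing a heterogeneous (two-type) pattern.

    ``delta_eps_min`` is set by the minimal received signal (instability of
    the homogeneous u-v+ state), ``delta_eps_max`` by the maximal one
    (instability of the homogeneous u+v- state).
    """

    delta_eps_min: float
    delta_eps_max: float
    s_min: float
    s_max: float

    @property
    def width(self) -> float:
        return self.delta_eps_max - self.delta_eps_min

    @property
    def eta_u_min(self) -> float:
        """Lower bound on eta_u, ``exp(delta_eps_min)``."""
        return math.exp(self.delta_eps_min)

    @property
    def eta_u_max(self) -> float:
        return math.exp(self.delta_eps_max)

    def grid(self, n: int = 20):
        """``n`` equidistant ``-delta_eps_u`` values spanning the interval,
        endpoints included."""
        import numpy as np

        if n < 2:
            raise ValueError("grid needs at least 2 points")
        return np.linspace(self.delta_eps_min, self.delta_eps_max, n)


def default_params() -> ModelParams:
    """Default parameter set of the package.

    Calibrated against three constraints: production/decay ratios
    ``r_u/gamma_u = r_v/gamma_v = 0.1``; lower heterogeneity bound
    ``-delta_eps_u = 6`` (so ``eta_v = e^6 ≈ 403.43`` with equal rate
    ratios); and upper bound ``eta_u = 2606.08``, fixing
    ``eta_s*eta_vs ≈ 54.6``.  The split of the product into ``eta_vs = 20``
    and ``eta_s ≈ 2.73`` keeps the steady-state correction
    ``(1 + eta_s*r_u/gamma_u)/eta_u`` below 0.0043 on the whole interval.
    ``eta_u`` defaults to the interval midpoint ``exp(6.93)``.
    """
    eta_vs = 20.0
    interval_mid = (6.0 + math.log(2606.08)) / 2.0
    return ModelParams(
        r_u=1.0,
        r_v=1.0,
        gamma_u=10.0,
        gamma_v=10.0,
        eta_u=math.exp(interval_mid),
        eta_v=math.exp(6.0),
        eta_s=DEFAULT_ETA_S_ETA_VS / eta_vs,
        eta_vs=eta_vs,
    )
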