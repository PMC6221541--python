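"""Clamped-linear activator-inhibitor kinetics and Turing-instability analysis.

The reaction terms are linear in the activator ``u`` and inhibitor ``v`` but
truncated below at 0 and above at a maximum net production rate:

    F(u, v) = clamp(a_u*u + b_u*v + c_u, 0, F_max)
    G(u, v) = clamp(a_v*u + b_v*v + c_v, 0, G_max)

Coupled to constitutive degradation (d_u, d_v) and Fickian diffusion
(D_u, D_v), these kinetics support diffusion-driven (Turing) instability of
the homogeneous steady state when the inhibitor diffuses sufficiently faster
than the activator.  This module owns the parameter container, the
homogeneous steady state, and the linear-stability validator; the PDE
integration lives in :mod:`denticle_rd.grid_solver`.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np

__all__ = [
    "KineticParams",
    "SteadyStateReport",
    "DegenerateParametersError",
    "ClampedSteadyStateError",
    "catshark_params",
    "reaction_F",
    "reaction_G",
    "steady_state",
    "turing_check",
    "growth_rate",
]


class DegenerateParametersError(ValueError):
    """The homogeneous linear system has no unique steady state."""


class ClampedSteadyStateError(ValueError):
    """The steady state sits on a clamp boundary; linearization is invalid."""


@dataclass(frozen=True)
class KineticParams:
    """The twelve reaction/diffusion constants of one species pair.

    ``a_*``, ``b_*``, ``c_*`` are the linear production coefficients of the
    activator (``_u``) and inhibitor (``_v``) equations; ``F_max``/``G_max``
    the production ceilings; ``d_*`` the constitutive degradation rates
    (per unit time); ``D_*`` the diffusion coefficients (area per unit time).
    Inhibition of the activator by the inhibitor corresponds to ``b_u <= 0``.
    """

    a_u: float
    b_u: float
    c_u: float
    F_max: float
    d_u: float
    D_u: float
    a_v: float
    b_v: float
    c_v: float
    G_max: float
    d_v: float
    D_v: float

    def __post_init__(self) -> None:
        for name in ("F_max", "G_max", "d_u", "d_v", "D_u", "D_v"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    def to_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "KineticParams":
        return cls(**{k: float(v) for k, v in d.items()})

    def replace(self, **changes: float) -> "KineticParams":
        d = self.to_dict()
        d.update(changes)
        return KineticParams.from_dict(d)


def catshark_params() -> KineticParams:
    """Parameter set tuned for catshark-like (dense) denticle patterning."""
    return KineticParams(
        a_u=0.08, b_u=-0.08, c_u=0.04, F_max=0.2, d_u=0.03, D_u=0.02,
        a_v=0.16, b_v=0.0, c_v=-0.05, G_max=0.5, d_v=0.08, D_v=0.6,
    )


def reaction_F(u, v, p: KineticParams):
    """Activator net production, clamped to [0, F_max].

    Total on all real inputs: values whose raw linear expression falls
    outside the interval are clamped by the same exact piecewise rule.
    Accepts scalars or arrays (broadcast).
    """
    return np.clip(p.a_u * u + p.b_u * v + p.c_u, 0.0, p.F_max)


def reaction_G(u, v, p: KineticParams):
    """Inhibitor net production, clamped to [0, G_max]."""
    return np.clip(p.a_v * u + p.b_v * v + p.c_v, 0.0, p.G_max)


@dataclass
class SteadyStateReport:
    """Homogeneous steady state and linear-stability verdict.

    ``jacobian`` is the 2x2 matrix of the linearized reaction-minus-
    degradation kinetics at the steady state, using the *unclamped*
    production expressions (valid only when ``clamps_inactive``).
    ``k2_range`` is the open interval of squared wavenumbers with positive
    linear growth rate; it is ``None`` exactly when ``turing_unstable`` is
    false.
    """

    u_star: float
    v_star: float
    clamps_inactive: bool
    jacobian: np.ndarray = field(repr=False)
    trace: float = 0.0
    determinant: float = 0.0
    stable_without_diffusion: bool = False
    turing_unstable: bool = False
    k2_range: tuple[float, float] | None = None


def steady_state(p: KineticParams) -> SteadyStateReport:
    """Solve for the spatially homogeneous fixed point.

    With the clamps inactive, the fixed point solves the linear system

        (a_u - d_u) u + b_u v + c_u = 0
        a_v u + (b_v - d_v) v + c_v = 0.

    The report's ``clamps_inactive`` flag records whether both raw
    production expressions lie strictly inside (0, F_max) and (0, G_max)
    at the solution; when they do not, the linear solution is not a fixed
    point of the clamped system and downstream analysis refuses it.

    Raises
    ------
    DegenerateParametersError
        If (a_u - d_u)(b_v - d_v) = b_u * a_v (singular system).
    """
    j11 = p.a_u - p.d_u
    j12 = p.b_u
    j21 = p.a_v
    j22 = p.b_v - p.d_v
    det = j11 * j22 - j12 * j21
    if det == 0.0:
        raise DegenerateParametersError(
            "homogeneous kinetics are singular: (a_u-d_u)(b_v-d_v) == b_u*a_v"
        )
    # Cramer's rule for J @ (u, v) = (-c_u, -c_v)
    u_star = (-p.c_u * j22 + p.c_v * j12) / det
    v_star = (-p.c_v * j11 + p.c_u * j21) / det

    raw_F = p.a_u * u_star + p.b_u * v_star + p.c_u
    raw_G = p.a_v * u_star + p.b_v * v_star + p.c_v
    clamps_inactive = (0.0 < raw_F < p.F_max) and (0.0 < raw_G < p.G_max)

    J = np.array([[j11, j12], [j21, j22]], dtype=float)
    return SteadyStateReport(
        u_star=u_star,
        v_star=v_star,
        clamps_inactive=clamps_inactive,
        jacobian=J,
        trace=j11 + j22,
        determinant=det,
    )


def turing_check(p: KineticParams) -> SteadyStateReport:
    """Validate that a parameter set is Turing-unstable.

    The steady state must be stable to spatially homogeneous perturbations
    (tr J < 0 and det J > 0) yet destabilized by diffusion, i.e.

        D_v J11 + D_u J22 > 2 sqrt(D_u D_v det J).

    When both hold, the growth rate h(k^2) = D_u D_v k^4
    - (D_v J11 + D_u J22) k^2 + det J is negative on a non-empty interval
    of squared wavenumbers, reported as ``k2_range``.

    Raises
    ------
    ClampedSteadyStateError
        If a production clamp is active at the steady state (linearization
        at a kink of the piecewise kinetics would be meaningless).
    """
    rep = steady_state(p)
    if not rep.clamps_inactive:
        raise ClampedSteadyStateError(
            "steady state sits on a production clamp; linear analysis refused"
        )
    j11, j12 = rep.jacobian[0]
    j21, j22 = rep.jacobian[1]
    tr, det = rep.trace, rep.determinant
    rep.stable_without_diffusion = tr < 0.0 and det > 0.0

    cross = p.D_v * j11 + p.D_u * j22
    rep.turing_unstable = bool(
        rep.stable_without_diffusion
        and det > 0.0
        and cross > 2.0 * math.sqrt(p.D_u * p.D_v * det)
    )
    if rep.turing_unstable:
        # roots of D_u D_v k^4 - cross k^2 + det = 0
        disc = math.sqrt(cross * cross - 4.0 * p.D_u * p.D_v * det)
        denom = 2.0 * p.D_u * p.D_v
        rep.k2_range = ((cross - disc) / denom, (cross + disc) / denom)
    return rep


def growth_rate(p: KineticParams, k2) -> np.ndarray:
    """Max real part of the linearized growth rate at squared wavenumber k2.

    Eigenvalues of J - diag(D_u, D_v) k^2; accepts scalar or array k2.
    Used by the ``check`` CLI to print the dispersion relation; tests verify
    its sign structure independently by brute-force eigen-decomposition.
    """
    k2 = np.asarray(k2, dtype=float)
    rep = steady_state(p)
    j11, j12 = rep.jacobian[0]
    j21, j22 = rep.jacobian[1]
    a11 = j11 - p.D_u * k2
    a22 = j22 - p.D_v * k2
    tr = a11 + a22
    det = a11 * a22 - j12 * j21
    disc = tr * tr - 4.0 * det + 0j
    lam = 0.5 * (tr + np.sqrt(disc))
    lam2 = 0.5 * (tr - np.sqrt(disc))
    return np.maximum(lam.real, lam2.real)
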