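"""Per-fiber force balance and sliding velocities.

A lint fiber sandwiched between shirt and hair feels equal normal forces F_N
at both contacts. The shirt-side friction F_S = mu_SL * F_N drags the fiber
along the shirt's motion; the hair-side friction F_H = mu_HL * F_N opposes
it, with mu_HL directional (larger tip-to-root). The net traction
F_T = F_S - F_H is balanced against Stokes-scale air drag F_D ~ eta * l * U,
giving the phase sliding speed U = (mu_SL - mu_HL) F_N / (eta l). With equal
inhale/exhale durations the cycle-averaged drift toward the navel is
u_bar = (U+ - U-)/2.

All "~" scaling relations are evaluated as equalities with proportionality
constant 1, as the worked estimates require; outputs are order-of-magnitude
physics, not precision mechanics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from lintflux.params import FiberGeometry, ModelParams

logger = logging.getLogger(__name__)

__all__ = [
    "ForceBalance", "VelocityPair",
    "fabric_tension", "skin_pressure", "normal_force", "contact_area",
    "phase_velocity", "mean_velocity", "fiber_mass", "force_balance",
]


@dataclass(frozen=True)
class ForceBalance:
    """Forces on one sandwiched fiber, for a given hair-friction direction.

    ``drag_coefficient`` is the Stokes-scale drag per unit speed, eta*l
    (N s/m), so that F_D = drag_coefficient * U.
    """

    F_N: float
    F_S: float
    F_H: float
    F_T: float
    A_c: float
    gamma: float
    drag_coefficient: float

    def __post_init__(self) -> None:
        if self.F_N < 0 or self.A_c < 0 or self.gamma < 0:
            raise ValueError("F_N, A_c and gamma must be non-negative")


@dataclass(frozen=True)
class VelocityPair:
    """Phase and cycle-averaged fiber velocities.

    U_plus is the exhale (root-to-tip) sliding speed, U_minus the inhale
    speed; u_bar = (U_plus - U_minus)/2 is the net drift toward the navel and
    dx_cycle = u_bar * T the net displacement per breathing cycle.
    """

    U_plus: float
    U_minus: float
    u_bar: float
    dx_cycle: float


def fabric_tension(p: float, R: float) -> float:
    """Fabric line tension gamma = p * R (N/m) from the Laplace relation.

    The garment wrapped on the abdominal wall of longitudinal radius R under
    skin pressure p behaves like a membrane under tension, p = gamma / R.
    With p = 100 Pa and R = 0.47 m this gives gamma ≈ 47 N/m.
    """
    if R <= 0:
        raise ValueError(f"radius of curvature R must be > 0, got {R}")
    if p < 0:
        raise ValueError(f"pressure p must be >= 0, got {p}")
    return p * R


def skin_pressure(gamma: float, R: float) -> float:
    """Skin pressure p = gamma / R (Pa); exact inverse of :func:`fabric_tension`.

    At fixed fabric tension, a larger belly (smaller longitudinal R) bears a
    higher skin pressure — the mechanism behind the bigger-belly effect.
    """
    if R <= 0:
        raise ValueError(f"radius of curvature R must be > 0, got {R}")
    if gamma < 0:
        raise ValueError(f"line tension gamma must be >= 0, got {gamma}")
    return gamma / R


def contact_area(geometry: FiberGeometry, alpha: float) -> float:
    """Real contact area A_c = alpha * d * l (m^2).

    The real contact between the cylindrical fiber and the fabric is a small
    fraction alpha of the projected area d*l (surface roughness limits true
    contact to asperity tips).
    """
    return alpha * geometry.d * geometry.l


def normal_force(p: float, geometry: FiberGeometry, alpha: float) -> float:
    """Interfacial normal force F_N = p * A_c = p * alpha * d * l (N)."""
    if p < 0:
        raise ValueError(f"pressure p must be >= 0, got {p}")
    if alpha < 0:
        raise ValueError(f"contact fraction alpha must be >= 0, got {alpha}")
    return p * contact_area(geometry, alpha)


def phase_velocity(mu_SL: float, mu_HL_dir: float, F_N: float,
                   eta: float, l: float) -> float:
    """Sliding speed in one breathing phase: U = (mu_SL - mu_HL) F_N / (eta l).

    Traction (mu_SL - mu_HL) F_N balances Stokes-scale drag eta*l*U. A
    negative raw value means shirt friction cannot drag the fiber in that
    phase; the speed is clamped to zero (no-slip) and the event logged.
    """
    if eta <= 0 or l <= 0:
        raise ValueError("eta and l must be > 0")
    if F_N < 0:
        raise ValueError(f"normal force F_N must be >= 0, got {F_N}")
    raw = (mu_SL - mu_HL_dir) * F_N / (eta * l)
    if raw < 0:
        logger.info(
            "no-slip phase: mu_SL=%g < mu_HL=%g, clamping phase velocity to 0",
            mu_SL, mu_HL_dir,
        )
        return 0.0
    return raw


def mean_velocity(params: ModelParams) -> VelocityPair:
    """Phase velocities and cycle-averaged drift for a parameter set.

    u_bar = (U+ - U-)/2 = (mu_HL- - mu_HL+) F_N / (2 eta l) when both phases
    slide; mu_SL cancels. At the defaults u_bar ≈ 2.72e-5 m/s, i.e. a net
    step of u_bar*T ≈ 0.16 mm toward the navel per six-second breath.

    Raises
    ------
    ValueError
        If u_bar < 0 (lint would migrate away from the navel; requires
        mu_HL_minus < mu_HL_plus, already excluded by :class:`FrictionSet`).
    """
    F_N = normal_force(params.garment.p, params.geometry, params.garment.alpha)
    eta, l = params.garment.eta, params.geometry.l
    U_plus = phase_velocity(params.friction.mu_SL, params.friction.mu_HL_plus, F_N, eta, l)
    U_minus = phase_velocity(params.friction.mu_SL, params.friction.mu_HL_minus, F_N, eta, l)
    u_bar = (U_plus - U_minus) / 2.0
    if u_bar < 0:
        raise ValueError(
            f"u_bar = {u_bar:g} < 0: lint would migrate away from the navel "
            "(mu_HL_minus < mu_HL_plus)"
        )
    return VelocityPair(U_plus=U_plus, U_minus=U_minus, u_bar=u_bar,
                        dx_cycle=u_bar * params.transport.T)


def fiber_mass(geometry: FiberGeometry) -> float:
    """Mass of one cylindrical lint fiber, m_L = rho * pi * d^2 * l / 4 (kg).

    ≈ 3.53e-11 kg (35 ng) for the nominal cotton fiber.
    """
    return geometry.rho * math.pi * geometry.d ** 2 * geometry.l / 4.0


def force_balance(params: ModelParams, direction: str = "+") -> ForceBalance:
    """Full force bookkeeping for one sliding direction ("+" root-to-tip /
    exhale, "-" tip-to-root / inhale)."""
    if direction not in ("+", "-"):
        raise ValueError(f"direction must be '+' or '-', got {direction!r}")
    mu_HL = (params.friction.mu_HL_plus if direction == "+"
             else params.friction.mu_HL_minus)
    F_N = normal_force(params.garment.p, params.geometry, params.garment.alpha)
    F_S = params.friction.mu_SL * F_N
    F_H = mu_HL * F_N
    return ForceBalance(
        F_N=F_N,
        F_S=F_S,
        F_H=F_H,
        F_T=F_S - F_H,
        A_c=contact_area(params.geometry, params.garment.alpha),
        gamma=fabric_tension(params.garment.p, params.garment.R),
        drag_coefficient=params.garment.eta * params.geometry.l,
    )
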