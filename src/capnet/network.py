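"""Three-node capillary network: topology, scaling and nodal pressure solver.

The motif has two inlet vessels (1, diameter ``alpha*D``; 2, diameter ``D``)
feeding internal nodes N134 and N235, a redundant vessel 3 (diameter ``D``)
connecting the two, vessels 4 (``alpha*D``) and 5 (``D``) converging at N456,
and an outlet vessel 6 (``D``).  All vessels have unit dimensionless length.

Nondimensionalisation: resistances are scaled by the resistance of vessel 2 at
the inlet haematocrit ``H0``, fluxes by the reference steady-state flux of
vessel 2 (so the reference state has ``Q2 = 1``), and time by the haematocrit
transit time of vessel 2 in that state.  The scaled resistance of vessel ``i``
is ``R_i = mu(H_i, alpha_i*D) / (alpha_i**4 * mu(H0, D))`` with ``alpha_i =
alpha`` for vessels 1 and 4 and 1 otherwise; the dimensionless velocity is
``U_i = Q_i / alpha_i**2``.

Internal nodal pressures obey the junction law ``p0 = sum(K_j p_j)/sum(K_j)``
with conductivities ``K_j = 1/R_j``; a Gauss–Seidel iteration (as used in the
original study) and a direct linear solve are both provided — the direct solve
doubles as an oracle for the iterative one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

from .rheology import relative_viscosity

__all__ = [
    "ALPHA_FACTORS",
    "NetworkSpec",
    "PressureState",
    "three_node_network",
    "calibrate_deltaP",
    "scaled_resistance",
    "trivial_Q1",
    "solve_nodal_pressures",
    "junction_pressure",
    "vessel_fluxes",
]

#: per-vessel diameter factor alpha_i (index 0 unused; vessels are 1-based)
ALPHA_FACTORS = (None, "alpha", 1.0, 1.0, "alpha", 1.0, 1.0)


@dataclass(frozen=True)
class NetworkSpec:
    """Parameters of the three-node motif.

    alpha : diameter ratio of vessels 1 and 4 to the common diameter D
    H0 : inlet discharge haematocrit (both inlets)
    D : nominal dimensionless diameter in microns
    bc_type : 'equal_inlet_pressure' or 'fixed_inlet_flux'
    deltaP : dimensionless inlet-outlet pressure difference (pressure BC);
        calibrated so that the reference steady state has Q2 = 1
    """

    alpha: float
    H0: float
    D: float = 20.0
    bc_type: str = "equal_inlet_pressure"
    deltaP: float | None = None

    def __post_init__(self):
        if not 0.25 <= self.alpha <= 2.25:
            raise ValueError(f"alpha={self.alpha} outside [0.25, 2.25]")
        if not 0.0 <= self.H0 <= 1.0:
            raise ValueError(f"H0={self.H0} outside [0, 1]")
        if self.D <= 1.1:
            raise ValueError(f"D={self.D} must exceed 1.1")
        if self.bc_type not in ("equal_inlet_pressure", "fixed_inlet_flux"):
            raise ValueError(f"unknown bc_type {self.bc_type!r}")

    def alpha_i(self, i: int) -> float:
        """Diameter factor of vessel i (alpha for vessels 1 and 4, else 1)."""
        a = ALPHA_FACTORS[i]
        return self.alpha if a == "alpha" else a

    def diameter(self, i: int) -> float:
        return self.alpha_i(i) * self.D

    def mu0(self) -> float:
        """Reference viscosity mu(H0, D) used in the resistance scaling."""
        return relative_viscosity(self.H0, self.D)


@dataclass
class PressureState:
    """Internal nodal pressures and the conductivities that produced them."""

    p134: float
    p235: float
    p456: float
    p_in: float
    p_out: float
    K: Tuple[float, ...]  # K[0] unused; K[1..6] vessel conductivities


def three_node_network(
    alpha: float,
    H0: float,
    D: float = 20.0,
    bc_type: str = "equal_inlet_pressure",
) -> NetworkSpec:
    """Build a :class:`NetworkSpec` with a trivially-calibrated pressure drop."""
    spec = NetworkSpec(alpha=alpha, H0=H0, D=D, bc_type=bc_type)
    return NetworkSpec(
        alpha=alpha, H0=H0, D=D, bc_type=bc_type, deltaP=calibrate_deltaP(spec)
    )


def scaled_resistance(spec: NetworkSpec, i: int, H: float) -> float:
    """Scaled resistance of vessel i at discharge haematocrit H."""
    a = spec.alpha_i(i)
    return relative_viscosity(H, a * spec.D) / (a**4 * spec.mu0())


def trivial_Q1(alpha: float, H0: float, D: float = 20.0) -> float:
    """Flux in the top branch at the zero-redundant-flow equilibrium.

    ``Q1 = 1/R1 = alpha**4 * mu(H0, D) / mu(H0, alpha*D)``.
    """
    return alpha**4 * relative_viscosity(H0, D) / relative_viscosity(H0, alpha * D)


def calibrate_deltaP(spec: NetworkSpec) -> float:
    """Pressure difference for which the trivial equilibrium has ``Q2 = 1``.

    Along the bottom path, vessels 2 and 5 carry unit flux at unit scaled
    resistance and vessel 6 carries ``1 + Q1`` at unit resistance, so
    ``deltaP = 3 + Q1``.
    """
    return 3.0 + trivial_Q1(spec.alpha, spec.H0, spec.D)


def junction_pressure(K: Sequence[float], p: Sequence[float]) -> float:
    """Nodal pressure of a generic three-way junction: conductivity-weighted mean."""
    num = sum(k * pj for k, pj in zip(K, p))
    den = sum(K)
    return num / den


def _node_system(K, p_in, p_out):
    """Direct 3x3 system M p = b for the internal pressures (p134, p235, p456)."""
    K1, K2, K3, K4, K5, K6 = K[1:7]
    M = np.array(
        [
            [K1 + K3 + K4, -K3, -K4],
            [-K3, K2 + K3 + K5, -K5],
            [-K4, -K5, K4 + K5 + K6],
        ]
    )
    b = np.array([K1 * p_in, K2 * p_in, K6 * p_out])
    return M, b


def solve_nodal_pressures(
    spec: NetworkSpec,
    K: Sequence[float],
    p_in: float | None = None,
    p_out: float = 0.0,
    method: str = "direct",
    tol: float = 1e-20,
    max_iter: int = 100_000,
) -> PressureState:
    """Solve for the three internal nodal pressures.

    ``K`` is a length-7 sequence (index 0 unused) of positive vessel
    conductivities.  ``method='gauss-seidel'`` iterates the junction law until
    the relative change drops below ``tol`` or stagnates at machine precision;
    ``method='direct'`` solves the equivalent 3x3 linear system.
    """
    if p_in is None:
        p_in = spec.deltaP if spec.deltaP is not None else calibrate_deltaP(spec)
    if any(k <= 0 for k in K[1:7]):
        raise ValueError("conductivities must be positive")
    if method == "direct":
        M, b = _node_system(K, p_in, p_out)
        p134, p235, p456 = np.linalg.solve(M, b)
    elif method == "gauss-seidel":
        K1, K2, K3, K4, K5, K6 = K[1:7]
        p134 = p235 = p456 = 0.5 * (p_in + p_out)
        for _ in range(max_iter):
            n134 = junction_pressure((K1, K3, K4), (p_in, p235, p456))
            n235 = junction_pressure((K2, K3, K5), (p_in, n134, p456))
            n456 = junction_pressure((K4, K5, K6), (n134, n235, p_out))
            change = max(
                abs(n134 - p134), abs(n235 - p235), abs(n456 - p456)
            )
            scale = max(abs(n134), abs(n235), abs(n456), 1e-300)
            stalled = change == 0.0 or change / scale < 4e-16
            p134, p235, p456 = n134, n235, n456
            if change / scale < tol or stalled:
                break
        else:
            raise RuntimeError("Gauss-Seidel pressure solve did not converge")
    else:
        raise ValueError(f"unknown method {method!r}")
    return PressureState(
        p134=float(p134), p235=float(p235), p456=float(p456),
        p_in=float(p_in), p_out=float(p_out), K=tuple(K),
    )


def vessel_fluxes(spec: NetworkSpec, ps: PressureState) -> Tuple[float, ...]:
    """Signed fluxes ``Q1..Q6`` (index 0 unused) from a pressure state.

    Sign convention: positive along the nominal flow directions — inlets to
    internal nodes, internal nodes to outlet, and for the redundant vessel 3
    positive from N134 (top) towards N235 (bottom).  ``Q3 > 0`` therefore means
    top-to-bottom flow (Case II); ``Q3 < 0`` bottom-to-top (Case I).
    """
    K = ps.K
    Q1 = K[1] * (ps.p_in - ps.p134)
    Q2 = K[2] * (ps.p_in - ps.p235)
    Q3 = K[3] * (ps.p134 - ps.p235)
    Q4 = K[4] * (ps.p134 - ps.p456)
    Q5 = K[5] * (ps.p235 - ps.p456)
    Q6 = K[6] * (ps.p456 - ps.p_out)
    return (0.0, Q1, Q2, Q3, Q4, Q5, Q6)
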