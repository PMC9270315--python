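"""Apparent blood viscosity in microvessels (Fåhræus–Lindqvist effect).

Empirical in-vitro law of Pries, Neuhaus & Gaehtgens for the relative apparent
viscosity of blood as a function of vessel diameter ``D`` (in microns) and
discharge haematocrit ``H``::

    mu(H, D) = eta * beta * [1 + beta*(eta45 - 1) * ((1-H)**C - 1)/((0.55)**C - 1)]

where ``beta``, ``eta45``, ``C`` (and the auxiliary factor ``f``) are functions
of the diameter alone.  ``eta`` is the plasma-viscosity scale; everything
downstream of this module works with viscosity *ratios*, so ``eta`` defaults to
1 and cancels out of the nondimensional network equations.

The Fåhræus (tube vs discharge haematocrit) correction is deliberately not
included; the network model transports discharge haematocrit only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

__all__ = [
    "ViscosityParams",
    "diameter_coefficients",
    "relative_viscosity",
    "viscosity_derivative",
]

_H45_DENOM_H = 0.55  # (1 - 0.45): haematocrit at which eta45 is defined


@dataclass(frozen=True)
class ViscosityParams:
    """Diameter-dependent coefficients of the apparent-viscosity law.

    Attributes
    ----------
    D : float
        Vessel diameter in microns (dimensionless number ``diameter / 1 um``).
    beta : float
        Geometric factor ``(D/(D-1.1))**2 > 1``.
    eta45 : float
        Relative apparent viscosity at ``H = 0.45``.
    C : float
        Shape exponent controlling the haematocrit dependence.
    f : float
        Diameter correction factor ``1 + 10*(D/10)**12 >= 1``.
    eta : float
        Plasma-viscosity scale (default 1; cancels in viscosity ratios).
    """

    D: float
    beta: float
    eta45: float
    C: float
    f: float
    eta: float = 1.0


@lru_cache(maxsize=256)
def _coefficients(D: float, eta: float) -> ViscosityParams:
    beta = (D / (D - 1.1)) ** 2
    eta45 = 6.0 * math.exp(-0.085 * D) + 3.2 - 2.44 * math.exp(-0.06 * D**0.645)
    f = 1.0 + 10.0 * (D / 10.0) ** 12
    C = (0.8 + math.exp(-0.075 * D)) * (1.0 / f - 1.0) + 1.0 / f
    return ViscosityParams(D=D, beta=beta, eta45=eta45, C=C, f=f, eta=eta)


def diameter_coefficients(D: float, eta: float = 1.0) -> ViscosityParams:
    """Evaluate the diameter-dependent coefficients ``beta, eta45, C, f``.

    Parameters
    ----------
    D : float
        Vessel diameter in microns; must exceed 1.1 (``beta`` is singular at
        ``D = 1.1``).
    eta : float, optional
        Plasma-viscosity scale.

    Returns
    -------
    ViscosityParams
    """
    if D <= 1.1:
        raise ValueError(f"diameter D={D} must exceed 1.1 um (beta singular)")
    return _coefficients(float(D), float(eta))


def _pow1mH(H: float, C: float) -> float:
    # (1-H)**C via exp(C*log(1-H)), guarded for H -> 1
    if H >= 1.0:
        if C > 0.0:
            return 0.0
        raise ValueError("(1-H)**C singular at H=1 with C <= 0")
    return math.exp(C * math.log1p(-H))


def relative_viscosity(H: float, D: float, eta: float = 1.0) -> float:
    """Apparent viscosity ``mu(H, D)`` in units of the plasma viscosity.

    ``mu(0, D) = eta*beta`` and ``mu`` increases monotonically with ``H``
    throughout the physiological range.
    """
    if not 0.0 <= H <= 1.0:
        raise ValueError(f"discharge haematocrit H={H} outside [0, 1]")
    p = diameter_coefficients(D, eta)
    num = _pow1mH(H, p.C) - 1.0
    den = _H45_DENOM_H**p.C - 1.0
    return p.eta * p.beta * (1.0 + p.beta * (p.eta45 - 1.0) * num / den)


def viscosity_derivative(H: float, D: float, eta: float = 1.0) -> float:
    """Analytic derivative ``d mu / d H`` of the viscosity law.

    Raises for ``H = 1`` when ``(1-H)**(C-1)`` is singular (``C < 1``).
    """
    if not 0.0 <= H <= 1.0:
        raise ValueError(f"discharge haematocrit H={H} outside [0, 1]")
    p = diameter_coefficients(D, eta)
    if H == 1.0 and p.C < 1.0:
        raise ValueError("d mu/dH singular at H=1 for C < 1")
    den = _H45_DENOM_H**p.C - 1.0
    return -p.eta * p.beta**2 * (p.eta45 - 1.0) * p.C * _pow1mH(H, p.C - 1.0) / den
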