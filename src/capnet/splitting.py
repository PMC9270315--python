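"""Haematocrit partitioning at diverging microvascular bifurcations.

Implements the phase-separation (plasma-skimming) rule of Pries et al.: the
fraction ``F`` of the parent vessel's red-cell flux entering a daughter branch
as a function of the daughter-to-parent flux ratio ``psi``::

              0                                            psi < psi0
    F(psi) =  e^A (psi-psi0)^B / (e^A (psi-psi0)^B
                  + (1-psi-psi0)^B)                        psi0 <= psi <= 1-psi0
              1                                            psi > 1-psi0

with A a diameter-asymmetry coefficient, B a haematocrit-dependent exponent
and ``psi0`` the skimming threshold below which no red cells enter the
daughter branch.  The rule is nonsmooth at ``psi0`` and ``1-psi0``.

A spline-smoothed variant replaces the constant pieces with minimal cubics
``y_L = a psi**3`` and ``y_U = 1 - b (1-psi)**3`` joined C1-continuously to the
logistic core; the cubic forms are the lowest-order polynomials with
``F(0) = F'(0) = F''(0) = 0`` (and the mirrored conditions at ``psi = 1``),
which preserves the stability properties of the zero-flow equilibrium of a
redundant vessel.

The sensitivity function ``S(psi) = -(1/psi)(F/psi - dF/dpsi)`` measures how
strongly the daughter haematocrit responds to flux perturbations; it controls
the feedback strength behind oscillatory instabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

from scipy.optimize import brentq

__all__ = [
    "SplitRule",
    "make_split_rule",
    "split_fraction",
    "split_derivative",
    "build_smoothing",
    "skimming_sensitivity",
]


@dataclass(frozen=True)
class SplitRule:
    """Coefficients of a haematocrit splitting rule at a diverging node.

    ``variant`` is ``"nonsmooth"`` (piecewise rule with constant tails) or
    ``"smooth"`` (cubic-smoothed tails).  For the smooth variant ``psiL`` /
    ``psiU`` are the junction points and ``a`` / ``b`` the cubic coefficients
    of ``y_L = a psi**3`` and ``y_U = 1 - b (1-psi)**3``.
    """

    A: float
    B: float
    psi0: float
    variant: str = "nonsmooth"
    psiL: Optional[float] = None
    psiU: Optional[float] = None
    a: Optional[float] = None
    b: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "A": self.A, "B": self.B, "psi0": self.psi0, "variant": self.variant,
            "psiL": self.psiL, "psiU": self.psiU, "a": self.a, "b": self.b,
        }

    @staticmethod
    def from_dict(d: dict) -> "SplitRule":
        return SplitRule(**d)


def make_split_rule(
    D_parent: float,
    D_daughter_fav: float,
    D_daughter_other: float,
    H_parent: float,
    variant: str = "nonsmooth",
) -> SplitRule:
    """Build the splitting rule for a diverging bifurcation.

    ``D_daughter_fav`` is the daughter branch whose red-cell flux fraction the
    rule returns (the redundant vessel in the three-node network);
    ``D_daughter_other`` is its sibling.  ``H_parent`` is the discharge
    haematocrit of the parent vessel (the inlet haematocrit ``H0`` in the
    three-node network, where the parent of every splitting node is an inlet
    vessel).
    """
    for D in (D_parent, D_daughter_fav, D_daughter_other):
        if D <= 1.1:
            raise ValueError("vessel diameters must exceed 1.1 um")
    if not 0.0 <= H_parent <= 1.0:
        raise ValueError("parent haematocrit outside [0, 1]")
    A = -(6.96 / D_parent) * math.log(D_daughter_fav / D_daughter_other)
    B = 1.0 + 6.98 * (1.0 - H_parent) / D_parent
    psi0 = 0.4 / D_parent
    rule = SplitRule(A=A, B=B, psi0=psi0)
    if variant == "smooth":
        rule = build_smoothing(rule)
    elif variant != "nonsmooth":
        raise ValueError(f"unknown splitting variant {variant!r}")
    return rule


def _core(rule: SplitRule, psi: float) -> float:
    """Logistic-like middle piece, valid on [psi0, 1-psi0]."""
    x = psi - rule.psi0
    y = 1.0 - psi - rule.psi0
    if x <= 0.0:
        return 0.0
    if y <= 0.0:
        return 1.0
    ea = math.exp(rule.A)
    num = ea * x**rule.B
    return num / (num + y**rule.B)


def _core_deriv(rule: SplitRule, psi: float) -> float:
    x = psi - rule.psi0
    y = 1.0 - psi - rule.psi0
    if x <= 0.0 or y <= 0.0:
        return 0.0
    ea = math.exp(rule.A)
    u = ea * x**rule.B
    v = y**rule.B
    # F = u/(u+v); F' = (u'v - uv')/(u+v)^2, u' = B u/x, v' = -B v/y
    return (rule.B * u * v / x + rule.B * u * v / y) / (u + v) ** 2


def split_fraction(rule: SplitRule, psi: float) -> float:
    """Red-cell flux fraction ``F(psi)`` entering the favoured daughter."""
    if not 0.0 <= psi <= 1.0:
        raise ValueError(f"flux ratio psi={psi} outside [0, 1]")
    if rule.variant == "smooth":
        if psi < rule.psiL:
            return rule.a * psi**3
        if psi > rule.psiU:
            return 1.0 - rule.b * (1.0 - psi) ** 3
        return _core(rule, psi)
    if psi < rule.psi0:
        return 0.0
    if psi > 1.0 - rule.psi0:
        return 1.0
    return _core(rule, psi)


def split_derivative(rule: SplitRule, psi: float) -> float:
    """Derivative ``dF/dpsi`` of the active piece.

    At the nonsmooth kinks ``psi0`` and ``1-psi0`` the one-sided derivative of
    the interior (logistic) piece is returned: linearisations are only ever
    evaluated at states strictly inside a piece, and the jump at the threshold
    is precisely the source of the nonsmooth Hopf bifurcation.
    """
    if not 0.0 <= psi <= 1.0:
        raise ValueError(f"flux ratio psi={psi} outside [0, 1]")
    if rule.variant == "smooth":
        if psi < rule.psiL:
            return 3.0 * rule.a * psi**2
        if psi > rule.psiU:
            return 3.0 * rule.b * (1.0 - psi) ** 2
        return _core_deriv(rule, psi)
    if psi < rule.psi0:
        return 0.0
    if psi > 1.0 - rule.psi0:
        return 0.0
    return _core_deriv(rule, psi)


def build_smoothing(rule: SplitRule) -> SplitRule:
    """Construct the cubic-smoothed variant of a nonsmooth rule.

    The lower cubic ``y_L = a psi**3`` and the junction ``psiL`` are fixed by
    value and slope continuity with the logistic core, which reduces to the
    scalar condition ``G(psi) - psi G'(psi)/3 = 0``; the upper pair ``(b,
    psiU)`` follows from the mirrored condition ``(1 - G) - (1-psi) G'/3 = 0``.
    """
    if rule.variant != "nonsmooth":
        raise ValueError("smoothing must start from a nonsmooth rule")

    def glo(psi: float) -> float:
        return _core(rule, psi) - psi * _core_deriv(rule, psi) / 3.0

    def gup(psi: float) -> float:
        return (1.0 - _core(rule, psi)) - (1.0 - psi) * _core_deriv(rule, psi) / 3.0

    psiL = _scan_root(glo, rule.psi0, 1.0 - rule.psi0)
    psiU = _scan_root(gup, 1.0 - rule.psi0, rule.psi0)
    if psiL is None or psiU is None or not (rule.psi0 < psiL < psiU < 1.0 - rule.psi0):
        raise RuntimeError("no valid cubic junction points found for smoothing")
    a = _core_deriv(rule, psiL) / (3.0 * psiL**2)
    b = _core_deriv(rule, psiU) / (3.0 * (1.0 - psiU) ** 2)
    return replace(rule, variant="smooth", psiL=psiL, psiU=psiU, a=a, b=b)


def _scan_root(g, lo: float, hi: float, n: int = 400) -> Optional[float]:
    """First sign change of g scanning from lo towards hi (lo may exceed hi)."""
    eps = 1e-12 * (1.0 + abs(hi - lo))
    step = (hi - lo) / n
    x0 = lo + 1e-9 * (1.0 if step > 0 else -1.0)
    f0 = g(x0)
    for k in range(1, n + 1):
        x1 = lo + k * step
        f1 = g(x1)
        if f0 == 0.0:
            return x0
        if f0 * f1 < 0.0:
            aa, bb = (x0, x1) if x0 < x1 else (x1, x0)
            return brentq(g, aa, bb, xtol=1e-14)
        x0, f0 = x1, f1
    return None


def skimming_sensitivity(rule: SplitRule, psi: float) -> float:
    """Sensitivity ``S(psi) = -(1/psi)(F(psi)/psi - dF/dpsi)``.

    ``S`` sets the ratio of haematocrit to flux perturbations in the daughter
    branch; the limit ``psi -> 0`` is 0 whenever ``F`` and ``F'`` vanish at the
    origin (both variants).
    """
    if psi < 0.0 or psi > 1.0:
        raise ValueError(f"flux ratio psi={psi} outside [0, 1]")
    if psi == 0.0:
        return 0.0
    return -(split_fraction(rule, psi) / psi - split_derivative(rule, psi)) / psi
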