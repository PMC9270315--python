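"""Linear stability of the network's steady states.

Perturbations about a steady state are taken in the normal-mode form
``Q_i = Q_i0 + eps q_i e^{lam t}``, ``Rbar_i = R_i0 + eps r_i e^{lam t}`` and
``H_i = H_i0 + eps h_i e^{lam(t - alpha_i^2 x / Q_i0)}`` with complex
``lam = sigma + i omega``.  Haematocrit advection turns each vessel into a
pure delay of one transit time ``tau_i = alpha_i^2 / Q_i0``, so the resistance
response to an inlet-haematocrit perturbation carries the transit filter
``g(x) = (1 - e^{-x})/x`` evaluated at ``x = alpha_i^2 lam / Q_i0``:

    r_i = dmu/dH|_(H_i0, alpha_i D) / (alpha_i^4 mu(H0, D)) * g(x) * h_i

For the *trivial* state (no flow in the redundant vessel) the perturbation
system closes on the six flux amplitudes; under fixed-flux boundary conditions
it collapses to a single transcendental equation whose roots are provably
real, so the trivial state can only lose stability through a transcritical
exchange (the ``lam -> 0`` limit gives the critical curve in ``(alpha, H0)``).

For *nontrivial* states the splitting rule contributes ``h3 = H0 (F/psi -
F') (q_parent - q_3/psi_den)`` and the delay ``e^{-lam/Q3}`` of the redundant
vessel enters the daughter haematocrit — the ingredient responsible for the
Hopf bifurcation to oscillatory flow.  The full system is a 14x14
transcendental eigenproblem ``A(lam) v = 0`` in ``v = (h3..h6, r3..r6,
q1..q6)``; growth rates are located as roots of ``det A`` by complex Newton
iteration seeded from a coarse modulus scan, with an argument-principle box
count as a global safeguard.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq, root

from .rheology import relative_viscosity, viscosity_derivative
from .splitting import SplitRule, split_derivative, split_fraction
from .steady import SteadyState, solve_nontrivial, split_rule_for_case, trivial_Q1

__all__ = [
    "Eigenmode",
    "transit_filter",
    "trivial_determinant",
    "trivial_critical_H0",
    "critical_curve",
    "asymptotic_critical_H0",
    "nontrivial_system_matrix",
    "growth_rate",
    "count_complex_roots",
    "iso_sigma_contour",
]


@dataclass
class Eigenmode:
    """An eigenvalue ``lam = sigma + i omega`` with its perturbation vector."""

    lam: complex
    v: Optional[np.ndarray]
    bc: str
    base: Optional[SteadyState] = None

    @property
    def sigma(self) -> float:
        return self.lam.real

    @property
    def omega(self) -> float:
        return self.lam.imag


def _cexp(z: complex) -> complex:
    """Complex exponential clamped against overflow (|Re z| huge)."""
    if z.real > 700.0:
        z = complex(700.0, z.imag)
    return cmath.exp(z)


def transit_filter(x: complex) -> complex:
    """``g(x) = (1 - e^{-x})/x`` with the analytic value 1 at ``x = 0``."""
    if abs(x) < 1e-8:
        return 1.0 - x / 2.0 + x * x / 6.0
    return (1.0 - _cexp(-x)) / x


def _rcoef(lam: complex, Q: float, a: float, H: float, D: float, mu0: float) -> complex:
    """Resistance response coefficient ``r_i / h_i`` of one vessel."""
    dmu = viscosity_derivative(H, a * D)
    return dmu / (a**4 * mu0) * transit_filter(a * a * lam / Q)


# ---------------------------------------------------------------------------
# trivial state
# ---------------------------------------------------------------------------

def _trivial_scalars(alpha: float, H0: float, D: float):
    mu0 = relative_viscosity(H0, D)
    R1 = relative_viscosity(H0, alpha * D) / (alpha**4 * mu0)
    R3 = relative_viscosity(0.0, D) / mu0
    return mu0, R1, R3


def trivial_determinant(lam: complex, alpha: float, H0: float, D: float = 20.0,
                        bc: str = "pressure") -> complex:
    """Characteristic residual of the trivial state's eigenproblem.

    Pressure boundary conditions: determinant of the 6x6 flux system (the
    haematocrit and resistance amplitudes are eliminated analytically in terms
    of ``q3``).  Flux boundary conditions: the scalar residual of the single
    transcendental equation.
    """
    mu0, R1, R3 = _trivial_scalars(alpha, H0, D)
    lam = complex(lam)
    Q1 = 1.0 / R1
    c4 = _rcoef(lam, Q1, alpha, H0, D, mu0)
    c5 = _rcoef(lam, 1.0, 1.0, H0, D, mu0)
    if bc == "flux":
        return (1.0 + R3 + R1) - H0 * (c4 + c5)
    if bc != "pressure":
        raise ValueError(f"unknown bc {bc!r}")
    Q6 = 1.0 + Q1
    c6 = _rcoef(lam, Q6, 1.0, H0, D, mu0)
    # h-amplitudes per unit q3:  h4 = -R1*H0, h5 = H0,
    # h6 = (H0*R1/(1+R1)) * (e^{-lam} - e^{-R1 alpha^2 lam})
    e5 = _cexp(-lam)
    e4 = _cexp(-R1 * alpha**2 * lam)
    h6_per_q3 = (H0 * R1 / (1.0 + R1)) * (e5 - e4)
    # rows in q = (q1..q6)
    M = np.zeros((6, 6), dtype=complex)
    # internal loop: R3 q3 + R1 q4 - q5 + (1/R1) r4 - r5 = 0
    M[0, 2] = R3 - H0 * c4 - H0 * c5
    M[0, 3] = R1
    M[0, 4] = -1.0
    # outer loop: R1 q1 + R1 q4 + q6 + (1/R1) r4 + ((1+R1)/R1) r6 = 0
    M[1, 0] = R1
    M[1, 3] = R1
    M[1, 5] = 1.0
    M[1, 2] = -H0 * c4 + ((1.0 + R1) / R1) * c6 * h6_per_q3
    # inlet loop: R1 q1 - q2 - R3 q3 = 0
    M[2, 0] = R1
    M[2, 1] = -1.0
    M[2, 2] = -R3
    # node balances
    M[3, 0] = 1.0; M[3, 1] = 1.0; M[3, 5] = -1.0
    M[4, 0] = 1.0; M[4, 2] = 1.0; M[4, 3] = -1.0
    M[5, 1] = 1.0; M[5, 2] = -1.0; M[5, 4] = -1.0
    return _scaled_det(M)


def _scaled_det(M: np.ndarray) -> complex:
    s = np.max(np.abs(M), axis=1)
    s[s == 0.0] = 1.0
    return complex(np.linalg.det(M / s[:, None]))


def trivial_critical_H0(alpha: float, D: float = 20.0, bc: str = "pressure",
                        H0_lo: float = 0.02, H0_hi: float = 0.98) -> float:
    """Critical inlet haematocrit of the trivial state (``lam -> 0`` root).

    Above the returned value the trivial state is unstable.  Raises if no
    root lies in the search interval (no instability).
    """
    def f(H0):
        return trivial_determinant(0.0, alpha, H0, D, bc).real

    grid = np.linspace(H0_lo, H0_hi, 97)
    vals = [f(h) for h in grid]
    for k in range(len(grid) - 1):
        if vals[k] == 0.0:
            return float(grid[k])
        if vals[k] * vals[k + 1] < 0.0:
            return float(brentq(f, grid[k], grid[k + 1], xtol=1e-12))
    raise RuntimeError(
        f"no critical H0 in [{H0_lo}, {H0_hi}] for alpha={alpha}, bc={bc}"
    )


def critical_curve(alphas: Sequence[float], D: float = 20.0,
                   bc: str = "pressure") -> np.ndarray:
    """Critical curve ``H0(alpha)``; columns (alpha, H0)."""
    out = []
    for a in alphas:
        out.append((float(a), trivial_critical_H0(a, D, bc)))
    return np.array(out)


def asymptotic_critical_H0(regime: str, bc: str = "pressure", D: float = 20.0,
                           alpha: Optional[float] = None) -> float:
    """Asymptotic critical inlet haematocrit for extreme diameter ratios.

    ``regime='small_alpha'``: both boundary conditions collapse onto the root
    of ``mu(H0, aD) - H0 [a^4 mu_H(H0,D) + mu_H(H0,aD)] = 0`` (requires
    ``alpha``).  ``regime='large_alpha'``: the critical curves flatten to the
    alpha-independent roots of ``H0 mu_H(H0,D)/mu(H0,D) = 1 + R3`` (flux) or
    ``= 1 + 2 R3`` (pressure).
    """
    if regime == "small_alpha":
        if alpha is None:
            raise ValueError("small-alpha asymptote needs alpha")

        def f(H0):
            return relative_viscosity(H0, alpha * D) - H0 * (
                alpha**4 * viscosity_derivative(H0, D)
                + viscosity_derivative(H0, alpha * D)
            )
    elif regime == "large_alpha":
        fac = 2.0 if bc == "pressure" else 1.0

        def f(H0):
            mu0 = relative_viscosity(H0, D)
            R3 = relative_viscosity(0.0, D) / mu0
            return H0 * viscosity_derivative(H0, D) / mu0 - (1.0 + fac * R3)
    else:
        raise ValueError(f"unknown regime {regime!r}")
    return float(brentq(f, 0.01, 0.99, xtol=1e-12))


# ---------------------------------------------------------------------------
# nontrivial states
# ---------------------------------------------------------------------------

_IDX = {name: k for k, name in enumerate(
    ["h3", "h4", "h5", "h6", "r3", "r4", "r5", "r6",
     "q1", "q2", "q3", "q4", "q5", "q6"]
)}


def nontrivial_system_matrix(
    lam: complex,
    base: SteadyState,
    bc: str = "pressure",
    rule: Optional[SplitRule] = None,
    kink_tol: float = 1e-9,
) -> np.ndarray:
    """Matrix ``A(lam)`` of the 14x14 perturbation system about ``base``.

    Unknown ordering: ``(h3, h4, h5, h6, r3, r4, r5, r6, q1..q6)``.  The base
    state must sit strictly inside one piece of the splitting rule; a base on
    a kink of the nonsmooth rule raises (the nonsmooth Hopf point).
    """
    case = base.case
    if case not in ("I", "II"):
        raise ValueError("nontrivial matrix requires a Case I/II base state")
    alpha, H0, D = base.alpha, base.H0, base.D
    if rule is None:
        rule = split_rule_for_case(case, alpha, H0, D)
    lam = complex(lam)
    mu0 = relative_viscosity(H0, D)
    Q1, Q3 = base.Q1, base.Q3
    Q4, Q5, Q6 = base.Q4, base.Q5, base.Q6
    H3, H4, H5, H6 = base.H3, base.H4, base.H5, base.H6
    psi = Q3 if case == "I" else Q3 / Q1
    if not 0.0 < psi < 1.0:
        raise ValueError(f"flux ratio psi={psi} of base state outside (0, 1)")
    if rule.variant == "nonsmooth" and (
        abs(psi - rule.psi0) < kink_tol or abs(1.0 - psi - rule.psi0) < kink_tol
    ):
        raise ValueError("base state on a splitting-rule kink (nonsmooth Hopf)")
    F = split_fraction(rule, psi)
    Fp = split_derivative(rule, psi)
    R = [None] + [base.resistance(i) for i in range(1, 7)]

    A = np.zeros((14, 14), dtype=complex)
    ix = _IDX

    def put(row, **coef):
        for name, val in coef.items():
            A[row, ix[name]] += val

    edel3 = _cexp(-lam / Q3)  # redundant-vessel transit delay
    edel4 = _cexp(-alpha**2 * lam / Q4)
    edel5 = _cexp(-lam / Q5)

    if case == "I":
        # h3: splitting at node 2-3-5, psi = Q3/Q2
        sc = H0 * (F / psi - Fp)
        put(0, h3=1.0, q2=-sc, q3=sc / Q3)
        # h4: converging node 1-3-4 fed by vessels 1 (H0) and 3 (delayed h3)
        c = H0 * (Q3 - F) / Q4**2
        put(1, h4=1.0, q1=-c, q3=c * Q1 / Q3, h3=-(Q3 / Q4) * edel3)
        # h5: sibling daughter at the diverging node
        put(2, h5=1.0,
            q2=-H0 * ((1.0 - F) / Q5 + Fp * Q3 / Q5),
            q5=H0 * (1.0 - F) / Q5**2,
            q3=H0 * Fp / Q5)
        # nodes: q1 + q3 = q4 ; q2 - q3 = q5 ; q4 + q5 = q6
        put(11, q1=1.0, q3=1.0, q4=-1.0)
        put(12, q2=1.0, q3=-1.0, q5=-1.0)
        # internal loop: dp3 + dp4 - dp5 = 0
        put(8, q3=R[3], r3=Q3, q4=R[4], r4=Q4, q5=-R[5], r5=-Q5)
        loop_in = dict(q1=R[1], q2=-1.0, q3=-R[3], r3=-Q3)
    else:
        # h3: splitting at node 1-3-4, psi* = Q3/Q1
        put(0, h3=1.0,
            q1=-(H0 / Q3) * (F - psi * Fp),
            q3=-(H0 / Q3) * (Fp - F / psi))
        # h4: sibling daughter at the diverging node
        put(1, h4=1.0,
            q1=-H0 * ((1.0 - F) / Q4 + Fp * psi / Q4),
            q4=H0 * (1.0 - F) * Q1 / Q4**2,
            q3=H0 * Fp / Q4)
        # h5: converging node 2-3-5 fed by vessels 2 (H0) and 3 (delayed h3)
        put(2, h5=Q5, h3=-Q3 * edel3, q2=-H0, q3=-H3, q5=H5)
        put(11, q1=1.0, q3=-1.0, q4=-1.0)
        put(12, q2=1.0, q3=1.0, q5=-1.0)
        put(8, q4=R[4], r4=Q4, q3=-R[3], r3=-Q3, q5=-R[5], r5=-Q5)
        loop_in = dict(q1=R[1], q2=-1.0, q3=R[3], r3=Q3)
    # h6: converging node 4-5-6 (both cases)
    put(3, h6=Q6, h4=-Q4 * edel4, h5=-Q5 * edel5, q4=-H4, q5=-H5, q6=H6)
    # resistance responses r_i = c_i h_i
    for k, (i, Qi, ai, Hi) in enumerate(
        [(3, Q3, 1.0, H3), (4, Q4, alpha, H4), (5, Q5, 1.0, H5), (6, Q6, 1.0, H6)]
    ):
        ci = _rcoef(lam, Qi, ai, Hi, D, mu0)
        A[4 + k, ix[f"r{i}"]] = 1.0
        A[4 + k, ix[f"h{i}"]] = -ci
    # boundary conditions
    if bc == "pressure":
        put(9, **loop_in)
        put(10, q1=R[1], q4=R[4], r4=Q4, q6=R[6], r6=Q6)
    elif bc == "flux":
        put(9, q1=1.0)
        put(10, q2=1.0)
    else:
        raise ValueError(f"unknown bc {bc!r}")
    put(13, q4=1.0, q5=1.0, q6=-1.0)
    return A


def nontrivial_det(lam: complex, base: SteadyState, bc: str = "pressure",
                   rule: Optional[SplitRule] = None) -> complex:
    return _scaled_det(nontrivial_system_matrix(lam, base, bc, rule))


def _newton_root(f, lam0: complex, tol: float = 1e-12, maxit: int = 60
                 ) -> Optional[complex]:
    lam = complex(lam0)
    for _ in range(maxit):
        fv = f(lam)
        h = 1e-7 * max(1.0, abs(lam))
        df = (f(lam + h) - f(lam - h)) / (2.0 * h)
        if df == 0:
            return None
        step = fv / df
        lam = lam - step
        if abs(step) < tol * max(1.0, abs(lam)):
            return lam
    return None


def _nullvector(A: np.ndarray) -> np.ndarray:
    _, _, vh = np.linalg.svd(A)
    return vh[-1].conj()


def growth_rate(
    base: SteadyState,
    bc: str = "pressure",
    rule: Optional[SplitRule] = None,
    sigma_range: Tuple[float, float] = (-0.1, 0.15),
    omega_range: Tuple[float, float] = (1e-3, 0.5),
    n_scan: int = 40,
    seed: Optional[complex] = None,
) -> Eigenmode:
    """Dominant oscillatory eigenmode of a nontrivial steady state.

    Scans ``|det A|`` over a rectangle in the upper half ``lam`` plane (modes
    come in conjugate pairs), polishes local minima by complex Newton, and
    returns the converged root with the largest growth rate.  ``seed`` (e.g. a
    simulation-estimated ``sigma + i omega``) is polished first.
    """
    if rule is None:
        rule = split_rule_for_case(base.case, base.alpha, base.H0, base.D)

    def f(lam):
        return nontrivial_det(lam, base, bc, rule)

    roots: List[complex] = []

    def try_seed(lam0):
        lam = _newton_root(f, lam0)
        if lam is None:
            return
        if abs(f(lam)) > 1e-6:
            return
        if lam.imag < 0:
            lam = lam.conjugate()
        if not any(abs(lam - r) < 1e-8 * max(1.0, abs(r)) for r in roots):
            roots.append(lam)

    if seed is not None:
        try_seed(seed)
    sig = np.linspace(*sigma_range, n_scan)
    ome = np.geomspace(max(omega_range[0], 1e-4), omega_range[1], n_scan)
    vals = np.empty((n_scan, n_scan))
    for i, s in enumerate(sig):
        for j, w in enumerate(ome):
            vals[i, j] = abs(f(complex(s, w)))
    interior = np.ones_like(vals, bool)
    for k, mins in enumerate(np.argsort(vals, axis=None)[: 3 * n_scan]):
        i, j = np.unravel_index(mins, vals.shape)
        if 0 < i < n_scan - 1 and 0 < j < n_scan - 1:
            nb = vals[i - 1 : i + 2, j - 1 : j + 2]
            if vals[i, j] == nb.min():
                try_seed(complex(sig[i], ome[j]))
        if len(roots) >= 6:
            break
    if not roots:
        raise RuntimeError(
            f"no oscillatory eigenvalue found for base at alpha={base.alpha}, "
            f"H0={base.H0}, case {base.case}"
        )
    lam = max(roots, key=lambda z: z.real)
    v = _nullvector(nontrivial_system_matrix(lam, base, bc, rule))
    return Eigenmode(lam=lam, v=v, bc=bc, base=base)


# ---------------------------------------------------------------------------
# argument-principle box count
# ---------------------------------------------------------------------------

def count_complex_roots(
    f,
    sigma_range: Tuple[float, float],
    omega_range: Tuple[float, float],
    n_edge: int = 600,
    max_refine: int = 14,
) -> int:
    """Number of zeros of analytic ``f`` inside a rectangle of the lam plane.

    Winding number of ``f`` around the positively-oriented boundary, with
    adaptive bisection of edge segments whose phase jump exceeds pi/2.
    """
    s0, s1 = sigma_range
    w0, w1 = omega_range
    corners = [complex(s0, w0), complex(s1, w0), complex(s1, w1), complex(s0, w1)]
    pts: List[complex] = []
    for a, b in zip(corners, corners[1:] + corners[:1]):
        for t in np.linspace(0.0, 1.0, n_edge, endpoint=False):
            pts.append(a + t * (b - a))
    vals = [f(z) for z in pts]
    total = 0.0
    n = len(pts)
    for k in range(n):
        z0, z1 = pts[k], pts[(k + 1) % n]
        v0, v1 = vals[k], vals[(k + 1) % n]
        total += _phase_change(f, z0, z1, v0, v1, max_refine)
    return int(round(total / (2.0 * math.pi)))


def _phase_change(f, z0, z1, v0, v1, depth):
    d = cmath.phase(v1 / v0) if v0 != 0 and v1 != 0 else math.pi
    if abs(d) <= math.pi / 2 or depth == 0:
        return d
    zm = 0.5 * (z0 + z1)
    vm = f(zm)
    return (_phase_change(f, z0, zm, v0, vm, depth - 1)
            + _phase_change(f, zm, z1, vm, v1, depth - 1))


# ---------------------------------------------------------------------------
# iso-growth-rate contours
# ---------------------------------------------------------------------------

def _solve_base(alpha, H0, case, D, rule_variant, guess):
    rule = split_rule_for_case(case, alpha, H0, D, rule_variant)
    return solve_nontrivial(alpha, H0, case, guess, D, rule), rule


def iso_sigma_point(
    sigma: float,
    alpha: float,
    case: str,
    H0_guess: float,
    omega_guess: float,
    state_guess: Tuple[float, float],
    D: float = 20.0,
    bc: str = "pressure",
    rule_variant: str = "nonsmooth",
) -> dict:
    """Solve ``Re det A = Im det A = 0`` for ``(H0, omega)`` at fixed alpha.

    ``state_guess = (Q1, Q3)`` seeds the inner steady-state solve.
    """
    inner = {"xy": tuple(state_guess)}

    def eqs(v):
        H0, om = v
        if not 0.005 < H0 < 0.995 or om <= 0.0:
            return np.array([1e3, 1e3])
        try:
            base, rule = _solve_base(alpha, H0, case, D, rule_variant, inner["xy"])
            inner["xy"] = (base.Q1, base.Q3)
            d = nontrivial_det(complex(sigma, om), base, bc, rule)
        except (RuntimeError, ValueError):
            return np.array([1e3, 1e3])
        return np.array([d.real, d.imag])

    sol = root(eqs, np.array([H0_guess, omega_guess]), method="hybr", tol=1e-12)
    r = eqs(sol.x)
    if not sol.success or np.max(np.abs(r)) > 1e-8:
        raise RuntimeError(
            f"iso-sigma solve failed at alpha={alpha}: residual {r}"
        )
    H0, om = float(sol.x[0]), float(sol.x[1])
    base, _ = _solve_base(alpha, H0, case, D, rule_variant, inner["xy"])
    return {"alpha": alpha, "H0": H0, "omega": om,
            "Q1": base.Q1, "Q3": base.Q3}


def iso_sigma_contour(
    sigma: float,
    case: str,
    alphas: Sequence[float],
    seed_point: dict,
    D: float = 20.0,
    bc: str = "pressure",
    rule_variant: str = "nonsmooth",
) -> List[dict]:
    """Continue an iso-growth-rate contour over a sequence of alpha values.

    ``seed_point`` must contain ``H0``, ``omega``, ``Q1``, ``Q3`` at the first
    alpha (typically from :func:`growth_rate` at a simulated parameter point).
    Continuation stops where the two-equation solve fails (for the nonsmooth
    rule, contours terminate on the skimming threshold instead of closing).
    """
    out: List[dict] = []
    H0g, omg = seed_point["H0"], seed_point["omega"]
    xy = (seed_point["Q1"], seed_point["Q3"])
    a_prev: Optional[float] = None
    for a in alphas:
        try:
            pt = iso_sigma_point(sigma, a, case, H0g, omg, xy, D, bc, rule_variant)
        except RuntimeError:
            # adaptive sub-stepping in alpha from the last converged point
            pt = None
            if a_prev is not None:
                lo, n_sub = a_prev, 2
                while n_sub <= 16 and pt is None:
                    ok = True
                    H0s, oms, xys = H0g, omg, xy
                    for k in range(1, n_sub + 1):
                        am = lo + (a - lo) * k / n_sub
                        try:
                            sub = iso_sigma_point(sigma, am, case, H0s, oms,
                                                  xys, D, bc, rule_variant)
                        except RuntimeError:
                            ok = False
                            break
                        H0s, oms, xys = sub["H0"], sub["omega"], (sub["Q1"], sub["Q3"])
                    if ok:
                        pt = sub
                    else:
                        n_sub *= 2
            if pt is None:
                break
        out.append(pt)
        H0g, omg, xy = pt["H0"], pt["omega"], (pt["Q1"], pt["Q3"])
        a_prev = a
    return out
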