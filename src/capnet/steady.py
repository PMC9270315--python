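"""Steady states of the three-node network and their bifurcations.

Under equal inlet pressures the network always admits the *trivial* steady
state with no flow (and no haematocrit) in the redundant vessel 3.  Two
families of nontrivial states exist, distinguished by the flow direction in
vessel 3:

* Case I  — bottom-to-top flow (node 2-3-5 towards node 1-3-4); the
  haematocrit splitting rule acts at node 2-3-5 with flux ratio
  ``psi = Q3/Q2 = Q3``.
* Case II — top-to-bottom flow; the splitting rule acts at node 1-3-4 with
  ``psi* = Q3/Q1``.

Within a case ``Q3`` is stored positive; in bifurcation diagrams Case I is
plotted with negative sign (matching the sign convention of the flux solver in
:mod:`capnet.network`).

Each nontrivial state solves two residual equations in ``(Q1, Q3)``: the
pressure identity around the internal loop and the equal-inlet-pressure
identity, with the vessel haematocrits eliminated through the splitting rule
and red-cell mass balances.  Branches are tracked in ``H0`` by
pseudo-arclength continuation; the branch directed toward the
higher-resistance main branch terminates on the trivial state at a
transcritical bifurcation ``H_T``, while the branch directed toward the
lower-resistance main branch ends at a fold ``H_S < H_T``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq, root

from .network import NetworkSpec, scaled_resistance, trivial_Q1
from .rheology import relative_viscosity
from .splitting import SplitRule, make_split_rule, split_fraction

__all__ = [
    "SteadyState",
    "Branch",
    "split_rule_for_case",
    "trivial_state",
    "nontrivial_residual",
    "solve_nontrivial",
    "find_starting_state",
    "continue_branch",
    "skimming_threshold_H0",
    "bifurcation_points",
    "skimming_threshold_curves",
]

RESIDUAL_TOL = 1e-10


@dataclass
class SteadyState:
    """A steady solution ``V0 = (Q1, Q3, H3, H4, H5)`` of the network.

    ``case`` is ``'trivial'``, ``'I'`` or ``'II'``; ``Q3 >= 0`` within a case.
    Vessel 6 always carries haematocrit ``H0`` (global red-cell balance) and
    flux ``1 + Q1``.
    """

    case: str
    alpha: float
    H0: float
    D: float
    Q1: float
    Q3: float
    H3: float
    H4: float
    H5: float

    @property
    def Q4(self) -> float:
        if self.case == "II":
            return self.Q1 - self.Q3
        return self.Q1 + self.Q3

    @property
    def Q5(self) -> float:
        if self.case == "II":
            return 1.0 + self.Q3
        return 1.0 - self.Q3

    @property
    def Q6(self) -> float:
        return 1.0 + self.Q1

    @property
    def H6(self) -> float:
        return self.H0

    @property
    def signed_Q3(self) -> float:
        """Q3 in the diagram sign convention (Case I negative, II positive)."""
        return -self.Q3 if self.case == "I" else self.Q3

    def haematocrit(self, i: int) -> float:
        return (0.0, self.H0, self.H0, self.H3, self.H4, self.H5, self.H6)[i]

    def flux(self, i: int) -> float:
        return (0.0, self.Q1, 1.0, self.Q3, self.Q4, self.Q5, self.Q6)[i]

    def resistance(self, i: int) -> float:
        spec = NetworkSpec(alpha=self.alpha, H0=self.H0, D=self.D)
        return scaled_resistance(spec, i, self.haematocrit(i))


def split_rule_for_case(
    case: str, alpha: float, H0: float, D: float = 20.0, variant: str = "nonsmooth"
) -> SplitRule:
    """Splitting rule at the diverging node of the given case.

    Case I diverges at node 2-3-5 (parent 2, daughters 3 and 5, all diameter
    ``D``); Case II diverges at node 1-3-4 (parent 1 and daughter 4 of
    diameter ``alpha*D``, daughter 3 of diameter ``D``).
    """
    if case == "I":
        return make_split_rule(D, D, D, H0, variant=variant)
    if case == "II":
        return make_split_rule(alpha * D, D, alpha * D, H0, variant=variant)
    raise ValueError(f"no splitting rule for case {case!r}")


def trivial_state(alpha: float, H0: float, D: float = 20.0) -> SteadyState:
    """Closed-form zero-redundant-flow equilibrium."""
    return SteadyState(
        case="trivial", alpha=alpha, H0=H0, D=D,
        Q1=trivial_Q1(alpha, H0, D), Q3=0.0, H3=0.0, H4=H0, H5=H0,
    )


def _F_extended(rule: SplitRule, psi: float) -> float:
    """Splitting fraction extended smoothly outside [0, 1] for continuation."""
    if rule.variant == "smooth":
        if psi < rule.psiL:
            return rule.a * psi**3
        if psi > rule.psiU:
            return 1.0 - rule.b * (1.0 - psi) ** 3
        return split_fraction(rule, psi)
    if psi < rule.psi0:
        return 0.0
    if psi > 1.0 - rule.psi0:
        return 1.0
    return split_fraction(rule, psi)


def _clip_H(H: float) -> float:
    return min(max(H, 0.0), 0.999)


def case_haematocrits(
    case: str, Q1: float, Q3: float, H0: float, rule: SplitRule
) -> Tuple[float, float, float]:
    """(H3, H4, H5) eliminated via the splitting rule and red-cell balances."""
    if case == "I":
        psi = Q3
        F = _F_extended(rule, psi)
        H3 = H0 * F / Q3 if Q3 > 0 else 0.0
        H5 = H0 * (1.0 - F) / (1.0 - Q3)
        H4 = H0 * (Q1 + F) / (Q1 + Q3)
    elif case == "II":
        psi = Q3 / Q1
        F = _F_extended(rule, psi)
        H3 = H0 * Q1 * F / Q3 if Q3 > 0 else 0.0
        H4 = H0 * Q1 * (1.0 - F) / (Q1 - Q3)
        H5 = H0 * (1.0 + Q1 * F) / (1.0 + Q3)
    else:
        raise ValueError(f"unknown case {case!r}")
    return _clip_H(H3), _clip_H(H4), _clip_H(H5)


def nontrivial_residual(
    V: Tuple[float, float],
    case: str,
    alpha: float,
    H0: float,
    D: float = 20.0,
    rule: SplitRule | None = None,
) -> np.ndarray:
    """Residual pair (internal-loop and equal-inlet-pressure identities).

    ``V = (Q1, Q3)`` with ``Q3 >= 0`` in the case's own flow direction.  The
    residuals are written in unscaled viscosity units: multiplying the scaled
    pressure identities through by ``mu(H0, D)`` gives, for Case I::

        mu(H4, aD)/a^4 * Q1 + [mu(H3,D) + mu(H4,aD)/a^4 + mu(H5,D)] * Q3
            - mu(H5, D) = 0
        mu(H0, aD)/a^4 * Q1 - mu(H3, D)*Q3 - mu(H0, D) = 0

    and for Case II the signs of the ``Q3`` terms flip.
    """
    Q1, Q3 = float(V[0]), float(V[1])
    if rule is None:
        rule = split_rule_for_case(case, alpha, H0, D)
    if Q1 <= 0.0:
        raise ValueError("Q1 must be positive")
    Q4 = Q1 - Q3 if case == "II" else Q1 + Q3
    Q5 = 1.0 + Q3 if case == "II" else 1.0 - Q3
    if Q4 <= 0.0 or Q5 <= 0.0:
        raise ValueError("daughter fluxes must remain positive")
    H3, H4, H5 = case_haematocrits(case, Q1, Q3, H0, rule)
    a4 = alpha**4
    mu3 = relative_viscosity(H3, D)
    mu4 = relative_viscosity(H4, alpha * D) / a4
    mu5 = relative_viscosity(H5, D)
    mu1 = relative_viscosity(H0, alpha * D) / a4
    mu0 = relative_viscosity(H0, D)
    s = -1.0 if case == "II" else 1.0
    r_loop = mu4 * Q1 + s * (mu3 + mu4 + mu5) * Q3 - mu5
    r_inlet = mu1 * Q1 - s * mu3 * Q3 - mu0
    return np.array([r_loop, r_inlet])


def solve_nontrivial(
    alpha: float,
    H0: float,
    case: str,
    guess: Tuple[float, float],
    D: float = 20.0,
    rule: SplitRule | None = None,
    tol: float = RESIDUAL_TOL,
) -> SteadyState:
    """Newton solve for a nontrivial steady state from ``guess = (Q1, Q3)``."""
    if rule is None:
        rule = split_rule_for_case(case, alpha, H0, D)

    def fun(x):
        try:
            return nontrivial_residual(x, case, alpha, H0, D, rule)
        except ValueError:
            return np.array([1e6, 1e6])

    sol = root(fun, np.asarray(guess, float), method="hybr", tol=1e-13)
    res = fun(sol.x)
    if not sol.success or np.max(np.abs(res)) > tol:
        raise RuntimeError(
            f"nontrivial steady-state solve failed at alpha={alpha}, H0={H0}, "
            f"case {case}: residual {res}, last iterate {sol.x}"
        )
    Q1, Q3 = float(sol.x[0]), float(sol.x[1])
    if Q3 < 1e-10:
        raise RuntimeError(
            f"solver converged to the trivial solution (Q3={Q3}) at "
            f"alpha={alpha}, H0={H0}, case {case}"
        )
    H3, H4, H5 = case_haematocrits(case, Q1, Q3, H0, rule)
    return SteadyState(case=case, alpha=alpha, H0=H0, D=D,
                       Q1=Q1, Q3=Q3, H3=H3, H4=H4, H5=H5)


def _default_guesses(case: str, alpha: float, H0: float, D: float):
    Q1t = trivial_Q1(alpha, H0, D)
    if case == "I":
        return [(Q1t + q3, q3) for q3 in (0.02, 0.05, 0.1, 0.2, 0.3, 0.45)]
    return [(Q1t, f * Q1t) for f in (0.02, 0.05, 0.12, 0.3, 0.6, 0.85)]


def find_starting_state(
    alpha: float, case: str, D: float = 20.0, H0_start: float = 0.6,
    rule_variant: str = "nonsmooth",
) -> SteadyState:
    """Locate a nontrivial state at a high inlet haematocrit to seed a branch."""
    rule = split_rule_for_case(case, alpha, H0_start, D, rule_variant)
    last_err: Exception | None = None
    for guess in _default_guesses(case, alpha, H0_start, D):
        try:
            st = solve_nontrivial(alpha, H0_start, case, guess, D, rule)
        except RuntimeError as err:
            last_err = err
            continue
        if st.Q3 > 1e-8:
            return st
    raise RuntimeError(
        f"no nontrivial case-{case} state found at alpha={alpha}, "
        f"H0={H0_start}: {last_err}"
    )


@dataclass
class Branch:
    """A continuation branch in ``H0`` at fixed ``alpha``."""

    case: str
    alpha: float
    D: float
    H0: np.ndarray
    Q1: np.ndarray
    Q3: np.ndarray
    terminated_by: str = "end"  # 'transcritical' | 'fold' | 'end' | 'stall'
    event_H0: Optional[float] = None

    @property
    def signed_Q3(self) -> np.ndarray:
        return -self.Q3 if self.case == "I" else self.Q3


def continue_branch(
    alpha: float,
    case: str,
    H0_start: float = 0.6,
    H0_end: float = 0.05,
    D: float = 20.0,
    ds: float = 4e-3,
    max_steps: int = 4000,
    rule_variant: str = "nonsmooth",
) -> Branch:
    """Pseudo-arclength continuation of a nontrivial branch, decreasing ``H0``.

    Terminates with a transcritical event when ``Q3`` reaches zero, with a
    fold event when ``H0`` turns around and the branch is followed past the
    turning point, or at ``H0_end``.
    """
    st = find_starting_state(alpha, case, D, H0_start, rule_variant)
    u = np.array([st.Q1, st.Q3, st.H0])
    pts = [u.copy()]

    def G(v):
        Q1, Q3, H0 = v
        try:
            rule = split_rule_for_case(case, alpha, H0, D, rule_variant)
            return nontrivial_residual((Q1, Q3), case, alpha, H0, D, rule)
        except (ValueError, RuntimeError):
            return np.array([1e6, 1e6])

    def jac(v, h=1e-8):
        J = np.empty((2, 3))
        f0 = G(v)
        for j in range(3):
            dv = v.copy()
            dv[j] += h * max(1.0, abs(v[j]))
            J[:, j] = (G(dv) - f0) / (dv[j] - v[j])
        return J

    # initial tangent: decrease H0
    t = _nullspace_tangent(jac(u))
    if t[2] > 0:
        t = -t

    step = ds
    fold_seen = False
    status, event = "end", None
    for _ in range(max_steps):
        pred = u + step * t

        def aug(v, u0=u.copy(), t0=t.copy()):
            return np.append(G(v), np.dot(v - u0, t0) - step)

        sol = root(aug, pred, method="hybr", tol=1e-13)
        if not sol.success or np.max(np.abs(G(sol.x))) > 1e-9:
            step *= 0.5
            if step < ds / 1024:
                status = "stall"
                break
            continue
        unew = sol.x
        tnew = _nullspace_tangent(jac(unew))
        if np.dot(tnew, t) < 0:
            tnew = -tnew
        # transcritical: Q3 through zero
        if unew[1] <= 0.0:
            lam = u[1] / (u[1] - unew[1])
            event = float(u[2] + lam * (unew[2] - u[2]))
            pts.append(unew)
            status = "transcritical"
            break
        # fold: H0 direction reverses
        if t[2] < 0 <= tnew[2] or (fold_seen and unew[2] >= H0_start):
            fold_seen = True
            pts.append(unew)
            if len(pts) >= 3:
                event = _fold_from_points(np.array(pts[-3:]))
                status = "fold"
                break
        else:
            pts.append(unew)
        u, t = unew, tnew
        step = min(ds, step * 1.4)
        if u[2] <= H0_end:
            break
    arr = np.array(pts)
    return Branch(case=case, alpha=alpha, D=D,
                  H0=arr[:, 2], Q1=arr[:, 0], Q3=arr[:, 1],
                  terminated_by=status, event_H0=event)


def _nullspace_tangent(J: np.ndarray) -> np.ndarray:
    _, _, vt = np.linalg.svd(J)
    t = vt[-1]
    return t / np.linalg.norm(t)


def _fold_from_points(pts: np.ndarray) -> float:
    """Quadratic fit of H0 against arclength through three branch points."""
    s = np.zeros(3)
    for k in (1, 2):
        s[k] = s[k - 1] + np.linalg.norm(pts[k] - pts[k - 1])
    coef = np.polyfit(s, pts[:, 2], 2)
    if abs(coef[0]) < 1e-30:
        return float(np.min(pts[:, 2]))
    s_ext = -coef[1] / (2.0 * coef[0])
    s_ext = min(max(s_ext, s[0]), s[2])
    return float(np.polyval(coef, s_ext))


def _refine_transcritical(alpha, D, branch, rule_variant="nonsmooth"):
    """Bisection on the sign of Q3 of the continued solution near the event."""
    # bracket around the linearly interpolated event
    i = np.argmin(np.abs(branch.Q3))
    seed = (branch.Q1[i], max(branch.Q3[i], 1e-4))

    def q3_at(H0):
        rule = split_rule_for_case(branch.case, alpha, H0, D, rule_variant)
        sol = root(
            lambda x: _residual_safe(x, branch.case, alpha, H0, D, rule),
            np.asarray(seed, float), method="hybr", tol=1e-13,
        )
        return sol.x[1]

    H_T = branch.event_H0
    lo, hi = H_T - 5e-3, H_T + 5e-3
    try:
        return brentq(q3_at, lo, hi, xtol=1e-8)
    except ValueError:
        return H_T


def _residual_safe(x, case, alpha, H0, D, rule):
    try:
        return nontrivial_residual(x, case, alpha, H0, D, rule)
    except ValueError:
        return np.array([1e6, 1e6])


def bifurcation_points(
    alpha: float, D: float = 20.0, H0_start: float = 0.6,
    rule_variant: str = "nonsmooth",
) -> dict:
    """Locate the transcritical (``H_T``) and fold (``H_S``) inlet haematocrits.

    For ``alpha < 1`` the higher-resistance main branch is the top one, so the
    transcritical branch is Case I and the folding branch Case II; for
    ``alpha > 1`` the roles are exchanged.
    """
    if alpha == 1.0:
        raise ValueError("alpha=1 is degenerate (equal branch resistances)")
    trans_case, fold_case = ("I", "II") if alpha < 1.0 else ("II", "I")
    btrans = continue_branch(alpha, trans_case, H0_start, D=D,
                             rule_variant=rule_variant)
    if btrans.terminated_by != "transcritical":
        raise RuntimeError(
            f"transcritical event not found for case {trans_case} at alpha={alpha}"
        )
    H_T = _refine_transcritical(alpha, D, btrans, rule_variant)
    bfold = continue_branch(alpha, fold_case, H0_start, D=D, ds=2e-3,
                            rule_variant=rule_variant)
    if bfold.terminated_by != "fold":
        raise RuntimeError(
            f"fold event not found for case {fold_case} at alpha={alpha}"
        )
    return {"H_T": float(H_T), "H_S": float(bfold.event_H0),
            "branch_T": btrans, "branch_S": bfold}


def skimming_threshold_H0(
    alpha: float, case: str, D: float = 20.0, H0_start: float = 0.6,
) -> float:
    """Inlet haematocrit at which a branch crosses its skimming threshold.

    On the threshold the flux ratio at the splitting node equals ``psi0``
    exactly: ``Q3 = 0.4/D`` for Case I (node 2-3-5) and ``Q3/Q1 = 0.4/(alpha*D)``
    for Case II (node 1-3-4).  Solved directly as a three-unknown system
    (Q1, Q3, H0) = (residuals, threshold condition).
    """
    st = find_starting_state(alpha, case, D, H0_start)

    def sys(v):
        Q1, Q3, H0 = v
        rule = split_rule_for_case(case, alpha, H0, D)
        r = _residual_safe((Q1, Q3), case, alpha, H0, D, rule)
        thr = Q3 - rule.psi0 * (1.0 if case == "I" else Q1)
        return np.append(r, thr)

    psi0 = split_rule_for_case(case, alpha, H0_start, D).psi0
    q3g = psi0 if case == "I" else psi0 * st.Q1
    sol = root(sys, np.array([st.Q1, q3g, H0_start * 0.7]), method="hybr", tol=1e-13)
    if not sol.success or np.max(np.abs(sys(sol.x))) > 1e-8:
        raise RuntimeError(f"skimming-threshold solve failed for case {case}")
    return float(sol.x[2])


def skimming_threshold_curves(
    alphas, D: float = 20.0
) -> dict:
    """Skimming-threshold curves H0(alpha) for both branch families."""
    out = {"I": [], "II": []}
    for case in ("I", "II"):
        for a in alphas:
            try:
                out[case].append((float(a), skimming_threshold_H0(a, case, D)))
            except RuntimeError:
                out[case].append((float(a), math.nan))
    return {k: np.array(v) for k, v in out.items()}
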