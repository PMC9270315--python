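"""Time-domain simulation of unsteady flow in the three-node network.

Each step performs, in order: (1) a nodal pressure solve with conductivities
from the current vessel-averaged viscosities; (2) flux and velocity updates;
(3) outlet-haematocrit evaluation by the method of characteristics — the
outlet value equals the inlet value one transit time ago, where the retarded
time ``tau`` solves the transit integral ``int_{t-tau}^{t} U ds = 1``;
(4) junction updates (red-cell mass balance at converging nodes, the
plasma-skimming rule at the diverging node); (5) explicit Euler updates of the
vessel-averaged haematocrit and viscosity.

The transit integral is accumulated trapezoidally over the discrete velocity
history; the crossing is located by sign change and, by default, snapped to
the first grid time past the crossing (``interp='grid'``), with sub-step
linear interpolation available as ``interp='linear'``.  The grid scheme is
the default because near-grazing limit cycles (where the redundant-vessel
flux dips towards zero) are sustained under it but can be captured by the
zero-flow equilibrium family under the interpolated scheme.  The search
starts from the previous step's retarded time, which keeps the cost per step
O(1) when the flow direction does not change.  Flow reversal inside a vessel
that has already established a direction is outside the model's scope and
aborts the run with the partial trajectory attached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .network import NetworkSpec, calibrate_deltaP
from .rheology import diameter_coefficients, relative_viscosity
from .splitting import SplitRule, split_fraction
from .steady import SteadyState, split_rule_for_case, trivial_state

__all__ = [
    "FlowReversalError",
    "Perturbation",
    "VesselHistory",
    "SimulationResult",
    "retarded_time",
    "junction_update",
    "Simulator",
    "simulate",
    "limit_cycle_metrics",
    "oscillation_metrics",
    "envelope_growth_rate",
]

# |Q3| above which the redundant vessel's flow direction counts as established;
# below it the sign may dither around zero while the vessel carries no
# haematocrit, which is harmless
_DIR_EPS = 1e-8


class FlowReversalError(RuntimeError):
    """Raised when a vessel's flow reverses mid-run (unsupported regime)."""

    def __init__(self, msg, result=None):
        super().__init__(msg)
        self.result = result


@dataclass(frozen=True)
class Perturbation:
    """Additive perturbation to the inlet haematocrit of one vessel.

    Applied during the first ``steps`` time steps only (the protocol used to
    probe stability of equilibria: ``magnitude = +-1e-6`` on vessel 2).
    """

    magnitude: float = 1e-6
    vessel: int = 2
    steps: int = 1


class VesselHistory:
    """Inlet-haematocrit and velocity history of one vessel.

    Supports the retarded-time lookup: ``outlet(t)`` returns the inlet
    haematocrit at ``t - tau(t)`` with ``tau`` the transit time, or the
    initial outlet value while the initial content has not yet cleared the
    vessel.
    """

    def __init__(self, t0: float, U0: float, Hin0: float, Hout0: float,
                 interp: str = "linear"):
        self.t: List[float] = [t0]
        self.U: List[float] = [U0]
        self.Hin: List[float] = [Hin0]
        self.cum: List[float] = [0.0]  # trapezoidal integral of |U|
        self.Hout0 = Hout0
        self._ptr = 0  # monotone search pointer for the retarded time
        self.interp = interp  # 'linear' | 'grid' (snap crossing to the grid)

    def append(self, t: float, U: float, Hin: float) -> None:
        dt = t - self.t[-1]
        self.cum.append(self.cum[-1] + 0.5 * (abs(U) + abs(self.U[-1])) * dt)
        self.t.append(t)
        self.U.append(U)
        self.Hin.append(Hin)

    def set_last_Hin(self, Hin: float) -> None:
        self.Hin[-1] = Hin

    def tau(self) -> Optional[float]:
        """Retarded transit time at the latest history point (None: transient)."""
        target = self.cum[-1] - 1.0
        if target < 0.0:
            return None
        k = self._ptr
        cum = self.cum
        n = len(cum) - 1
        while k < n and cum[k + 1] <= target:
            k += 1
        self._ptr = k
        # crossing within [t[k], t[k+1]]
        if k >= n:
            return 0.0
        if self.interp == "grid":
            # snap to the first grid time past the crossing
            return self.t[-1] - self.t[k + 1]
        dcum = cum[k + 1] - cum[k]
        frac = 0.0 if dcum <= 0.0 else (target - cum[k]) / dcum
        s = self.t[k] + frac * (self.t[k + 1] - self.t[k])
        return self.t[-1] - s

    def outlet(self) -> float:
        """Outlet haematocrit at the latest history point."""
        tau = self.tau()
        if tau is None:
            return self.Hout0
        s = self.t[-1] - tau
        k = self._ptr
        if k + 1 >= len(self.t):
            return self.Hin[-1]
        if self.interp == "grid":
            return self.Hin[k + 1]
        t0, t1 = self.t[k], self.t[k + 1]
        f = 0.0 if t1 == t0 else (s - t0) / (t1 - t0)
        return self.Hin[k] + f * (self.Hin[k + 1] - self.Hin[k])


def retarded_time(times, U, t=None) -> Optional[float]:
    """Transit time ``tau`` solving ``int_{t-tau}^{t} |U| ds = 1``.

    ``times``/``U`` are a discrete velocity history (the integral is
    trapezoidal, the crossing linearly interpolated).  Returns ``None`` while
    the accumulated travel is below one vessel length (initial transient).
    """
    h = VesselHistory(times[0], U[0], 0.0, 0.0)
    for tk, Uk in zip(times[1:], U[1:]):
        h.append(tk, Uk, 0.0)
    return h.tau()


def junction_update(
    Q_parents: Tuple[float, ...],
    H_parents: Tuple[float, ...],
    Q_daughters: Tuple[float, ...],
    rule: Optional[SplitRule] = None,
) -> Tuple[float, ...]:
    """Inlet haematocrit(s) of the daughter vessel(s) at a junction.

    Converging (two parents, one daughter): red-cell flux balance.  Diverging
    (one parent, two daughters, ``rule`` required): the splitting rule gives
    the favoured daughter (the first of ``Q_daughters``) the fraction
    ``F(psi)`` of the parent red-cell flux and its sibling the complement, so
    red-cell flux is conserved exactly.
    """
    rbc_in = sum(q * h for q, h in zip(Q_parents, H_parents))
    if len(Q_daughters) == 1:
        (qd,) = Q_daughters
        if qd <= 0.0:
            if abs(rbc_in) > 1e-15:
                raise ValueError("zero daughter flux with nonzero RBC flux")
            return (0.0,)
        return (rbc_in / qd,)
    if rule is None:
        raise ValueError("diverging junction requires a splitting rule")
    (qp,) = Q_parents
    q_fav, q_other = Q_daughters
    psi = min(max(q_fav / qp, 0.0), 1.0)
    F = split_fraction(rule, psi)
    H_fav = 0.0 if q_fav <= 0.0 or F == 0.0 else rbc_in * F / q_fav
    H_other = rbc_in * (1.0 - F) / q_other if q_other > 0.0 else 0.0
    return (H_fav, H_other)


@dataclass
class SimulationResult:
    """Trajectory of a network simulation (arrays indexed [step, vessel-1])."""

    times: np.ndarray
    Q: np.ndarray
    Hbar: np.ndarray
    Hin: np.ndarray
    Hout: np.ndarray
    mubar: np.ndarray
    pressures: np.ndarray  # columns p134, p235, p456
    metadata: dict = field(default_factory=dict)

    def series(self, name: str, vessel: int) -> np.ndarray:
        return getattr(self, name)[:, vessel - 1]

    def to_frame(self):
        """Tidy (time, vessel, variable, value) DataFrame."""
        import pandas as pd

        rows = []
        for name in ("Q", "Hbar", "Hin", "Hout", "mubar"):
            arr = getattr(self, name)
            for i in range(6):
                rows.append(
                    pd.DataFrame(
                        {"time": self.times, "vessel": i + 1,
                         "variable": name, "value": arr[:, i]}
                    )
                )
        return pd.concat(rows, ignore_index=True)


def per_cycle_amplitudes(
    t,
    y_seg,
    others: Optional[dict] = None,
    depth_fraction: float = 0.25,
    min_separation: float = 20.0,
) -> dict:
    """Per-cycle oscillation amplitudes segmented by deep troughs of ``y_seg``.

    Troughs are local minima within ``depth_fraction`` of the global range
    above the global minimum, at least ``min_separation`` time units apart
    (the deepest wins within a separation window); each pair of consecutive
    troughs bounds one full cycle.  Returns the trough times and, for
    ``y_seg`` and every series in ``others``, the per-cycle half-ranges.
    Robust for relaxation-type cycles with long dwell phases and for
    trajectories where the oscillatory epoch is finite.
    """
    t = np.asarray(t)
    y = np.asarray(y_seg)
    rng = float(np.max(y) - np.min(y))
    if rng <= 0.0:
        return {"trough_times": np.array([]), "amplitudes": {}}
    thresh = np.min(y) + depth_fraction * rng
    idx = np.nonzero((y[1:-1] < y[:-2]) & (y[1:-1] <= y[2:]) & (y[1:-1] < thresh))[0] + 1
    # merge troughs closer than min_separation, keeping the deepest
    merged: List[int] = []
    for i in idx:
        if merged and t[i] - t[merged[-1]] < min_separation:
            if y[i] < y[merged[-1]]:
                merged[-1] = i
        else:
            merged.append(i)
    series = {"seg": y}
    if others:
        series.update(others)
    amps = {k: [] for k in series}
    for a, b in zip(merged[:-1], merged[1:]):
        for k, s in series.items():
            seg = np.asarray(s)[a : b + 1]
            amps[k].append(0.5 * (np.max(seg) - np.min(seg)))
    return {
        "trough_times": t[merged],
        "amplitudes": {k: np.array(v) for k, v in amps.items()},
    }


def envelope_growth_rate(
    t,
    y,
    baseline: float,
    amp_min: float = 1e-9,
    amp_max: Optional[float] = None,
    t_min: float = 0.0,
) -> dict:
    """Exponential growth rate and frequency of a small oscillation.

    Fits ``log`` of the successive positive-deviation maxima of ``y -
    baseline`` against time (one maximum per oscillation period), restricted
    to the linear-growth window ``amp_min <= deviation <= amp_max`` and
    ``t >= t_min``.  Returns ``sigma`` (envelope growth rate), ``omega``
    (``2 pi`` over the mean maximum spacing) and the number of maxima used.
    """
    t = np.asarray(t)
    dev = np.asarray(y) - baseline
    pk = np.nonzero((dev[1:-1] > dev[:-2]) & (dev[1:-1] >= dev[2:]))[0] + 1
    keep = (dev[pk] >= amp_min) & (t[pk] >= t_min)
    if amp_max is not None:
        keep &= dev[pk] <= amp_max
    tp, ap = t[pk[keep]], dev[pk[keep]]
    if len(tp) < 4:
        raise ValueError("too few oscillation maxima in the fit window")
    slope, _ = np.polyfit(tp, np.log(ap), 1)
    spacing = np.diff(tp)
    return {
        "sigma": float(slope),
        "omega": float(2.0 * math.pi / np.mean(spacing)),
        "n_peaks": int(len(tp)),
    }


class Simulator:
    """Explicit-Euler integrator for the three-node network."""

    def __init__(
        self,
        spec: NetworkSpec,
        dt: float = 0.01,
        init: Optional[SteadyState] = None,
        rule_variant: str = "nonsmooth",
        deltaP: Optional[float] = None,
        interp: str = "grid",
    ):
        self.spec = spec
        self.dt = float(dt)
        self.rule_variant = rule_variant
        self.interp = interp
        base = init if init is not None else trivial_state(spec.alpha, spec.H0, spec.D)
        self.base = base
        if deltaP is not None:
            self.deltaP = float(deltaP)
        elif base.case == "trivial":
            self.deltaP = calibrate_deltaP(spec)
        else:
            # bottom-path pressure drop of the base state, so that the base
            # state is an exact equilibrium in the Q2^(0)=1 normalisation
            self.deltaP = (
                1.0
                + base.resistance(5) * base.Q5
                + base.resistance(6) * base.Q6
            )
        self.rule235 = split_rule_for_case("I", spec.alpha, spec.H0, spec.D,
                                           rule_variant)
        self.rule134 = split_rule_for_case("II", spec.alpha, spec.H0, spec.D,
                                           rule_variant)
        self.mu0 = spec.mu0()
        # per-vessel constants
        self.alpha_i = [None] + [spec.alpha_i(i) for i in range(1, 7)]
        self.mucoef = [None]
        self.Cexp = [None]
        for i in range(1, 7):
            p = diameter_coefficients(spec.alpha_i(i) * spec.D)
            self.mucoef.append(
                p.eta * p.beta**2 * (p.eta45 - 1.0) / (0.55**p.C - 1.0)
            )
            self.Cexp.append(p.C)
        # state
        self.t = 0.0
        self.Hbar = [None] + [base.haematocrit(i) for i in range(1, 7)]
        self.Hin = list(self.Hbar)
        self.Hout = list(self.Hbar)
        self.mubar = [None] + [
            relative_viscosity(base.haematocrit(i), spec.alpha_i(i) * spec.D)
            for i in range(1, 7)
        ]
        signedQ3 = base.signed_Q3 if base.case != "trivial" else 0.0
        self.dir3 = 0 if abs(signedQ3) < _DIR_EPS else (1 if signedQ3 > 0 else -1)
        self._dir3_locked = self.dir3 != 0
        self.hist = [None] + [
            VesselHistory(0.0, 0.0, self.Hin[i], self.Hout[i], interp=interp)
            for i in range(1, 7)
        ]
        # seed histories with the base-state velocities
        Q = self._fluxes()
        for i in range(1, 7):
            self.hist[i].U[0] = Q[i] / self.alpha_i[i] ** 2
        self.Q = Q
        self._step_count = 0
        # running maxima of the per-step conservation residuals
        self.max_node_residual = 0.0
        self.max_rbc_residual = 0.0

    # -- one full step ----------------------------------------------------
    def _pressures(self) -> Tuple[float, float, float]:
        K = [None] + [
            self.alpha_i[i] ** 4 * self.mu0 / self.mubar[i] for i in range(1, 7)
        ]
        K1, K2, K3, K4, K5, K6 = K[1:7]
        pin, pout = self.deltaP, 0.0
        # direct elimination of the 3x3 junction system
        a11, a12, a13 = K1 + K3 + K4, -K3, -K4
        a21, a22, a23 = -K3, K2 + K3 + K5, -K5
        a31, a32, a33 = -K4, -K5, K4 + K5 + K6
        b1, b2, b3 = K1 * pin, K2 * pin, K6 * pout
        det = (a11 * (a22 * a33 - a23 * a32)
               - a12 * (a21 * a33 - a23 * a31)
               + a13 * (a21 * a32 - a22 * a31))
        p134 = (b1 * (a22 * a33 - a23 * a32)
                - a12 * (b2 * a33 - a23 * b3)
                + a13 * (b2 * a32 - a22 * b3)) / det
        p235 = (a11 * (b2 * a33 - a23 * b3)
                - b1 * (a21 * a33 - a23 * a31)
                + a13 * (a21 * b3 - b2 * a31)) / det
        p456 = (a11 * (a22 * b3 - b2 * a32)
                - a12 * (a21 * b3 - b2 * a31)
                + b1 * (a21 * a32 - a22 * a31)) / det
        self.K = K
        return p134, p235, p456

    def _fluxes(self) -> List[float]:
        p134, p235, p456 = self._pressures()
        self.p = (p134, p235, p456)
        K = self.K
        pin, pout = self.deltaP, 0.0
        return [
            0.0,
            K[1] * (pin - p134),
            K[2] * (pin - p235),
            K[3] * (p134 - p235),
            K[4] * (p134 - p456),
            K[5] * (p235 - p456),
            K[6] * (p456 - pout),
        ]

    def step(self, Hin_override: Optional[Dict[int, float]] = None) -> None:
        """Advance the state by one time step."""
        dt = self.dt
        Q = self._fluxes()
        self.Q = Q
        # flow-direction bookkeeping
        for i in (1, 2, 4, 5, 6):
            if Q[i] <= 0.0:
                raise FlowReversalError(f"flux reversal in vessel {i} at t={self.t}")
        q3 = Q[3]
        if self._dir3_locked:
            if q3 * self.dir3 < 0.0 and abs(q3) > _DIR_EPS:
                raise FlowReversalError(f"flux reversal in vessel 3 at t={self.t}")
        else:
            self.dir3 = 0 if q3 == 0.0 else (1 if q3 > 0 else -1)
            if abs(q3) > _DIR_EPS:
                self._dir3_locked = True
        t_new = self.t + dt
        # Kirchhoff residuals of the pressure solve (vessel-3 sign: N134->N235)
        self.max_node_residual = max(
            self.max_node_residual,
            abs(Q[1] - q3 - Q[4]),
            abs(Q[2] + q3 - Q[5]),
            abs(Q[4] + Q[5] - Q[6]),
        )

        # record velocities; Hin values are filled after the junction update
        for i in range(1, 7):
            U = Q[i] / self.alpha_i[i] ** 2
            self.hist[i].append(t_new, U, self.Hin[i])

        # outlet haematocrits via retarded time
        for i in range(1, 7):
            self.Hout[i] = self.hist[i].outlet()

        # junction updates -> inlet haematocrits
        H0 = self.spec.H0
        Hin = self.Hin
        Hin[1] = H0
        Hin[2] = H0
        aq3 = abs(q3)
        if self.dir3 < 0:  # Case I: node 2-3-5 diverges, node 1-3-4 converges
            Q5 = Q[5]
            h3, h5 = junction_update((Q[2],), (self.Hout[2],), (aq3, Q5),
                                     self.rule235)
            Hin[3], Hin[5] = h3, h5
            (Hin[4],) = junction_update(
                (Q[1], aq3), (self.Hout[1], self.Hout[3]), (Q[4],)
            )
        elif self.dir3 > 0:  # Case II: node 1-3-4 diverges, node 2-3-5 converges
            h3, h4 = junction_update((Q[1],), (self.Hout[1],), (aq3, Q[4]),
                                     self.rule134)
            Hin[3], Hin[4] = h3, h4
            (Hin[5],) = junction_update(
                (Q[2], aq3), (self.Hout[2], self.Hout[3]), (Q[5],)
            )
        else:  # no established flow in vessel 3
            Hin[3] = 0.0
            Hin[4] = self.Hout[1]
            Hin[5] = self.Hout[2]
        (Hin[6],) = junction_update(
            (Q[4], Q[5]), (self.Hout[4], self.Hout[5]), (Q[6],)
        )
        # red-cell flux balance across the junction updates
        if self.dir3 < 0:
            rbc = max(
                abs(Q[2] * self.Hout[2] - aq3 * Hin[3] - Q[5] * Hin[5]),
                abs(Q[1] * self.Hout[1] + aq3 * self.Hout[3] - Q[4] * Hin[4]),
            )
        elif self.dir3 > 0:
            rbc = max(
                abs(Q[1] * self.Hout[1] - aq3 * Hin[3] - Q[4] * Hin[4]),
                abs(Q[2] * self.Hout[2] + aq3 * self.Hout[3] - Q[5] * Hin[5]),
            )
        else:
            rbc = 0.0
        rbc = max(
            rbc, abs(Q[4] * self.Hout[4] + Q[5] * self.Hout[5] - Q[6] * Hin[6])
        )
        self.max_rbc_residual = max(self.max_rbc_residual, rbc)
        if Hin_override:
            for i, v in Hin_override.items():
                Hin[i] = v
        for i in range(1, 7):
            if Hin[i] < 0.0:
                Hin[i] = 0.0
            elif Hin[i] > 1.0:
                Hin[i] = 1.0
            self.hist[i].set_last_Hin(Hin[i])

        # Euler updates of averaged haematocrit and viscosity
        for i in range(1, 7):
            U = abs(Q[i]) / self.alpha_i[i] ** 2
            self.Hbar[i] += dt * U * (Hin[i] - self.Hout[i])
            if self.Hbar[i] < 0.0:
                self.Hbar[i] = 0.0
            elif self.Hbar[i] > 1.0:
                self.Hbar[i] = 1.0
            C = self.Cexp[i]
            self.mubar[i] += dt * U * self.mucoef[i] * (
                (1.0 - Hin[i]) ** C - (1.0 - Hout_safe(self.Hout[i])) ** C
            )
        self.t = t_new
        self._step_count += 1


def Hout_safe(H: float) -> float:
    return min(max(H, 0.0), 0.999999)


def simulate(
    spec: NetworkSpec,
    T: float,
    dt: float = 0.01,
    perturbation: Optional[Perturbation] = None,
    init: Optional[SteadyState] = None,
    rule_variant: str = "nonsmooth",
    deltaP: Optional[float] = None,
    save_stride: int = 1,
    interp: str = "grid",
) -> SimulationResult:
    """Run the network simulation for ``T`` dimensionless time units.

    The trajectory is deterministic in ``(spec, T, dt, perturbation, init)``.
    A flow reversal aborts with :class:`FlowReversalError` carrying the
    partial trajectory in its ``result`` attribute.
    """
    simr = Simulator(spec, dt=dt, init=init, rule_variant=rule_variant,
                     deltaP=deltaP, interp=interp)
    n_steps = int(round(T / dt))
    times, rows = [], {k: [] for k in ("Q", "Hbar", "Hin", "Hout", "mubar", "p")}

    def record():
        times.append(simr.t)
        rows["Q"].append(simr.Q[1:7])
        rows["Hbar"].append(list(simr.Hbar[1:7]))
        rows["Hin"].append(list(simr.Hin[1:7]))
        rows["Hout"].append(list(simr.Hout[1:7]))
        rows["mubar"].append(list(simr.mubar[1:7]))
        rows["p"].append(list(getattr(simr, "p", (0.0, 0.0, 0.0))))

    record()
    meta = {
        "alpha": spec.alpha, "H0": spec.H0, "D": spec.D, "dt": dt, "T": T,
        "bc_type": spec.bc_type, "rule_variant": rule_variant,
        "deltaP": simr.deltaP,
        "init_case": simr.base.case,
        "perturbation": None if perturbation is None else {
            "magnitude": perturbation.magnitude, "vessel": perturbation.vessel,
            "steps": perturbation.steps},
    }

    def build():
        meta["max_node_residual"] = simr.max_node_residual
        meta["max_rbc_residual"] = simr.max_rbc_residual
        return SimulationResult(
            times=np.array(times),
            Q=np.array(rows["Q"]), Hbar=np.array(rows["Hbar"]),
            Hin=np.array(rows["Hin"]), Hout=np.array(rows["Hout"]),
            mubar=np.array(rows["mubar"]), pressures=np.array(rows["p"]),
            metadata=meta,
        )

    for n in range(n_steps):
        override = None
        if perturbation is not None and n < perturbation.steps:
            override = {
                perturbation.vessel: spec.H0 + perturbation.magnitude
            }
        try:
            simr.step(Hin_override=override)
        except FlowReversalError as err:
            err.result = build()
            raise
        if (n + 1) % save_stride == 0 or n == n_steps - 1:
            record()
    return build()


def limit_cycle_metrics(
    result: SimulationResult,
    observable: str = "Q",
    vessel: int = 3,
    transient_fraction: float = 0.5,
) -> dict:
    """Amplitude, period and mean of a (possibly) oscillatory observable.

    The post-transient window is the trailing ``1 - transient_fraction`` of
    the trajectory.  The amplitude is ``(max - min)/2`` over the window, the
    period the mean spacing of successive interior maxima (parabolically
    refined), and ``converged`` flags a relative drift of the per-cycle
    amplitude below 1% across the last three cycles.  A non-oscillatory
    trajectory returns amplitude 0 with ``oscillatory=False``.
    """
    return oscillation_metrics(
        result.times, result.series(observable, vessel), transient_fraction
    )


def oscillation_metrics(t, y, transient_fraction: float = 0.5) -> dict:
    """Array-level core of :func:`limit_cycle_metrics`."""
    t = np.asarray(t)
    y = np.asarray(y)
    i0 = int(len(t) * transient_fraction)
    tw, yw = t[i0:], y[i0:]
    span = float(np.max(yw) - np.min(yw))
    scale = max(abs(float(np.mean(yw))), 1e-12)
    out = {
        "amplitude": 0.5 * span,
        "period": math.nan,
        "mean": float(np.mean(yw)),
        "oscillatory": False,
        "converged": False,
        "n_peaks": 0,
    }
    if span < 1e-9 * max(scale, 1.0):
        out["amplitude"] = 0.0
        out["converged"] = True
        return out
    interior = (yw[1:-1] > yw[:-2]) & (yw[1:-1] >= yw[2:])
    idx = np.nonzero(interior)[0] + 1
    # keep only prominent peaks (reject numerical ripples)
    level = np.min(yw) + 0.5 * span
    idx = idx[yw[idx] > level]
    if len(idx) < 5:
        return out
    tpk = []
    for i in idx:
        denom = yw[i - 1] - 2.0 * yw[i] + yw[i + 1]
        if denom != 0.0:
            dtau = 0.5 * (yw[i - 1] - yw[i + 1]) / denom
            dtau = min(max(dtau, -1.0), 1.0)
        else:
            dtau = 0.0
        tpk.append(tw[i] + dtau * (tw[min(i + 1, len(tw) - 1)] - tw[i]))
    tpk = np.array(tpk)
    periods = np.diff(tpk)
    out["oscillatory"] = True
    out["n_peaks"] = int(len(idx))
    out["period"] = float(np.mean(periods[-5:]))
    # per-cycle amplitude drift over the last three full cycles
    amps = []
    for a, b in zip(idx[-4:-1], idx[1:][-3:]):
        seg = yw[a : b + 1]
        amps.append(0.5 * (np.max(seg) - np.min(seg)))
    if amps and amps[-1] > 0:
        drift = (max(amps) - min(amps)) / amps[-1]
        out["converged"] = bool(drift < 0.01)
    return out
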