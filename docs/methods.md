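# Methods

This note documents the model implemented in `capnet`, the numerical choices
behind each module, and what the package's tests do and do not establish.

## Model

**Geometry.** Six cylindrical vessels of equal dimensionless length 1 join
three internal nodes.  Vessels 2, 3, 5, 6 share the nominal diameter `D`
(default 20, i.e. 20 µm — a representative microcapillary); vessels 1 and 4
have diameter `alpha*D` with `alpha` in [0.25, 2.25].  Vessels 1 and 2 are
inlets held at a common pressure, vessel 6 drains to the outlet, and vessel 3
("redundant") connects the two flow paths.  Flow directions are fixed except
in vessel 3, whose sign distinguishes the two nontrivial flow configurations
(Case I: bottom-to-top; Case II: top-to-bottom).

**Rheology.** Apparent viscosity follows the empirical in-vitro law of
Pries, Neuhaus & Gaehtgens as a function of diameter and discharge
haematocrit (module `rheology`).  The plasma-viscosity scale `eta` is set to
1: every downstream quantity is a viscosity *ratio*, so its value cancels.
`(1-H)^C` is evaluated through `exp(C log1p(-H))`, guarded at `H -> 1`.
The Fåhræus (tube-versus-discharge haematocrit) correction is deliberately
omitted; the model transports discharge haematocrit only.

**Haematocrit transport.** Plug-flow advection makes each vessel a pure
delay line: the outlet haematocrit equals the inlet haematocrit one transit
time earlier, where the transit (retarded) time solves
`int_{t-tau}^{t} U ds = 1`.  The vessel-averaged haematocrit and viscosity
obey exact ODEs driven by the inlet/outlet difference; both are advanced with
explicit Euler.

**Junctions.** Converging nodes apply a red-cell flux balance.  The single
diverging node applies the Pries phase-separation rule
`F(psi)` with coefficients `A` (diameter asymmetry), `B = 1 +
6.98(1-H_parent)/D_parent` and skimming threshold `psi0 = 0.4/D_parent`;
the parent at either possible diverging node of this network is an inlet
vessel, so `H_parent = H0` exactly.  Red-cell flux is conserved to machine
precision by construction, and the per-step maxima of the node mass and
junction red-cell residuals are recorded in the run metadata.

**Nondimensionalisation.** Resistances are scaled by that of vessel 2 at the
inlet haematocrit, fluxes by the reference steady flux of vessel 2 and time
by vessel 2's transit time, so every reference state has `Q2 = 1`.  The
driving pressure difference is calibrated to make this normalisation exact:
`deltaP = 3 + Q1` for the trivial state and the bottom-path pressure drop of
the base state when a simulation is initialised at a nontrivial equilibrium
(which is then an exact fixed point of the discrete scheme — drift is at the
1e-16 level in the fixed-point tests).

## Steady states and continuation

The trivial state (`Q3 = H3 = 0`, all other haematocrits `H0`) is closed
form.  Nontrivial states reduce to two residual equations in `(Q1, Q3)` —
the internal-loop and equal-inlet-pressure identities — with the vessel
haematocrits eliminated through the splitting rule and red-cell balances;
they are solved by `scipy.optimize.root` (hybr) to residuals below 1e-10 and
verified against independent node-by-node red-cell balances in the tests.
Branches are tracked in `H0` by pseudo-arclength continuation (SVD tangent,
adaptive step halving).  The transcritical point `H_T` is refined by
bisection on the sign of the continued `Q3`; the fold `H_S` by a quadratic
fit of `H0` against arclength through the three points around the turning
point.  At `alpha = 0.45` the fold coincides (to ~4e-5) with the point where
the branch crosses its skimming threshold — the branch has a corner there,
which is why the fold-localisation also cross-checks against the direct
threshold-event solve.

## Time-domain simulation

Each step: pressure solve (closed-form elimination of the 3x3 junction
system; a Gauss–Seidel iteration with a "tolerance-or-stagnation" stopping
rule is provided and tested against the direct solve, which is the oracle) →
fluxes and velocities → retarded-time outlet haematocrits → junction updates
→ Euler update of averaged haematocrit and viscosity.  Default time step
`dt = 0.01` transit times; the limit-cycle comparisons are re-run at
`dt = 0.005` as a refinement check.

The retarded-time crossing is located by sign change of the accumulated
trapezoidal transit integral, searching forward from the previous step's
crossing (O(1) per step).  Two lookup variants exist:

* `interp='grid'` (default): the crossing snaps to the first grid time past
  the sign change and the stored inlet value at that grid time is used.
* `interp='linear'`: sub-step linear interpolation of both the crossing and
  the inlet-haematocrit history.

The grid variant is the default for a dynamical reason, not an accuracy one.
Any state with `Q3 = 0` is an equilibrium *regardless of the haematocrit
stored in vessel 3* (no flow means no transport), so the model contains a
continuum of "frozen" zero-flow states.  Limit cycles whose redundant-vessel
flux dips close to zero — e.g. at `(alpha, H0) = (0.9, 0.5)` — graze this
family; under the interpolated scheme the grazing trajectory is captured and
the oscillation dies, while the grid scheme's quantisation keeps the cycle
alive for thousands of transit times with stable per-cycle amplitudes.  The
interpolated variant remains available and is used where it is the better
tool: the small-amplitude envelope measurements that cross-validate the
eigenvalue analysis (no grazing occurs in the linear regime).

**Perturbation protocol.** Stability probes add ±1e-6 to the vessel-2 inlet
haematocrit during the first step only.  From the trivial state at
`(0.5, 0.45)` the sign selects the attractor: positive gives the steady
top-to-bottom state, negative the bottom-to-top limit cycle.

**Limit-cycle measurement.** Converged amplitudes are the median half-ranges
of the last three full cycles, with cycles segmented by the deep troughs of
the redundant-vessel flux (threshold: lowest quarter of the global range,
minimum separation 20 time units).  This segmentation is robust both to the
long dwell phases of the relaxation-type cycles and to trajectories whose
oscillatory epoch is finite.  Horizons of 3000 transit times at
`(0.5, 0.5)` and 6000 at `(0.9, 0.5)` give 8–12 full cycles after the
growth transient; halving the step changes the measured amplitude reductions
by under 2 percentage points.

## Linear stability

Normal-mode perturbations `exp(lam t)` turn each vessel's advection into the
transit filter `g(x) = (1 - e^{-x})/x`, `x = alpha_i^2 lam / Q_i`, entering
the resistance response; `lam -> 0` limits are taken analytically.

* **Trivial state.** The pressure-BC system closes on the six flux
  amplitudes (6x6 determinant); fixed-flux conditions collapse it to one
  scalar transcendental equation.  The critical curves `H0(alpha)` are the
  `lam -> 0` roots, found by bracketed bisection and continued in `alpha`;
  the pressure-BC curve reproduces the transcritical points of the
  steady-state continuation to ~1e-5 — the two computations share no code
  path beyond the viscosity law.  Closed-form small- and large-`alpha`
  asymptotes are provided.  The small-`alpha` asymptote agrees with the full
  curves to 0.4% at `alpha = 0.25`, degrading to ~3% by `alpha = 0.4` (the
  neglected term is `O(alpha^4 (1+R3) mu0)`, which is a few percent there).
* **Nontrivial states.** The perturbation system is assembled mechanically
  from the same linearisation recipe (splitting-rule linearisation at the
  diverging node, delayed red-cell balances at converging nodes, transit
  filters, loop and node equations) into a 14x14 matrix `A(lam)` over
  `(h3..h6, r3..r6, q1..q6)`; Case II mirrors Case I with the splitting rule
  moved to the other node.  `det A` is evaluated with row max-scaling; roots
  are found by complex Newton seeded from a modulus scan over a rectangle of
  the upper half-plane, with an adaptive argument-principle winding count as
  a global safeguard.  Because this system was re-derived rather than
  transcribed, its validation is mandatory and two-fold: (i) the growth rate
  and frequency of the dominant mode match the envelope growth rate and peak
  spacing of perturbed simulations at three near-onset points to within
  5%/10% (measured: ≤2% in sigma, ≤8% in omega); (ii) the eigenpair
  residual `|A v|` is below 1e-10.

**Spectral realness caveat.** The trivial state's characteristic function is
that of a retarded delay system: it has infinite chains of strongly damped
complex roots marching toward `Re lam -> -inf`.  For small `alpha` (large
top-branch delay) these chains enter `Re lam < -0.2`.  The physically
relevant statement — no oscillatory modes in the dominant part of the
spectrum (`Re lam >= -0.2`, in particular none with `Re lam >= 0`), so the
trivial state can only destabilise through a real (transcritical) eigenvalue
— is verified by argument-principle counts for both boundary-condition
types.

## Splitting-rule smoothing

The smoothed variant replaces the constant tails of the nonsmooth rule with
the minimal cubics `y_L = a psi^3` and `y_U = 1 - b (1-psi)^3` (the lowest
order satisfying `F = F' = F'' = 0` at the origin, preserving the trivial
state's stability properties), joined with value-and-slope continuity to the
logistic core; each junction point solves a scalar equation by bracketed
root finding.  The skimming sensitivity `S(psi) = -(F/psi - F')/psi`, which
sets the haematocrit response of the redundant vessel and hence the strength
of the oscillatory feedback, is `2 a psi` in the cubic region: it rises
linearly to the core value at `psi_L` and therefore *never exceeds* the
sharp spike the nonsmooth rule develops just above `psi0`.  A consequence
this package documents deliberately: under this C1 construction, smoothing
raises the oscillatory onset haematocrit (stabilises) at every diameter
ratio tested on both sides of `alpha = 1`, while removing the onset
discontinuity — the onset curve becomes a closed loop in `(alpha, H0)`
rather than a curve emanating from the skimming threshold.  Near-threshold
stability is thus highly sensitive to the smoothing construction; the
nonsmooth and smoothed rules should be read as bracketing the plausible
behaviours, and any comparison of *which* variant is more stable at large
`alpha` depends on details of the junction placement.

## Scope of the synthetic experiments

All experiments are simulations of the model itself; no measured data is
involved.  The model assumes plug flow (no velocity profile for red cells),
quasi-steady Poiseuille hydraulics, rigid vessels, constant inlet
haematocrit and pressure, and no Fåhræus effect, oxygen transport or
vasoregulation.  Passing tests therefore establish internal correctness and
reproducibility of the model's bifurcation structure, not fidelity to in
vivo microcirculation.  Flow reversal in a vessel that has established a
direction aborts a run (the haematocrit bookkeeping for back-flow is out of
scope); reversal never occurred in the reported runs.

## Known limitations

* The frozen zero-flow family makes long-time behaviour of near-grazing
  limit cycles sensitive to the retarded-time discretisation (see above);
  amplitudes are measured per cycle for this reason.
* Continuation of iso-growth-rate contours for the nonsmooth rule stalls
  where the contour hugs the skimming threshold (the steady state sits
  within ~1e-5 of the kink); targeted point solves are used there instead.
* Only the six-vessel motif is wired, although the junction law is generic.
* `D` is a free input but all validated results use `D = 20`.
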