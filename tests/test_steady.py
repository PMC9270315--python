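"""Steady states: closed-form trivial solution, Newton roots, continuation."""

import numpy as np
import pytest

from capnet.rheology import relative_viscosity
from capnet.steady import (
    bifurcation_points,
    continue_branch,
    find_starting_state,
    nontrivial_residual,
    skimming_threshold_H0,
    solve_nontrivial,
    split_rule_for_case,
    trivial_state,
)

D = 20.0


class TestTrivialState:
    def test_symmetric_unit_flux(self):
        assert trivial_state(1.0, 0.45).Q1 == pytest.approx(1.0, rel=1e-12)

    def test_printed_flux_value(self):
        st = trivial_state(0.5, 0.45)
        expect = 0.5**4 * relative_viscosity(0.45, 20.0) / relative_viscosity(0.45, 10.0)
        assert st.Q1 == pytest.approx(expect, rel=1e-12)
        assert st.Q1 == pytest.approx(0.0344, abs=1e-4)

    def test_vessel_3_empty(self):
        st = trivial_state(0.7, 0.3)
        assert st.Q3 == 0.0 and st.H3 == 0.0
        assert st.H4 == st.H5 == 0.3


class TestResiduals:
    @pytest.mark.parametrize("case", ["I", "II"])
    def test_trivial_point_solves_both_systems(self, case):
        # both nontrivial systems reduce to the trivial solution at Q3 = 0
        st = trivial_state(0.45, 0.5)
        r = nontrivial_residual((st.Q1, 0.0), case, 0.45, 0.5)
        assert np.max(np.abs(r)) < 1e-12

    @pytest.mark.parametrize(
        "alpha,ratio", [(0.5, 0.853), (0.9, 0.045)],
    )
    def test_case1_flux_ratios_at_H05(self, alpha, ratio):
        st = find_starting_state(alpha, "I", D, 0.5)
        assert st.Q3 / st.Q1 == pytest.approx(ratio, abs=5e-3)

    @pytest.mark.parametrize("alpha,case,H0", [
        (0.5, "I", 0.5), (0.9, "I", 0.5), (0.45, "II", 0.5), (1.6, "II", 0.6),
    ])
    def test_red_cell_balances_at_converged_roots(self, alpha, case, H0):
        # independent conservation oracle: recompute RBC balances from the
        # solution and check them node by node
        st = find_starting_state(alpha, case, D, H0)
        if case == "I":
            # diverging node 2-3-5 and converging node 1-3-4
            assert st.H3 * st.Q3 + st.H5 * st.Q5 == pytest.approx(H0 * 1.0, abs=1e-10)
            assert st.H4 * st.Q4 == pytest.approx(H0 * st.Q1 + st.H3 * st.Q3, abs=1e-10)
        else:
            assert st.H3 * st.Q3 + st.H4 * st.Q4 == pytest.approx(H0 * st.Q1, abs=1e-10)
            assert st.H5 * st.Q5 == pytest.approx(H0 * 1.0 + st.H3 * st.Q3, abs=1e-10)
        # global outlet balance
        assert st.Q6 == pytest.approx(st.Q4 + st.Q5, rel=1e-12)
        assert st.H4 * st.Q4 + st.H5 * st.Q5 == pytest.approx(
            st.H6 * st.Q6, abs=1e-10)

    def test_infeasible_point_rejected(self):
        with pytest.raises(ValueError):
            nontrivial_residual((0.05, 1.5), "I", 0.5, 0.5)  # Q5 < 0


@pytest.fixture(scope="module")
def bif45():
    return bifurcation_points(0.45, D)


class TestContinuation:
    def test_transcritical_location(self, bif45):
        assert bif45["H_T"] == pytest.approx(0.3365, abs=1e-3)

    def test_fold_location_and_ordering(self, bif45):
        assert bif45["H_S"] == pytest.approx(0.3288, abs=1e-3)
        assert bif45["H_S"] < bif45["H_T"]

    def test_branch_meets_trivial_solution_at_transcritical(self, bif45):
        # just above H_T the Case-I branch is a small deformation of the
        # trivial state
        H0 = bif45["H_T"] + 1e-3
        b = bif45["branch_T"]
        i = np.argmin(np.abs(b.H0 - H0))
        st = solve_nontrivial(0.45, H0, "I", (b.Q1[i], max(b.Q3[i], 1e-4)), D)
        assert st.Q3 < 0.02
        assert st.Q1 == pytest.approx(trivial_state(0.45, H0).Q1, rel=0.05)

    def test_three_solutions_coexist_above_threshold(self):
        # trivial + Case I + Case II at H0 slightly above H_T
        for case in ("I", "II"):
            st = find_starting_state(0.45, case, D, 0.35)
            assert st.Q3 > 0.0
        assert trivial_state(0.45, 0.35).Q1 > 0.0

    def test_branch_retraces_on_reversal(self):
        b = continue_branch(0.45, "I", H0_start=0.6, H0_end=0.45, D=D)
        # re-solve at three visited H0 values from independent seeds
        for k in (len(b.H0) // 3, len(b.H0) // 2, -1):
            st = find_starting_state(0.45, "I", D, float(b.H0[k]))
            assert st.Q3 == pytest.approx(b.Q3[k], rel=1e-6, abs=1e-9)


class TestSkimmingThresholds:
    def test_threshold_flux_ratio_exact(self):
        H0 = skimming_threshold_H0(0.45, "I", D)
        st = find_starting_state(0.45, "I", D, H0)
        assert st.Q3 == pytest.approx(0.4 / D, rel=1e-6)

    def test_branch_crossing_agrees_with_direct_solve(self):
        # localise the threshold from continuation data (bisection between
        # the bracketing branch points), then compare with the direct
        # three-unknown event solve
        from scipy.optimize import brentq

        H0_direct = skimming_threshold_H0(0.45, "I", D)
        b = continue_branch(0.45, "I", H0_start=0.6, H0_end=0.3, D=D, ds=1e-3)
        f = b.Q3 - 0.4 / D
        k = np.nonzero(f[:-1] * f[1:] < 0)[0]
        assert len(k) > 0
        k = k[0]
        seed = (b.Q1[k], b.Q3[k])

        def excess(H0):
            return solve_nontrivial(0.45, float(H0), "I", seed, D).Q3 - 0.4 / D

        lo, hi = sorted((b.H0[k], b.H0[k + 1]))
        H0_branch = brentq(excess, lo, hi, xtol=1e-10)
        assert H0_branch == pytest.approx(H0_direct, abs=1e-6)

    def test_grey_region_state_has_empty_redundant_vessel(self):
        # below the threshold (but above the fold) the nontrivial states
        # carry flow yet no haematocrit in vessel 3
        H0_thr = skimming_threshold_H0(0.45, "II", D)
        st = find_starting_state(0.45, "II", D, H0_thr + 0.02)
        assert st.H3 > 0.0
        st_grey = find_starting_state(0.45, "I", D, 0.40)
        thr_I = skimming_threshold_H0(0.45, "I", D)
        if st_grey.Q3 < 0.4 / D:
            assert st_grey.H3 == 0.0
            assert 0.40 < thr_I
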