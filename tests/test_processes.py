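"""Steady-state input/output maps and the admissibility calculus."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from antithetic import (
    AffineIOMap,
    GeneExpressionProcess,
    Interval,
    UnimolecularProcess,
    admissible_disturbances,
    admissible_input_setpoints,
    admissible_setpoints,
    hill,
    hurwitz_metzler_check,
    io_map_unimolecular,
    supporting_input,
)
from antithetic.crn import ValidationError, find_steady_state
from antithetic.processes import NoSupportingInputError, StabilityError


def gene_expression_as_unimolecular(k1=1.0, g1=1.0, g2=1.0, delta=0.0):
    # reactions: basal production of x1, decay of x1, translation, decay of x2
    S = np.array([[1, -1, 0, 0], [0, 0, 1, -1]], dtype=float)
    W = np.array([[0, 0], [g1, 0], [k1, 0], [0, g2]], dtype=float)
    b = np.array([delta, 0, 0, 0], dtype=float)
    return UnimolecularProcess(S=S, W=W, b=b)


def random_stable_unimolecular(rng, L):
    """First-order network: conversions at random nonnegative rates with
    degradation dominating each column (Hurwitz by Gershgorin)."""
    C = rng.uniform(0, 1, size=(L, L))
    np.fill_diagonal(C, 0.0)
    d = C.sum(axis=0) + rng.uniform(0.2, 1.5, size=L)
    cols, Wrows, b = [], [], []
    for i in range(L):
        for j in range(L):
            if i != j and C[i, j] > 0:
                e = np.zeros(L); e[i] = 1.0
                cols.append(e)
                w = np.zeros(L); w[j] = C[i, j]
                Wrows.append(w); b.append(0.0)
        e = np.zeros(L); e[i] = -1.0
        cols.append(e)
        w = np.zeros(L); w[i] = d[i]
        Wrows.append(w); b.append(0.0)
        if rng.uniform() < 0.5:  # occasional basal production
            e = np.zeros(L); e[i] = 1.0
            cols.append(e); Wrows.append(np.zeros(L)); b.append(rng.uniform(0, 2))
    return UnimolecularProcess(S=np.array(cols).T, W=np.array(Wrows),
                               b=np.array(b))


class TestIOMap:
    @pytest.mark.parametrize("delta,expected", [(0.0, (1.0, 0.0)),
                                                (5.0, (1.0, 5.0))])
    def test_gene_expression_gain_and_offset(self, delta, expected):
        m = io_map_unimolecular(gene_expression_as_unimolecular(delta=delta))
        assert (m.alpha, m.beta) == pytest.approx(expected)

    def test_single_species_gain_is_inverse_degradation(self):
        proc = UnimolecularProcess(S=np.array([[-1.0]]), W=np.array([[2.0]]),
                                   b=np.array([0.0]))
        m = io_map_unimolecular(proc)
        assert (m.alpha, m.beta) == pytest.approx((0.5, 0.0))

    def test_unstable_network_rejected(self):
        proc = UnimolecularProcess(S=np.array([[1.0]]), W=np.array([[1.0]]),
                                   b=np.array([0.0]))
        with pytest.raises(StabilityError):
            io_map_unimolecular(proc)

    def test_matches_gene_expression_closed_form(self):
        m = GeneExpressionProcess(k1=2.0, gamma1=4.0, gamma2=1.0, delta=3.0).io_map()
        assert m.alpha == pytest.approx(0.5)
        assert m.beta == pytest.approx(1.5)

    def test_gain_and_offset_nonnegative_on_random_stable_networks(self, rng):
        for _ in range(25):
            proc = random_stable_unimolecular(rng, int(rng.integers(2, 6)))
            m = io_map_unimolecular(proc)
            assert m.alpha >= 0 and m.beta >= -1e-12

    def test_map_agrees_with_steady_state_simulation(self, rng):
        class OpenLoop:
            def __init__(self, proc, u):
                self.proc, self.u = proc, u
                self.state_names = proc.species_names

            def rhs(self, t, x):
                return self.proc.rhs(t, x, self.u)

        for _ in range(15):
            proc = random_stable_unimolecular(rng, int(rng.integers(2, 5)))
            m = io_map_unimolecular(proc)
            u = float(rng.uniform(0, 3))
            res = find_steady_state(OpenLoop(proc, u), np.zeros(proc.n_species))
            assert res.converged
            assert proc.output(res.state) == pytest.approx(m(u), abs=1e-6)


class TestHurwitzMetzler:
    def test_diagonal_negative_is_both(self):
        v = hurwitz_metzler_check(np.diag([-1.0, -2.0]))
        assert v.hurwitz and v.metzler

    def test_nilpotent_is_not_hurwitz(self):
        v = hurwitz_metzler_check(np.array([[0.0, 1.0], [0.0, 0.0]]))
        assert not v.hurwitz and v.metzler

    def test_gene_expression_dynamics_matrix(self):
        A = gene_expression_as_unimolecular().A
        v = hurwitz_metzler_check(A)
        assert v.hurwitz and v.metzler
        assert v.max_real_part == pytest.approx(-1.0)


class TestSupportingInput:
    def test_affine_with_offset(self):
        m = AffineIOMap(1.0, 5.0)
        assert supporting_input(m, 10.0) == pytest.approx(5.0)

    def test_boundary_setpoint_needs_zero_input(self):
        m = AffineIOMap(2.0, 5.0)
        assert supporting_input(m, 5.0, U=Interval.nonnegative()) == 0.0

    def test_setpoint_below_offset_is_infeasible(self):
        m = AffineIOMap(1.0, 5.0)
        with pytest.raises(NoSupportingInputError):
            supporting_input(m, 4.0, U=Interval.nonnegative())

    def test_monotone_nonlinear_map_by_bracketing(self):
        f = lambda u: 8.0 * hill(5.0)(u)  # saturating map with range [0, 8)
        u = supporting_input(f, 5.0)
        assert f(u) == pytest.approx(5.0, abs=1e-9)

    def test_saturating_map_rejects_out_of_range_setpoint(self):
        f = lambda u: 8.0 * hill(5.0)(u)
        with pytest.raises(NoSupportingInputError):
            supporting_input(f, 9.0)

    @given(st.floats(min_value=0.0, max_value=1e6))
    @settings(deadline=None, max_examples=50)
    def test_round_trip_on_admissible_setpoints(self, r_above):
        m = AffineIOMap(1.0, 5.0)
        U = Interval.nonnegative()
        r = m.beta + r_above
        assert r in admissible_setpoints(m, U)
        assert m(supporting_input(m, r, U=U)) == pytest.approx(r, abs=1e-9)


class TestAdmissibleSets:
    def test_no_basal_means_all_nonnegative_setpoints(self):
        out = admissible_setpoints(AffineIOMap(1.0, 0.0), Interval.nonnegative())
        assert out.lo == 0.0 and np.isinf(out.hi)
        assert 0.0 in out and 1e9 in out

    def test_saturated_actuation_bounds_the_setpoints(self):
        # gain 1, offset 5, feasible inputs [0, 8] -> setpoints [5, 13]
        out = admissible_setpoints(AffineIOMap(1.0, 5.0), Interval(0.0, 8.0))
        assert (out.lo, out.hi) == pytest.approx((5.0, 13.0))
        assert out.lo_closed and out.hi_closed

    def test_single_input_gives_single_setpoint(self):
        out = admissible_setpoints(AffineIOMap(2.0, 1.0), Interval(3.0, 3.0))
        assert out.is_singleton and out.lo == pytest.approx(7.0)

    def test_disturbance_set_unbounded_actuation(self):
        fam = lambda d: GeneExpressionProcess(delta=d).io_map()
        D = admissible_disturbances(fam, 10.0, Interval.nonnegative(),
                                    Interval.nonnegative())
        assert (D.lo, D.hi) == pytest.approx((0.0, 10.0))

    def test_disturbance_set_saturated_actuation(self):
        fam = lambda d: GeneExpressionProcess(delta=d).io_map()
        D = admissible_disturbances(fam, 10.0, Interval(0.0, 8.0),
                                    Interval.nonnegative())
        assert (D.lo, D.hi) == pytest.approx((2.0, 10.0))

    def test_unreachable_setpoint_gives_empty_set(self):
        fam = lambda d: GeneExpressionProcess(delta=d).io_map()
        D = admissible_disturbances(fam, -3.0, Interval.nonnegative(),
                                    Interval.nonnegative())
        assert D.is_empty

    def test_input_setpoints_through_hill_sensing(self):
        out = Interval(5.0, 13.0)
        inn = admissible_input_setpoints(out, hill(5.0))
        assert (inn.lo, inn.hi) == pytest.approx((0.5, 13.0 / 18.0))

    def test_identity_sensing_is_a_no_op(self):
        out = Interval(5.0, 13.0)
        inn = admissible_input_setpoints(out, lambda y: y)
        assert (inn.lo, inn.hi) == (5.0, 13.0)

    def test_singleton_maps_to_singleton(self):
        inn = admissible_input_setpoints(Interval(5.0, 5.0), hill(5.0))
        assert inn.is_singleton and inn.lo == pytest.approx(0.5)

    def test_non_monotone_sensing_rejected(self):
        with pytest.raises(ValidationError, match="increasing"):
            admissible_input_setpoints(Interval(0.0, 10.0), lambda y: (y - 5) ** 2)


class TestInterval:
    def test_infinite_endpoints_are_open(self):
        iv = Interval(0.0, np.inf)
        assert iv.lo_closed and not iv.hi_closed

    def test_containment_respects_open_endpoints(self):
        iv = Interval(0.0, 1.0, lo_closed=False, hi_closed=True)
        assert 0.0 not in iv and 1.0 in iv and 0.5 in iv

    def test_intersection(self):
        a = Interval(0.0, 5.0)
        b = Interval(3.0, 9.0)
        c = a.intersect(b)
        assert (c.lo, c.hi) == (3.0, 5.0)
        assert a.intersect(Interval(7.0, 9.0)).is_empty
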