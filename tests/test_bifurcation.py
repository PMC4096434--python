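"""Transcritical, Hopf, saddle-node and Bogdanov-Takens localization."""

import numpy as np
import pytest

from crisprlv import (
    ModelSpec,
    Params,
    analyze,
    bogdanov_takens_locate,
    hopf_curve,
    hopf_threshold,
    interior_equilibria,
    jacobian,
    saddle_node_threshold,
    supercriticality_check,
    transcritical_M,
    trivial_equilibria,
)
from crisprlv.bifurcation import BracketError, unstable_cycle_exists
from conftest import random_params

M3V = ModelSpec("three", "logistic", "virus_dependent")
M2V = ModelSpec("two", "logistic", "virus_dependent")
AF1 = Params(l=0.0, e=0.0, d=1.0, M=12.0, b=0.1, a=1.0, k=1.0, s=0.15)


class TestTranscritical:
    def test_closed_form_value(self):
        p = Params(a=1.0, d=1.0, b=0.05, s=0.2)
        assert transcritical_M(p) == pytest.approx(1.01 / 0.04)  # 25.25

    def test_reduces_to_ad_over_b_for_tiny_innate_immunity(self):
        p = Params(a=1.0, d=1.0, b=0.05, s=1e-12)
        assert transcritical_M(p) == pytest.approx(p.a * p.d / p.b, rel=1e-9)

    def test_stability_flips_across_threshold(self, fig2_setup):
        model, params = fig2_setup
        M_tc = transcritical_M(params)
        below = params.replace(M=M_tc - 0.1)
        above = params.replace(M=M_tc + 0.1)
        A_lo = trivial_equilibria(model, below)[1]
        A_hi = trivial_equilibria(model, above)[1]
        assert analyze(A_lo, model, below).is_stable
        assert not analyze(A_hi, model, above).is_stable

    def test_numeric_crossing_matches_closed_form(self, rng):
        # bisection on the numeric leading eigenvalue of A reproduces the
        # closed form to 1e-9
        from scipy.optimize import brentq
        for _ in range(20):
            pr = random_params(rng, M3V)
            M_tc = transcritical_M(pr)

            def lam3(M):
                J = jacobian(M3V, np.array([0.0, 1.0 / pr.a, 0.0]),
                             pr.replace(M=M))
                return max(np.linalg.eigvals(J).real)

            M_cross = brentq(lam3, 0.5 * M_tc, 2.0 * M_tc, xtol=1e-12)
            assert M_cross == pytest.approx(M_tc, abs=1e-9)

    def test_interior_virus_level_vanishes_at_threshold(self, fig2_setup):
        _, params = fig2_setup
        M_tc = transcritical_M(params)
        eqs = interior_equilibria(M3V, params.replace(M=M_tc + 0.05))
        assert len(eqs) == 1
        assert eqs[0].z < 0.2  # z_e -> 0+ as M -> M_tc+

    def test_requires_logistic_growth(self):
        with pytest.raises(ValueError):
            transcritical_M(Params(a=0.0))


class TestHopfThreshold:
    def test_threshold_location_and_frequency(self, fig2_setup):
        model, params = fig2_setup
        bp = hopf_threshold(model, params, "M", (90.0, 110.0))
        assert bp.kind == "hopf"
        assert bp.omega is not None and bp.omega > 0
        assert abs(bp.diagnostics["re_pair"]) < 1e-8
        assert bp.diagnostics["transversality"] != 0
        # the threshold equilibrium continues the fig2 branch
        assert bp.equilibrium.x == pytest.approx(0.279, abs=1e-2)
        assert bp.equilibrium.y == pytest.approx(0.013, abs=1e-2)
        assert bp.equilibrium.z == pytest.approx(20.24, abs=0.1)

    def test_invariant_under_bracket_choice(self, fig2_setup):
        model, params = fig2_setup
        b1 = hopf_threshold(model, params, "M", (90.0, 110.0))
        b2 = hopf_threshold(model, params, "M", (95.0, 104.0))
        assert b1.param_value == pytest.approx(b2.param_value, abs=1e-8)

    def test_no_sign_change_raises_bracket_error(self, fig2_setup):
        model, params = fig2_setup
        with pytest.raises(BracketError):
            hopf_threshold(model, params, "M", (30.0, 50.0))

    def test_equilibrium_stable_below_unstable_above(self, fig2_setup):
        model, params = fig2_setup
        bp = hopf_threshold(model, params, "M", (90.0, 110.0))
        lo = params.replace(M=bp.param_value - 0.5)
        hi = params.replace(M=bp.param_value + 0.5)
        assert analyze(interior_equilibria(model, lo)[0], model, lo).is_stable
        assert not analyze(interior_equilibria(model, hi)[0], model, hi).is_stable


class TestHopfCurve:
    def test_acquisition_rate_curve(self, fig2_setup):
        # e_H(M) panel family: k = 0.2, free parameter e; with the lower
        # immunity steepness the oscillatory instability sets in at much
        # larger burst factors, so the curve lives at M of several hundred
        _, params = fig2_setup
        params = params.replace(k=0.2)
        pts, gaps = hopf_curve(M3V, params, "e", [700.0, 800.0, 900.0],
                               free_range=(0.05, 1.5))
        assert len(pts) == 3
        assert gaps == []
        # larger M destabilizes, so the critical acquisition rate decreases
        es = [bp.param_value for bp in pts]
        assert es[0] > es[1] > es[2]
        for bp in pts:
            assert abs(bp.diagnostics["re_pair"]) < 1e-8
            assert bp.omega > 0

    def test_points_revalidate_from_perturbed_bracket(self, fig2_setup):
        _, params = fig2_setup
        params = params.replace(k=0.2)
        pts, _ = hopf_curve(M3V, params, "e", [800.0], free_range=(0.05, 1.5))
        assert pts
        bp = pts[0]
        e_c = bp.param_value
        again = hopf_threshold(M3V, params.replace(M=800.0), "e",
                               (e_c - 0.04, e_c + 0.06))
        assert again.param_value == pytest.approx(e_c, abs=1e-6)


class TestSaddleNode:
    def test_threshold_between_empty_and_two_equilibria(self):
        bp = saddle_node_threshold(AF1, M_range=(5.0, 60.0))
        assert 12.0 < bp.param_value < 25.0
        assert abs(bp.diagnostics["det_residual"]) < 1e-9
        assert abs(bp.diagnostics["trace"]) > 1e-3  # genuine fold, not BT
        # counts flip around M*
        assert interior_equilibria(M2V, AF1.replace(M=bp.param_value - 0.5)) == []
        assert len(interior_equilibria(M2V, AF1.replace(M=bp.param_value + 0.5))) == 2

    def test_roots_coalesce_at_threshold(self):
        bp = saddle_node_threshold(AF1, M_range=(5.0, 60.0))
        eqs = interior_equilibria(M2V, AF1.replace(M=bp.param_value + 1e-3))
        assert len(eqs) == 2
        assert abs(eqs[0].z - eqs[1].z) < 0.5
        # and the pair straddles the located fold point
        assert eqs[0].z < bp.equilibrium.z < eqs[1].z


class TestBogdanovTakens:
    def test_double_zero_point(self):
        bp = bogdanov_takens_locate(AF1)
        assert bp.kind == "bogdanov_takens"
        assert abs(bp.diagnostics["det_residual"]) < 1e-9
        assert abs(bp.diagnostics["trace_residual"]) < 1e-9
        eigs = bp.diagnostics["eigenvalues"]
        assert all(abs(v) < 1e-5 for v in eigs)

    def test_unfolding_splits_double_zero(self):
        bp = bogdanov_takens_locate(AF1)
        M_bar, k_bar = bp.diagnostics["M"], bp.diagnostics["k"]
        for fac in (0.99, 1.01):
            p = AF1.replace(M=M_bar * fac, k=k_bar)
            eqs = interior_equilibria(M2V, p)
            if not eqs:
                continue
            eq = min(eqs, key=lambda q: abs(q.z - bp.equilibrium.z))
            vals = np.linalg.eigvals(jacobian(M2V, eq.state, p))
            assert np.max(np.abs(vals)) > 1e-4  # degeneracy resolved


class TestCycles:
    def test_unstable_cycle_surrounds_stable_spiral(self):
        # backward-time integration from near B2 settles onto the cycle
        assert unstable_cycle_exists(AF1.replace(M=100.0))

    def test_no_unstable_cycle_without_interior_equilibria(self):
        assert not unstable_cycle_exists(AF1.replace(M=5.0))

    def test_hopf_is_not_supercritical_at_reference_family(self, fig2_setup):
        # just above the threshold the trajectory bypasses any small cycle
        # and lands on the pre-existing large one: the amplitude does not
        # follow the square-root law, diagnosing a subcritical transition
        # with a fold of cycles (bistability extends below threshold)
        model, params = fig2_setup
        bp = hopf_threshold(model, params, "M", (90.0, 110.0))
        out = supercriticality_check(
            model, params, bp, rel_offsets=(1e-2, 3e-2, 1e-1),
            t_settle=20000.0, dt=0.5)
        assert out["slope"] is not None
        assert all(a > 1.0 for a in out["amplitudes"])  # stable cycle above
        assert abs(out["slope"]) < 0.2  # far from the sqrt exponent 0.5
        assert not out["supercritical"]
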