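"""Right-hand sides, immunity law and analytic Jacobians."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crisprlv import (
    ModelSpec,
    Params,
    immunity,
    immunity_derivative,
    jacobian,
    rhs,
)
from crisprlv.model import MODEL_VARIANTS
from conftest import random_params

M3V = ModelSpec("three", "logistic", "virus_dependent")


class TestImmunity:
    def test_full_immunity_at_zero_virus(self):
        p = Params(s=0.3, k=0.7)
        assert immunity(0.0, p) == pytest.approx(1.0)

    def test_tends_to_innate_level_at_high_virus(self):
        p = Params(s=0.2, k=0.1)
        z = 26.0 / p.k  # k z > 25
        assert immunity(z, p) - p.s < 1e-9

    def test_hand_computed_value(self):
        # (1 - 0.2) e^{-0.1 * 20.24} + 0.2
        p = Params(s=0.2, k=0.1)
        assert immunity(20.24, p) == pytest.approx(0.3057007, abs=1e-6)

    def test_constant_mode(self):
        p = Params(s=0.2, p_const=0.5)
        assert immunity(17.0, p, mode="constant") == 0.5
        assert immunity_derivative(17.0, p, mode="constant") == 0.0

    def test_negative_virus_density_rejected(self):
        with pytest.raises(ValueError):
            immunity(-0.1, Params())
        with pytest.raises(ValueError):
            immunity_derivative(-0.1, Params())

    @given(z=st.floats(0.0, 1e3), s=st.floats(0.05, 0.95), k=st.floats(0.01, 5.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounds_and_monotonicity(self, z, s, k):
        p = Params(s=s, k=k)
        val = immunity(z, p)
        assert s <= val <= 1.0 + 1e-15
        assert immunity_derivative(z, p) <= 0.0
        # strictly decreasing until exp(-k z) underflows to the innate floor
        if k * z < 30.0:
            assert immunity(z + 1.0, p) < val
        else:
            assert immunity(z + 1.0, p) <= val

    def test_derivative_examples(self):
        p = Params(s=0.2, k=0.1)
        assert immunity_derivative(0.0, p) == pytest.approx(p.k * (p.s - 1.0))
        assert immunity_derivative(20.24, p) == pytest.approx(-0.0105701, abs=1e-6)

    def test_derivative_matches_finite_difference(self):
        p = Params(s=0.3, k=0.4)
        for z in (0.5, 3.0, 17.0):
            fd = (immunity(z + 1e-6, p) - immunity(z - 1e-6, p)) / 2e-6
            assert immunity_derivative(z, p) == pytest.approx(fd, rel=1e-6)


class TestRHS:
    def test_origin_is_equilibrium(self):
        for model in MODEL_VARIANTS:
            p = Params(a=1.0 if model.growth == "logistic" else 0.0, p_const=0.5)
            assert np.allclose(rhs(model, np.zeros(model.dim), p), 0.0)

    def test_printed_equilibrium_is_near_stationary(self, fig2_setup):
        # the fixed point printed to 3 decimals must leave only rounding
        # residuals in the vector field
        model, params = fig2_setup
        f = rhs(model, np.array([0.279, 0.013, 20.24]), params)
        # the virus equation multiplies coordinate rounding (5e-4) by
        # roughly z b M (1-p) ~ 70, so its residual budget is larger
        assert np.max(np.abs(f[:2])) < 5e-3
        assert abs(f[2]) < 5e-2

    def test_matches_symbolic_rederivation(self, rng):
        sympy = pytest.importorskip("sympy")
        x, y, z = sympy.symbols("x y z")
        l, e, d, M, b, a, k, s = sympy.symbols("l e d M b a k s")
        p = (1 - s) * sympy.exp(-k * z) + s
        exprs = [
            x * (1 - l - a * (x + y)) - b * x * z * (1 - p) + e * s * y * z,
            y + l * x - a * y * (x + y) - b * y * z * (1 - s) - e * s * y * z,
            z * (-d + b * M * (x * (1 - p) + y * (1 - s)) - b * (x * p + y * s)),
        ]
        f = sympy.lambdify((x, y, z, l, e, d, M, b, a, k, s), exprs)
        for _ in range(20):
            pr = random_params(rng, M3V)
            st_ = rng.uniform(0.01, 5.0, size=3)
            expected = np.array(f(*st_, pr.l, pr.e, pr.d, pr.M, pr.b, pr.a, pr.k, pr.s))
            got = rhs(M3V, st_, pr)
            assert np.allclose(got, expected, rtol=1e-12, atol=1e-12)

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError):
            rhs(M3V, np.array([-0.1, 0.2, 1.0]), Params(a=1.0))

    def test_orthant_faces_invariant(self, rng):
        for _ in range(20):
            pr = random_params(rng, M3V)
            y, z = rng.uniform(0.01, 5.0, size=2)
            # x = 0: immigration only through acquisition
            f = rhs(M3V, np.array([0.0, y, z]), pr)
            assert f[0] == pytest.approx(pr.e * pr.s * y * z)
            assert f[0] >= 0.0
            # z = 0: virus extinction is absorbing
            x = rng.uniform(0.01, 5.0)
            assert rhs(M3V, np.array([x, y, 0.0]), pr)[2] == 0.0
            # y = 0: decay flow from immune hosts only
            assert rhs(M3V, np.array([x, 0.0, z]), pr)[1] == pytest.approx(pr.l * x)

    def test_constant_mode_host_sum_reduces_to_two_component(self, rng):
        # with p_const = s the three-component flow projects exactly onto
        # the two-component flow in (u, z), u = x + y
        for growth, a in (("malthusian", 0.0), ("logistic", 1.0)):
            m3 = ModelSpec("three", growth, "constant")
            m2 = ModelSpec("two", growth, "constant")
            pr = random_params(rng, m3).replace(a=a)
            pr = pr.replace(p_const=pr.s)
            for _ in range(10):
                x, y, z = rng.uniform(0.01, 5.0, size=3)
                f3 = rhs(m3, np.array([x, y, z]), pr)
                f2 = rhs(m2, np.array([x + y, z]), pr)
                assert f3[0] + f3[1] == pytest.approx(f2[0], rel=1e-12, abs=1e-12)
                assert f3[2] == pytest.approx(f2[1], rel=1e-12, abs=1e-12)


class TestJacobian:
    @pytest.mark.parametrize("model", MODEL_VARIANTS, ids=str)
    def test_matches_finite_differences(self, model, rng):
        # analytic Jacobian vs central differences, 100 random draws split
        # over the variants
        for _ in range(13):
            pr = random_params(rng, model)
            state = rng.uniform(0.05, 5.0, size=model.dim)
            J = jacobian(model, state, pr)
            Jfd = np.zeros_like(J)
            for j in range(model.dim):
                h = 1e-6 * max(1.0, abs(state[j]))
                sp, sm = state.copy(), state.copy()
                sp[j] += h
                sm[j] -= h
                Jfd[:, j] = (rhs(model, sp, pr) - rhs(model, sm, pr)) / (2 * h)
            scale = np.max(np.abs(Jfd)) or 1.0
            assert np.max(np.abs(J - Jfd)) / scale < 1e-6

    def test_closed_form_eigenvalues_at_origin(self):
        params = Params(d=1.0, l=0.1, a=1.0)
        J = jacobian(M3V, np.zeros(3), params)
        eig = np.sort(np.linalg.eigvals(J).real)
        assert eig == pytest.approx([-1.0, 0.9, 1.0], abs=1e-12)

    def test_closed_form_eigenvalue_at_virus_free_point(self, fig2_setup):
        model, params = fig2_setup
        J = jacobian(model, np.array([0.0, 1.0, 0.0]), params)
        lam3 = (params.b * (params.M * (1 - params.s) - params.s) - params.d) / params.a
        eig = np.sort(np.linalg.eigvals(J).real)
        assert eig == pytest.approx(sorted([-params.l, -1.0, lam3]), abs=1e-9)
        assert lam3 == pytest.approx(2.919, abs=1e-3)


class TestParams:
    @pytest.mark.parametrize("bad", [
        dict(d=0.0), dict(M=-1.0), dict(b=0.0), dict(s=0.0), dict(s=1.0),
        dict(l=-0.1), dict(p_const=0.1, s=0.2), dict(p_const=1.5),
    ])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            Params(**bad)

    def test_growth_consistency_enforced(self):
        with pytest.raises(ValueError):
            ModelSpec("three", "malthusian", "virus_dependent").validate_params(
                Params(a=1.0))
        with pytest.raises(ValueError):
            ModelSpec("three", "logistic", "virus_dependent").validate_params(
                Params(a=0.0))
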