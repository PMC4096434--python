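"""Linear stability classification of equilibria.

Classification is by the eigenvalues of the analytic Jacobian: a fixed
point is a node/spiral (stable or unstable) by the sign of the largest
real part, a saddle when real parts of both signs occur, a center when a
purely imaginary pair dominates, and nonhyperbolic when the leading real
part sits inside the hyperbolicity tolerance without an imaginary part.

Closed-form eigenvalues are known at the trivial equilibria of the
three-component family and serve as independent checks:

* origin O:         {1, -d, 1 - l}
* virus-free A (logistic): {-l, -1, (b (M (1 - s) - s) - d a)/a}

The zero crossing of the third eigenvalue at A defines the transcritical
threshold M^tc handled in :mod:`crisprlv.bifurcation`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .equilibria import Equilibrium, interior_equilibria
from .model import ModelSpec, Params, jacobian

__all__ = [
    "StabilityReport",
    "analyze",
    "classify_eigenvalues",
    "closed_form_eigen_check",
    "malthusian_interior_instability",
]

#: |Re lambda| below this counts as a zero real part
HYPERBOLICITY_TOL = 1e-8


@dataclass(frozen=True)
class StabilityReport:
    """Eigenvalues (sorted by descending real part, ties by descending
    imaginary part) and the derived class label."""

    eigenvalues: tuple[complex, ...]
    class_label: str
    leading_real: float

    @property
    def is_stable(self) -> bool:
        return self.class_label in ("stable_node", "stable_spiral")


def _sort_eigs(vals: np.ndarray) -> tuple[complex, ...]:
    order = np.lexsort((-vals.imag, -vals.real))
    return tuple(complex(v) for v in vals[order])


def classify_eigenvalues(
    eigenvalues, tol: float = HYPERBOLICITY_TOL
) -> StabilityReport:
    """Build a :class:`StabilityReport` from raw eigenvalues."""
    vals = np.asarray(eigenvalues, dtype=complex)
    eigs = _sort_eigs(vals)
    re = np.array([v.real for v in eigs])
    im = np.array([v.imag for v in eigs])
    leading = float(re[0])

    near_zero = np.abs(re) <= tol
    has_complex = np.any(np.abs(im) > tol)
    if np.all(near_zero):
        label = "center" if has_complex else "nonhyperbolic"
    elif np.any(near_zero):
        label = "nonhyperbolic"
    elif np.all(re < 0):
        label = "stable_spiral" if has_complex else "stable_node"
    elif np.all(re > 0):
        label = "unstable_spiral" if has_complex else "unstable_node"
    else:
        label = "saddle"
    return StabilityReport(eigenvalues=eigs, class_label=label, leading_real=leading)


def analyze(
    eq: Equilibrium,
    model: ModelSpec,
    params: Params,
    tol: float = HYPERBOLICITY_TOL,
    residual_tol: float = 1e-8,
) -> StabilityReport:
    """Eigen-classify an equilibrium of the given model variant."""
    if eq.residual > residual_tol:
        raise ValueError(
            f"equilibrium residual {eq.residual:.3e} exceeds {residual_tol:.1e}; "
            "refine the fixed point before analyzing stability"
        )
    J = jacobian(model, eq.state, params)
    return classify_eigenvalues(np.linalg.eigvals(J), tol=tol)


def closed_form_eigen_check(
    model: ModelSpec, params: Params, tol: float = 1e-9
) -> bool:
    """Numeric Jacobian eigenvalues at O (and A, logistic case) against the
    closed forms; three-component models only."""
    if model.components != "three":
        raise ValueError("closed forms apply to the three-component model")
    model.validate_params(params)
    J_O = jacobian(model, np.zeros(3), params)
    eig_O = np.sort_complex(np.linalg.eigvals(J_O))
    expect_O = np.sort_complex(np.array([1.0, -params.d, 1.0 - params.l], dtype=complex))
    ok = bool(np.max(np.abs(eig_O - expect_O)) < tol)
    if params.a > 0:
        J_A = jacobian(model, np.array([0.0, 1.0 / params.a, 0.0]), params)
        eig_A = np.sort_complex(np.linalg.eigvals(J_A))
        lam3 = (params.b * (params.M * (1.0 - params.s) - params.s) - params.d * params.a) / params.a
        expect_A = np.sort_complex(np.array([-params.l, -1.0, lam3], dtype=complex))
        ok = ok and bool(np.max(np.abs(eig_A - expect_A)) < tol)
    return ok


def eigenvalues_highprec(
    model: ModelSpec, params: Params, eq: Equilibrium, dps: int = 50
) -> tuple[complex, ...]:
    """Jacobian eigenvalues at an interior equilibrium in ``dps``-digit
    arithmetic (mpmath).

    Needed when the equilibrium is near-degenerate: in the Malthusian
    three-component model the destabilizing real part of the complex pair
    is of order ``(1 - s) exp(-k z_e)`` — at typical parameters around
    1e-23, far below what a double-precision eigensolver can resolve.
    The fixed point is first re-polished with Newton iteration at the
    working precision, then the analytic Jacobian is evaluated and its
    eigenvalues computed, all in mpmath arithmetic.
    """
    import mpmath as mp

    if model.components != "three":
        raise NotImplementedError("high-precision path implemented for the "
                                  "three-component model")
    with mp.workdps(dps):
        l = mp.mpf(params.l); e = mp.mpf(params.e); d = mp.mpf(params.d)
        M = mp.mpf(params.M); b = mp.mpf(params.b); a = mp.mpf(params.a)
        s = mp.mpf(params.s)

        if model.immunity_mode == "constant":
            pc = mp.mpf(params.p_const)
            p_of = lambda z: pc
            pz_of = lambda z: mp.mpf(0)
        else:
            k = mp.mpf(params.k)
            p_of = lambda z: (1 - s) * mp.e ** (-k * z) + s
            pz_of = lambda z: k * (s - p_of(z))

        def F(x, y, z):
            p = p_of(z)
            return (
                x * (1 - l - a * (x + y)) - b * x * z * (1 - p) + e * s * y * z,
                y + l * x - a * y * (x + y) - b * y * z * (1 - s) - e * s * y * z,
                -d + b * M * (x * (1 - p) + y * (1 - s)) - b * (x * p + y * s),
            )

        root = mp.findroot(F, tuple(mp.mpf(v) for v in eq.state))
        x, y, z = root
        p = p_of(z)
        pz = pz_of(z)
        J = mp.matrix([
            [1 - l - a * x - a * (x + y) - b * z * (1 - p),
             -a * x + e * s * z,
             e * s * y - b * x * (1 - p) + b * x * z * pz],
            [l - a * y,
             1 - a * y - a * (x + y) - b * (1 - s) * z - e * s * z,
             -b * (1 - s) * y - e * s * y],
            [b * M * z * (1 - p) - b * z * p,
             b * M * (1 - s) * z - b * s * z,
             -d + b * M * (x * (1 - p) + y * (1 - s)) - b * (x * p + y * s)
             - b * (1 + M) * x * z * pz],
        ])
        vals = mp.eig(J, left=False, right=False)
        out = np.array([complex(v) for v in vals])
    return _sort_eigs(out)


def malthusian_interior_instability(params: Params, dps: int = 50) -> StabilityReport:
    """Stability report of the unique interior equilibrium of the
    Malthusian three-component virus-dependent model; for the documented
    parameter box it has one negative real eigenvalue and a complex pair
    with a (tiny) positive real part.

    The pair's real part scales like ``(1 - s) exp(-k z_e)`` and is
    usually indistinguishable from zero at double precision, so whenever
    the double-precision analysis comes out nonhyperbolic the eigenvalues
    are recomputed in extended precision.
    """
    model = ModelSpec("three", "malthusian", "virus_dependent")
    eqs = interior_equilibria(model, params)
    if not eqs:
        raise ValueError("no interior equilibrium at these parameters")
    if len(eqs) > 1:
        raise ValueError(f"expected a single interior equilibrium, found {len(eqs)}")
    report = analyze(eqs[0], model, params)
    if report.class_label in ("center", "nonhyperbolic"):
        eigs = eigenvalues_highprec(model, params, eqs[0], dps=dps)
        report = classify_eigenvalues(eigs, tol=10.0 ** (5 - dps))
    return report


def stability_row(report: StabilityReport) -> dict:
    """Columns appended to the TSV scan schema."""
    row: dict = {}
    for i, v in enumerate(report.eigenvalues, start=1):
        row[f"re{i}"] = v.real
        row[f"im{i}"] = v.imag
    row["class"] = report.class_label
    return row
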