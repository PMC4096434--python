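"""Bifurcation localization.

* Transcritical threshold ``M^tc = (a d + b s)/(b (1 - s))`` where the
  virus-free equilibrium A exchanges stability with the coexistence point.
* Hopf threshold: bisection on the real part of the leading complex
  eigenvalue pair along the continued interior equilibrium; two-parameter
  Hopf curves by repeating the search over a grid.
* Saddle-node of the two-component logistic virus-dependent model: solves
  the equilibrium conditions together with ``det J = 0``.
* Bogdanov-Takens point (same model): solves equilibrium conditions plus
  ``det J = 0`` and ``trace J = 0`` for ``(x, z, M, k)`` from a coarse grid
  of Newton starts.
* Supercriticality of a Hopf point is assessed numerically: a stable
  cycle must exist just above threshold and its amplitude follow the
  square-root law (log amplitude vs log offset slope ~ 0.5), replacing a
  symbolic first-Lyapunov-coefficient computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .dynamics import integrate
from .equilibria import Equilibrium, _make_eq, interior_equilibria
from .model import ModelSpec, Params, _jacobian_unchecked, jacobian

__all__ = [
    "BifurcationPoint",
    "transcritical_M",
    "hopf_threshold",
    "hopf_curve",
    "saddle_node_threshold",
    "bogdanov_takens_locate",
    "unstable_cycle_exists",
    "supercriticality_check",
]


class BracketError(ValueError):
    """The defining condition does not change sign over the given bracket."""


class ConvergenceError(RuntimeError):
    """Newton/bisection failed to converge; carries the best residual seen."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


@dataclass(frozen=True)
class BifurcationPoint:
    """A parameter value and equilibrium where a named degeneracy holds."""

    kind: str  # transcritical | hopf | saddle_node | bogdanov_takens
    param_name: str
    param_value: float
    equilibrium: Equilibrium | None = None
    omega: float | None = None  # imaginary part of the critical pair (Hopf)
    diagnostics: dict = field(default_factory=dict)


def transcritical_M(params: Params) -> float:
    """Exchange-of-stability threshold of the virus-free point A,
    ``(a d + b s) / (b (1 - s))``; logistic models only."""
    if params.a <= 0:
        raise ValueError("transcritical threshold requires logistic growth (a > 0)")
    if params.s >= 1.0:
        raise ValueError("s = 1 makes the threshold singular")
    return (params.a * params.d + params.b * params.s) / (params.b * (1.0 - params.s))


# ---------------------------------------------------------------------------
# Hopf
# ---------------------------------------------------------------------------


def _continued_equilibrium(
    model: ModelSpec, params: Params, z_ref: float | None
) -> Equilibrium:
    eqs = interior_equilibria(model, params)
    if not eqs:
        raise ConvergenceError("no interior equilibrium at these parameters")
    if z_ref is None or len(eqs) == 1:
        return eqs[0]
    return min(eqs, key=lambda q: abs(q.z - z_ref))


def _leading_pair(model: ModelSpec, params: Params, eq: Equilibrium) -> complex:
    vals = np.linalg.eigvals(jacobian(model, eq.state, params))
    pairs = vals[np.abs(vals.imag) > 1e-12]
    if len(pairs) == 0:
        raise ConvergenceError("eigenvalue pair collapsed to real values")
    lead = pairs[np.argmax(pairs.real)]
    return complex(lead.real, abs(lead.imag))


def hopf_threshold(
    model: ModelSpec,
    params: Params,
    param_name: str,
    bracket: tuple[float, float],
    max_iter: int = 60,
    re_tol: float = 1e-12,
) -> BifurcationPoint:
    """Bisect the real part of the leading complex pair along the continued
    interior equilibrium; returns the critical parameter value, the
    equilibrium there, the pair frequency omega, and a finite-difference
    transversality estimate d(Re)/d(param)."""
    lo, hi = float(bracket[0]), float(bracket[1])

    def re_at(val: float, z_ref: float | None):
        p = params.replace(**{param_name: val})
        eq = _continued_equilibrium(model, p, z_ref)
        lam = _leading_pair(model, p, eq)
        return lam, eq

    lam_lo, eq_lo = re_at(lo, None)
    lam_hi, eq_hi = re_at(hi, eq_lo.z)
    if lam_lo.real * lam_hi.real > 0:
        raise BracketError(
            f"Re(pair) has the same sign at both ends of [{lo}, {hi}]: "
            f"{lam_lo.real:.3e}, {lam_hi.real:.3e}"
        )
    z_ref = eq_lo.z
    lam_mid, eq_mid = lam_lo, eq_lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        lam_mid, eq_mid = re_at(mid, z_ref)
        z_ref = eq_mid.z
        if abs(lam_mid.real) < re_tol:
            lo = hi = mid
            break
        if lam_mid.real * lam_lo.real > 0:
            lo, lam_lo = mid, lam_mid
        else:
            hi = mid
    crit = 0.5 * (lo + hi)
    # transversality by centered finite difference
    h = max(1e-6 * abs(crit), 1e-8)
    lam_p, _ = re_at(crit + h, z_ref)
    lam_m, _ = re_at(crit - h, z_ref)
    dre = (lam_p.real - lam_m.real) / (2.0 * h)
    return BifurcationPoint(
        kind="hopf",
        param_name=param_name,
        param_value=crit,
        equilibrium=eq_mid,
        omega=lam_mid.imag,
        diagnostics={
            "re_pair": lam_mid.real,
            "transversality": dre,
            "bracket": (float(bracket[0]), float(bracket[1])),
        },
    )


def hopf_curve(
    model: ModelSpec,
    params: Params,
    free_param: str,
    M_grid,
    free_range: tuple[float, float],
    scan_points: int = 40,
) -> tuple[list[BifurcationPoint], list[float]]:
    """Two-parameter Hopf curve: for each M on the grid, bracket the free
    parameter in ``free_range`` and bisect.  Returns the located points
    (monotone in M) and the list of grid M values with no crossing."""
    if free_param not in ("e", "l", "s"):
        raise ValueError("free_param must be one of 'e', 'l', 's'")
    points: list[BifurcationPoint] = []
    gaps: list[float] = []
    lo, hi = free_range
    vals = np.linspace(lo, hi, scan_points)
    for M in M_grid:
        pM = params.replace(M=float(M))
        signs = []
        for v in vals:
            try:
                p = pM.replace(**{free_param: float(v)})
                eq = _continued_equilibrium(model, p, None)
                lam = _leading_pair(model, p, eq)
                signs.append((v, lam.real))
            except (ConvergenceError, ValueError):
                signs.append((v, None))
        bracket = None
        for (v0, r0), (v1, r1) in zip(signs[:-1], signs[1:]):
            if r0 is not None and r1 is not None and r0 * r1 < 0:
                bracket = (v0, v1)
                break
        if bracket is None:
            gaps.append(float(M))
            continue
        bp = hopf_threshold(model, pM, free_param, bracket)
        bp.diagnostics["M"] = float(M)
        points.append(bp)
    return points, gaps


# ---------------------------------------------------------------------------
# saddle-node and Bogdanov-Takens (two-component logistic, p(z))
# ---------------------------------------------------------------------------


def _two_comp_conditions(params: Params, with_trace: bool):
    """F(x, z, M[, k]) = (host eq, virus eq, det J [, trace J])."""

    def F(v):
        if with_trace:
            x, z, M, k = v
            p = params.replace(M=abs(M), k=abs(k))
        else:
            x, z, M = v
            p = params.replace(M=abs(M))
        model = ModelSpec("two", "logistic", "virus_dependent")
        b, d, a, s = p.b, p.d, p.a, p.s
        pz_val = (1.0 - s) * math.exp(-p.k * z) + s
        J = _jacobian_unchecked(model, np.array([x, z]), p)
        out = [
            1.0 - a * x - b * z * (1.0 - pz_val),
            -d - b * x * pz_val + b * p.M * x * (1.0 - pz_val),
            J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0],
        ]
        if with_trace:
            out.append(J[0, 0] + J[1, 1])
        return out

    return F


def saddle_node_threshold(
    params: Params,
    M_range: tuple[float, float] = (1.0, 200.0),
    scan_points: int = 80,
) -> BifurcationPoint:
    """M* where the two interior equilibria of the two-component logistic
    virus-dependent model collide; below M* there are none, above, two
    (a saddle and a stable node/spiral)."""
    model = ModelSpec("two", "logistic", "virus_dependent")
    model.validate_params(params)
    Ms = np.linspace(*M_range, scan_points)
    counts = []
    for M in Ms:
        counts.append(len(interior_equilibria(model, params.replace(M=float(M)))))
    jump = None
    for (M0, c0), (M1, c1) in zip(zip(Ms[:-1], counts[:-1]), zip(Ms[1:], counts[1:])):
        if c0 == 0 and c1 >= 2:
            jump = (M0, M1)
            break
    if jump is None:
        raise ConvergenceError("no 0 -> 2 equilibrium-count transition in M_range")
    lo, hi = jump
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if interior_equilibria(model, params.replace(M=mid)):
            hi = mid
        else:
            lo = mid
    M_star = 0.5 * (lo + hi)
    eqs = interior_equilibria(model, params.replace(M=hi))
    z_start = float(np.mean([q.z for q in eqs])) if eqs else 1.0
    x_start = float(np.mean([q.x for q in eqs])) if eqs else 1.0
    F = _two_comp_conditions(params, with_trace=False)
    sol = optimize.root(F, [x_start, z_start, M_star], method="hybr", tol=1e-13)
    res = float(np.max(np.abs(F(sol.x))))
    if not sol.success or res > 1e-9:
        raise ConvergenceError("saddle-node refinement failed", best_residual=res)
    x, z, M = sol.x
    p_at = params.replace(M=abs(M))
    eq = _make_eq(model, p_at, np.array([x, z]), "interior")
    J = jacobian(model, eq.state, p_at)
    return BifurcationPoint(
        kind="saddle_node",
        param_name="M",
        param_value=float(abs(M)),
        equilibrium=eq,
        diagnostics={"det_residual": float(np.linalg.det(J)),
                     "trace": float(np.trace(J)),
                     "condition_residual": res},
    )


def bogdanov_takens_locate(
    params: Params,
    M_starts=(5.0, 10.0, 20.0, 50.0, 100.0),
    k_starts=(0.2, 0.5, 1.0, 2.0),
) -> BifurcationPoint:
    """Double-zero eigenvalue point of the two-component logistic
    virus-dependent model: solves equilibrium + det J = 0 + trace J = 0
    for (x, z, M, k) from a coarse grid of starts."""
    model = ModelSpec("two", "logistic", "virus_dependent")
    F = _two_comp_conditions(params, with_trace=True)
    best: tuple[float, np.ndarray] | None = None
    for M0 in M_starts:
        for k0 in k_starts:
            eqs = interior_equilibria(model, params.replace(M=M0, k=k0))
            starts = [q.state for q in eqs] or [np.array([params.d / (params.b * M0) * 2.0, 1.0 / k0])]
            for st in starts:
                v0 = [st[0], st[1], M0, k0]
                sol = optimize.root(F, v0, method="hybr", tol=1e-13)
                res = float(np.max(np.abs(F(sol.x))))
                if best is None or res < best[0]:
                    best = (res, sol.x.copy())
                if sol.success and res < 1e-9 and np.all(np.abs(sol.x) > 0):
                    x, z, M, k = np.abs(sol.x)
                    if x <= 0 or z <= 0:
                        continue
                    p_at = params.replace(M=M, k=k)
                    eq = _make_eq(model, p_at, np.array([x, z]), "interior")
                    J = jacobian(model, eq.state, p_at)
                    eig = np.linalg.eigvals(J)
                    return BifurcationPoint(
                        kind="bogdanov_takens",
                        param_name="M,k",
                        param_value=float(M),
                        equilibrium=eq,
                        diagnostics={
                            "M": float(M), "k": float(k),
                            "det_residual": float(np.linalg.det(J)),
                            "trace_residual": float(np.trace(J)),
                            "condition_residual": res,
                            "eigenvalues": [complex(v) for v in eig],
                        },
                    )
    raise ConvergenceError(
        "Bogdanov-Takens search did not converge from any start",
        best_residual=None if best is None else best[0],
    )


# ---------------------------------------------------------------------------
# cycle-based checks
# ---------------------------------------------------------------------------


def unstable_cycle_exists(
    params: Params,
    t_end: float = 3000.0,
    perturbation: float = 0.02,
    dt: float = 0.05,
) -> bool:
    """Backward-time test for an unstable limit cycle around the stable
    spiral B2 of the two-component logistic virus-dependent model: in
    reversed time the spiral repels and the cycle attracts, so a bounded,
    non-stationary reversed orbit that settles to steady oscillation
    witnesses the cycle."""
    model = ModelSpec("two", "logistic", "virus_dependent")
    eqs = interior_equilibria(model, params)
    if len(eqs) < 2:
        return False
    b2 = eqs[-1]  # larger-z equilibrium is the node/spiral
    init = b2.state * (1.0 + perturbation)
    traj = integrate(model, params, init, t_end, dt=dt, backward=True)
    if any(lab == "unbounded" for _, lab in traj.events):
        return False
    tail = traj.window(0.75 * t_end)
    prev = traj.window(0.5 * t_end, 0.75 * t_end)
    # settled oscillation: amplitude well above the spiral's neighbourhood
    # and stationary between the two late windows
    amp_tail = float(np.ptp(tail.z))
    amp_prev = float(np.ptp(prev.z))
    if amp_tail < 10 * np.linalg.norm(b2.state) * perturbation:
        return False
    return abs(amp_tail - amp_prev) < 0.2 * max(amp_tail, amp_prev)


def supercriticality_check(
    model: ModelSpec,
    params: Params,
    hp: BifurcationPoint,
    rel_offsets=(1e-3, 3e-3, 1e-2, 3e-2, 1e-1),
    t_settle: float | None = None,
    dt: float = 0.1,
) -> dict:
    """Amplitude-scaling test of Hopf supercriticality.

    For each offset dM above the threshold, integrates from near the
    continued equilibrium until the cycle establishes and measures the
    virus-coordinate amplitude over the final quarter of the run; fits
    log(amplitude) against log(dM).  A supercritical Hopf gives a stable
    cycle with slope ~ 1/2.
    """
    if hp.kind != "hopf":
        raise ValueError("supercriticality check applies to Hopf points")
    name = hp.param_name
    crit = hp.param_value
    trans = abs(hp.diagnostics.get("transversality", 1e-3)) or 1e-3
    amps, offs = [], []
    for rel in rel_offsets:
        dM = rel * abs(crit)
        p = params.replace(**{name: crit + dM})
        eq = _continued_equilibrium(model, p, hp.equilibrium.z if hp.equilibrium else None)
        growth = trans * dM
        t_end = t_settle if t_settle is not None else min(4e5, max(2e4, 25.0 / growth))
        init = eq.state * 1.001
        traj = integrate(model, p, init, t_end, dt=dt)
        tail = traj.window(0.75 * t_end)
        amp = 0.5 * float(np.ptp(tail.z))
        if amp < 1e-8:
            return {"supercritical": False, "slope": None,
                    "note": f"no cycle found at offset {dM:.3g}"}
        amps.append(amp)
        offs.append(dM)
    slope = float(np.polyfit(np.log(offs), np.log(amps), 1)[0])
    return {
        "supercritical": bool(abs(slope - 0.5) < 0.2),
        "slope": slope,
        "offsets": list(offs),
        "amplitudes": list(amps),
    }
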