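"""Equilibrium finding for all model variants.

The interior (coexistence) equilibria are found through a scalar reduction
derived directly from the equilibrium conditions.  For the three-component
models, summing the two host equations and using the virus equation gives a
quadratic for the host total ``u = x + y`` at fixed virus density ``z``::

    a u^2 - u (1 + M - b z)/(M + 1) + d z/(M + 1) = 0

(single linear root ``u = d z / (1 + M - b z)`` in the Malthusian case).
The virus equation then fixes ``p x + s y = (b M u - d)/(b (M + 1))``,
which together with ``x + y = u`` determines ``(x, y)`` linearly whenever
``p(z) > s``.  The remaining condition — the sensitive-host equation — is a
scalar function of ``z`` whose sign changes are bracketed on a grid over
``(0, (1 + M)/b)`` and refined by bisection; every candidate is re-polished
by full multivariate root finding on the original system.

For the two-component models the virus equation gives
``x = d / (b (M (1 - p(z)) - p(z)))`` and the host equation supplies the
scalar residual in ``z``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .model import ModelSpec, Params, _rhs_unchecked, immunity

__all__ = [
    "Equilibrium",
    "trivial_equilibria",
    "interior_equilibria",
    "all_equilibria",
    "equilibrium_bound_check",
    "malthusian_z_independence",
    "brute_force_equilibria",
    "equilibria_table",
]

#: default residual tolerance for a converged equilibrium
RESIDUAL_TOL = 1e-10
#: merge roots closer than this in z
_Z_MERGE_TOL = 1e-6


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point of the flow.

    Attributes
    ----------
    state : ndarray
        Coordinates, ``(x, y, z)`` or ``(x, z)``.
    residual : float
        Max abs component of the right-hand side at ``state``.
    kind : str
        'trivial_O' (origin), 'boundary_A' (virus-free), or 'interior'.
    branch : str
        'plus'/'minus' for logistic host-total branch bookkeeping, else 'none'.
    """

    state: np.ndarray
    residual: float
    kind: str
    branch: str = "none"

    @property
    def x(self) -> float:
        return float(self.state[0])

    @property
    def y(self) -> float:
        if len(self.state) != 3:
            raise AttributeError("two-component equilibrium has no y coordinate")
        return float(self.state[1])

    @property
    def z(self) -> float:
        return float(self.state[-1])


def _make_eq(model: ModelSpec, params: Params, state, kind: str, branch: str = "none") -> Equilibrium:
    state = np.asarray(state, dtype=float)
    res = float(np.max(np.abs(_rhs_unchecked(model, state, params))))
    return Equilibrium(state=state, residual=res, kind=kind, branch=branch)


def trivial_equilibria(model: ModelSpec, params: Params) -> list[Equilibrium]:
    """The origin O, plus the virus-free point A when growth is logistic."""
    model.validate_params(params)
    out = [_make_eq(model, params, np.zeros(model.dim), "trivial_O")]
    if params.a > 0:
        if model.components == "three":
            out.append(_make_eq(model, params, (0.0, 1.0 / params.a, 0.0), "boundary_A"))
        else:
            out.append(_make_eq(model, params, (1.0 / params.a, 0.0), "boundary_A"))
    return out


# ---------------------------------------------------------------------------
# scalar reduction internals
# ---------------------------------------------------------------------------


def _host_totals(z: float, params: Params) -> list[tuple[float, str]]:
    """Positive candidate host totals u = x + y at virus density z."""
    a, b, d, M = params.a, params.b, params.d, params.M
    c1 = (1.0 + M - b * z) / (M + 1.0)
    c0 = d * z / (M + 1.0)
    if a == 0.0:
        if c1 <= 0.0:
            return []
        u = c0 / c1
        return [(u, "none")] if u > 0.0 else []
    disc = c1 * c1 - 4.0 * a * c0
    if disc < 0.0:
        return []
    r = math.sqrt(disc)
    out = []
    for u, br in (((c1 + r) / (2.0 * a), "plus"), ((c1 - r) / (2.0 * a), "minus")):
        if u > 0.0:
            out.append((u, br))
    return out


def _xy_from_uz(u: float, z: float, params: Params, p: float) -> tuple[float, float] | None:
    """Split the host total using the virus equilibrium condition
    p x + s y = (b M u - d) / (b (M + 1)); needs p != s."""
    b, d, M, s = params.b, params.d, params.M, params.s
    w = (b * M * u - d) / (b * (M + 1.0))
    if abs(p - s) < 1e-13:
        return None
    x = (w - s * u) / (p - s)
    return x, u - x


def _three_candidates(z: float, model: ModelSpec, params: Params):
    """Candidate (state, branch, residual-of-remaining-condition) at z."""
    p = immunity(z, params, model.immunity_mode)
    s = params.s
    out = []
    for u, br in _host_totals(z, params):
        if abs(p - s) < 1e-13:
            # p = s: the virus equation constrains z only; the host split
            # comes from the sensitive-host equation, linear in y.
            b, d, M = params.b, params.d, params.M
            g = s * u - (b * M * u - d) / (b * (M + 1.0))
            denom = params.l + params.a * u + b * z * (1.0 - s) + params.e * s * z - 1.0
            # the host split is defined by the sensitive-host balance; when
            # its denominator is nonpositive no positive split exists and
            # the midpoint start below lets the polisher reject the root
            y = params.l * u / denom if denom > 0.0 else 0.5 * u
            x = u - y
            out.append((np.array([x, y, z]), br, g))
        else:
            split = _xy_from_uz(u, z, params, p)
            if split is None:
                continue
            x, y = split
            st = np.array([x, y, z])
            g = float(_rhs_unchecked(model, st, params)[1])  # sensitive-host eq
            out.append((st, br, g))
    return out


def _two_candidate(z: float, model: ModelSpec, params: Params):
    p = immunity(z, params, model.immunity_mode)
    b, d, M, a = params.b, params.d, params.M, params.a
    denom = b * (M * (1.0 - p) - p)
    if denom <= 0.0:
        return None
    x = d / denom
    g = 1.0 - a * x - b * z * (1.0 - p)
    return np.array([x, z]), "none", g


def _reduced_system(model: ModelSpec, params: Params):
    """Equilibrium conditions with the structural zero at z=0 divided out."""
    if model.components == "three":

        def F(v):
            x, y, z = v
            p = immunity(max(z, 0.0), params, model.immunity_mode)
            l, e, d, M, b, a, s = (
                params.l, params.e, params.d, params.M, params.b, params.a, params.s,
            )
            return [
                x * (1.0 - l - a * (x + y)) - b * x * z * (1.0 - p) + e * s * y * z,
                y + l * x - a * y * (x + y) - b * y * z * (1.0 - s) - e * s * y * z,
                -d + b * M * (x * (1.0 - p) + y * (1.0 - s)) - b * (x * p + y * s),
            ]

    else:

        def F(v):
            x, z = v
            p = immunity(max(z, 0.0), params, model.immunity_mode)
            d, M, b, a = params.d, params.M, params.b, params.a
            return [
                1.0 - a * x - b * z * (1.0 - p),
                -d - b * x * p + b * M * x * (1.0 - p),
            ]

    return F


def _polish(model: ModelSpec, params: Params, start: np.ndarray) -> np.ndarray | None:
    sol = optimize.root(_reduced_system(model, params), start, method="hybr", tol=1e-13)
    if not sol.success:
        return None
    return sol.x


def interior_equilibria(
    model: ModelSpec,
    params: Params,
    grid_points: int = 2000,
    residual_tol: float = RESIDUAL_TOL,
) -> list[Equilibrium]:
    """All strictly positive equilibria, via scalar reduction in z.

    Sign changes of the reduced residual are bracketed on a ``grid_points``
    grid over ``0 < z < (1 + M)/b`` (per branch of the logistic host-total
    quadratic), refined by bisection, and re-polished on the full system.
    Returns an empty list when no positive equilibrium exists.
    """
    model.validate_params(params)
    z_hi = (1.0 + params.M) / params.b

    # z-intervals on which the host-total branches are real.  For logistic
    # growth the radicand of the u-quadratic is itself quadratic in z, so
    # the branch endpoints (folds of u in z) are known exactly and the scan
    # grids run right up to them; a naive uniform grid can otherwise step
    # over a root squeezed against a fold.
    intervals = [(z_hi * 1e-12, z_hi * (1.0 - 1e-9))]
    if model.components == "three" and params.a > 0:
        a, b, d, M = params.a, params.b, params.d, params.M
        coef = [b * b, -(2.0 * b * (1.0 + M) + 4.0 * a * d * (1.0 + M)),
                (1.0 + M) ** 2]
        r = np.roots(coef)
        r = np.sort(r.real[np.abs(r.imag) < 1e-9 * z_hi])
        if len(r) == 2 and r[0] > 0:
            z1, z2 = r
            eps = 1e-12 * z_hi
            intervals = [(eps, min(z1, z_hi) - eps)]
            if z2 < z_hi:
                intervals.append((z2 + eps, z_hi * (1.0 - 1e-9)))

    branches: dict[tuple[int, str], list[tuple[float, float]]] = {}
    for seg, (z_lo, z_up) in enumerate(intervals):
        if z_up <= z_lo:
            continue
        zs = np.unique(np.concatenate([
            np.linspace(z_lo, z_up, grid_points),
            np.geomspace(max(z_lo, z_hi * 1e-8), z_up, grid_points // 2),
        ]))
        for z in zs:
            if model.components == "three":
                cands = _three_candidates(z, model, params)
            else:
                c = _two_candidate(z, model, params)
                cands = [c] if c is not None else []
            for st, br, g in cands:
                branches.setdefault((seg, br), []).append((z, g))

    roots: list[tuple[float, str]] = []
    for (seg, br), pts in branches.items():
        for (z0, g0), (z1, g1) in zip(pts[:-1], pts[1:]):
            if g0 == 0.0:
                roots.append((z0, br))
            if g0 * g1 < 0.0:
                zr = optimize.brentq(
                    lambda z: _scalar_residual(z, model, params, br),
                    z0, z1, xtol=1e-14, rtol=8.9e-16,
                )
                roots.append((zr, br))

    found: list[Equilibrium] = []
    for zr, br in roots:
        start = _state_at(zr, model, params, br)
        if start is None:
            continue
        polished = _polish(model, params, start)
        if polished is None:
            continue
        if np.any(polished <= 0.0):
            continue
        eq = _make_eq(model, params, polished, "interior", br)
        if eq.residual > residual_tol:
            continue
        if any(abs(eq.z - other.z) < _Z_MERGE_TOL and
               np.allclose(eq.state, other.state, atol=1e-6) for other in found):
            continue
        found.append(eq)
    found.sort(key=lambda q: q.z)
    return found


def _scalar_residual(z: float, model: ModelSpec, params: Params, branch: str) -> float:
    if model.components == "three":
        for st, br, g in _three_candidates(z, model, params):
            if br == branch:
                return g
    else:
        c = _two_candidate(z, model, params)
        if c is not None:
            return c[2]
    return math.nan


def _state_at(z: float, model: ModelSpec, params: Params, branch: str) -> np.ndarray | None:
    if model.components == "three":
        for st, br, g in _three_candidates(z, model, params):
            if br == branch:
                return st
        return None
    c = _two_candidate(z, model, params)
    return None if c is None else c[0]


def all_equilibria(model: ModelSpec, params: Params, **kw) -> list[Equilibrium]:
    """Trivial, boundary and interior equilibria together."""
    return trivial_equilibria(model, params) + interior_equilibria(model, params, **kw)


def equilibrium_bound_check(eq: Equilibrium, params: Params) -> bool:
    """Interior equilibria of the three-component logistic model lie in the
    box ``0 <= x + y < 1`` (with a = 1), ``z < (1 + M)/b``."""
    if len(eq.state) != 3 or eq.kind != "interior":
        raise ValueError("bound check applies to three-component interior equilibria")
    return (0.0 <= eq.x + eq.y < 1.0) and (eq.z < (1.0 + params.M) / params.b)


def malthusian_z_independence(
    params: Params, M_values, model: ModelSpec | None = None
) -> list[float | None]:
    """Virus coordinates of the interior equilibrium across an M grid.

    For the Malthusian three-component virus-dependent model the z
    coordinate of the coexistence equilibrium is independent of the virus
    reproduction rate M; entries are None where no positive equilibrium
    exists at that M.
    """
    if model is None:
        model = ModelSpec("three", "malthusian", "virus_dependent")
    out: list[float | None] = []
    for M in M_values:
        eqs = interior_equilibria(model, params.replace(M=float(M)))
        out.append(eqs[0].z if len(eqs) == 1 else (None if not eqs else eqs[0].z))
    return out


def brute_force_equilibria(
    model: ModelSpec,
    params: Params,
    n_starts: int = 200,
    seed: int = 0,
    residual_tol: float = RESIDUAL_TOL,
) -> list[Equilibrium]:
    """Independent multistart root search over the bounding box of
    admissible equilibria; used to cross-check the scalar reduction."""
    model.validate_params(params)
    rng = np.random.default_rng(seed)
    z_hi = (1.0 + params.M) / params.b
    host_hi = 1.0 / params.a if params.a > 0 else max(10.0, 10.0 * params.d / params.b)
    F = _reduced_system(model, params)
    found: list[Equilibrium] = []
    z_lo = z_hi * 1e-6
    for _ in range(n_starts):
        z0 = math.exp(rng.uniform(math.log(z_lo), math.log(z_hi)))
        if model.components == "three":
            start = np.array([rng.uniform(0, host_hi), rng.uniform(0, host_hi), z0])
        else:
            start = np.array([rng.uniform(0, host_hi), z0])
        sol = optimize.root(F, start, method="hybr", tol=1e-13)
        if not sol.success or np.any(sol.x <= 0.0):
            continue
        eq = _make_eq(model, params, sol.x, "interior")
        if eq.residual > residual_tol:
            continue
        if any(np.allclose(eq.state, o.state, atol=1e-6, rtol=1e-6) for o in found):
            continue
        found.append(eq)
    found.sort(key=lambda q: q.z)
    return found


def equilibria_table(
    model: ModelSpec, params: Params, eqs: list[Equilibrium]
) -> list[dict]:
    """Rows for the TSV scan export."""
    rows = []
    for eq in eqs:
        row = {
            "model": model.components,
            "growth": model.growth,
            "immunity_mode": model.immunity_mode,
            "l": params.l, "e": params.e, "d": params.d, "M": params.M,
            "b": params.b, "a": params.a, "k": params.k, "s": params.s,
            "p_const": params.p_const if params.p_const is not None else "",
            "x_e": eq.x,
            "y_e": eq.y if len(eq.state) == 3 else "",
            "z_e": eq.z,
            "residual": eq.residual,
            "kind": eq.kind,
            "branch": eq.branch,
        }
        rows.append(row)
    return rows
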