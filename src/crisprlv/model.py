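"""Model family for virus-host coevolution with CRISPR-like adaptive immunity.

The family couples a virus population ``z`` to one or two host classes:
immune hosts ``x`` (immunity level ``p``) and, in the three-component
variants, sensitive hosts ``y`` (innate immunity ``s`` only).  Hosts grow
either exponentially (Malthusian, ``a = 0``) or logistically (``a > 0``);
the adaptive immunity level is either a constant ``p_const`` or declines
with the virus load as ``p(z) = (1 - s) exp(-k z) + s``.

Three-component dynamics::

    dx/dt = x (1 - l - a (x + y)) - b x z (1 - p) + e s y z
    dy/dt = y + l x - a y (x + y) - b y z (1 - s) - e s y z
    dz/dt = z (-d + b M (x (1 - p) + y (1 - s)) - b (x p + y s))

Two-component dynamics (single host class ``x`` with immunity ``p``)::

    dx/dt = x (1 - a x - b z (1 - p))
    dz/dt = z (-d - b x p + b M x (1 - p))

Growth rates of both host classes are fixed at 1; all other rates are free
parameters (see :class:`Params`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Params",
    "ModelSpec",
    "immunity",
    "immunity_derivative",
    "rhs",
    "jacobian",
    "MODEL_VARIANTS",
]

#: numerical slack below zero tolerated in state validation
_NEG_SLACK = 1e-12


@dataclass(frozen=True)
class Params:
    """Parameter vector of the model family.

    Parameters
    ----------
    l : float
        Immunity decay rate (immune -> sensitive flow), per unit time, >= 0.
    e : float
        Immunity acquisition rate (sensitive -> immune on surviving an
        encounter), per unit time, >= 0.
    d : float
        Virus death rate, > 0.
    M : float
        Virus reproduction rate (burst factor), dimensionless, > 0.
    b : float
        Encounter rate coefficient, > 0.
    a : float
        Host density-dependence coefficient; ``a = 0`` is Malthusian growth,
        ``a > 0`` logistic.
    k : float
        Steepness of the immunity decline with virus density (only used in
        virus-dependent immunity mode), > 0.
    s : float
        Innate immunity of sensitive hosts, 0 < s < 1.
    p_const : float or None
        Constant immunity level of immune hosts (only used in constant
        immunity mode); must satisfy ``s <= p_const <= 1``.
    """

    l: float = 0.1
    e: float = 0.5
    d: float = 1.0
    M: float = 100.0
    b: float = 0.05
    a: float = 0.0
    k: float = 0.1
    s: float = 0.2
    p_const: float | None = None

    def __post_init__(self) -> None:
        if not (self.d > 0 and self.M > 0 and self.b > 0):
            raise ValueError("d, M, b must be strictly positive")
        if self.l < 0 or self.e < 0 or self.a < 0 or self.k < 0:
            raise ValueError("rates l, e, a, k must be nonnegative")
        if not (0.0 < self.s < 1.0):
            raise ValueError("innate immunity s must satisfy 0 < s < 1")
        if self.p_const is not None and not (self.s <= self.p_const <= 1.0):
            raise ValueError("constant immunity must satisfy s <= p_const <= 1")

    def replace(self, **changes) -> "Params":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class ModelSpec:
    """Which member of the model family is meant.

    components : 'two' | 'three'
    growth     : 'malthusian' | 'logistic'
    immunity_mode : 'constant' | 'virus_dependent'
    """

    components: str = "three"
    growth: str = "logistic"
    immunity_mode: str = "virus_dependent"

    def __post_init__(self) -> None:
        if self.components not in ("two", "three"):
            raise ValueError(f"components must be 'two' or 'three', got {self.components!r}")
        if self.growth not in ("malthusian", "logistic"):
            raise ValueError(f"growth must be 'malthusian' or 'logistic', got {self.growth!r}")
        if self.immunity_mode not in ("constant", "virus_dependent"):
            raise ValueError(
                f"immunity_mode must be 'constant' or 'virus_dependent', got {self.immunity_mode!r}"
            )

    @property
    def dim(self) -> int:
        return 2 if self.components == "two" else 3

    def validate_params(self, params: Params) -> None:
        """Check cross-invariants between the spec and a parameter vector."""
        if self.growth == "malthusian" and params.a != 0.0:
            raise ValueError("Malthusian growth requires a = 0")
        if self.growth == "logistic" and params.a <= 0.0:
            raise ValueError("logistic growth requires a > 0")
        if self.immunity_mode == "constant" and params.p_const is None:
            raise ValueError("constant immunity mode requires p_const")
        if self.immunity_mode == "virus_dependent" and params.k <= 0.0:
            raise ValueError("virus-dependent immunity requires k > 0")


#: the eight (components, growth, immunity_mode) combinations
MODEL_VARIANTS: tuple[ModelSpec, ...] = tuple(
    ModelSpec(c, g, m)
    for c in ("two", "three")
    for g in ("malthusian", "logistic")
    for m in ("constant", "virus_dependent")
)


def immunity(z, params: Params, mode: str = "virus_dependent"):
    """Immunity level of the immune host class at virus density ``z``.

    Constant mode returns ``p_const``; virus-dependent mode returns
    ``(1 - s) exp(-k z) + s``, which decreases from 1 at ``z = 0`` to the
    innate level ``s`` as ``z -> inf``.  Accepts scalars or arrays.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("virus density z must be nonnegative")
    if mode == "constant":
        if params.p_const is None:
            raise ValueError("constant immunity mode requires p_const")
        out = np.full_like(z, params.p_const)
    elif mode == "virus_dependent":
        out = (1.0 - params.s) * np.exp(-params.k * z) + params.s
    else:
        raise ValueError(f"unknown immunity mode {mode!r}")
    return out if out.ndim else float(out)


def immunity_derivative(z, params: Params, mode: str = "virus_dependent"):
    """d p / d z; zero in constant mode, ``k (s - p(z))`` otherwise."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("virus density z must be nonnegative")
    if mode == "constant":
        out = np.zeros_like(z)
    elif mode == "virus_dependent":
        p = (1.0 - params.s) * np.exp(-params.k * z) + params.s
        out = params.k * (params.s - p)
    else:
        raise ValueError(f"unknown immunity mode {mode!r}")
    return out if out.ndim else float(out)


def _check_state(model: ModelSpec, state) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.shape != (model.dim,):
        raise ValueError(f"state must have shape ({model.dim},), got {state.shape}")
    if np.any(state < -_NEG_SLACK):
        raise ValueError(f"state must lie in the nonnegative orthant, got {state}")
    return state


def _immunity_nocheck(z: float, params: Params, mode: str) -> float:
    """Immunity law extended smoothly to any real z (integrator internals)."""
    if mode == "constant":
        return params.p_const
    return (1.0 - params.s) * math.exp(-params.k * z) + params.s


def _rhs_unchecked(model: ModelSpec, state: np.ndarray, params: Params) -> np.ndarray:
    """Right-hand side without domain validation (used by integrators,
    where the vector field extends smoothly past the orthant faces)."""
    l, e, d, M, b, a, s = (
        params.l, params.e, params.d, params.M, params.b, params.a, params.s,
    )
    if model.components == "three":
        x, y, z = state
        p = _immunity_nocheck(z, params, model.immunity_mode)
        dx = x * (1.0 - l - a * (x + y)) - b * x * z * (1.0 - p) + e * s * y * z
        dy = y + l * x - a * y * (x + y) - b * y * z * (1.0 - s) - e * s * y * z
        dz = z * (-d + b * M * (x * (1.0 - p) + y * (1.0 - s)) - b * (x * p + y * s))
        return np.array([dx, dy, dz])
    x, z = state
    p = _immunity_nocheck(z, params, model.immunity_mode)
    dx = x * (1.0 - a * x - b * z * (1.0 - p))
    dz = z * (-d - b * x * p + b * M * x * (1.0 - p))
    return np.array([dx, dz])


def rhs(model: ModelSpec, state, params: Params) -> np.ndarray:
    """Time derivative of the state under the chosen model variant."""
    model.validate_params(params)
    state = _check_state(model, state)
    return _rhs_unchecked(model, np.maximum(state, 0.0), params)


def _jacobian_unchecked(model: ModelSpec, state: np.ndarray, params: Params) -> np.ndarray:
    l, e, d, M, b, a, s = (
        params.l, params.e, params.d, params.M, params.b, params.a, params.s,
    )

    def _pz(zv: float, pv: float) -> float:
        return 0.0 if model.immunity_mode == "constant" else params.k * (params.s - pv)

    if model.components == "three":
        x, y, z = state
        p = _immunity_nocheck(z, params, model.immunity_mode)
        pz = _pz(z, p)
        return np.array(
            [
                [
                    1.0 - l - a * x - a * (x + y) - b * z * (1.0 - p),
                    -a * x + e * s * z,
                    e * s * y - b * x * (1.0 - p) + b * x * z * pz,
                ],
                [
                    l - a * y,
                    1.0 - a * y - a * (x + y) - b * (1.0 - s) * z - e * s * z,
                    -b * (1.0 - s) * y - e * s * y,
                ],
                [
                    b * M * z * (1.0 - p) - b * z * p,
                    b * M * (1.0 - s) * z - b * s * z,
                    -d + b * M * (x * (1.0 - p) + y * (1.0 - s))
                    - b * (x * p + y * s)
                    - b * (1.0 + M) * x * z * pz,
                ],
            ]
        )
    x, z = state
    p = _immunity_nocheck(z, params, model.immunity_mode)
    pz = _pz(z, p)
    return np.array(
        [
            [
                1.0 - 2.0 * a * x - b * z * (1.0 - p),
                -b * x * (1.0 - p) + b * x * z * pz,
            ],
            [
                b * z * (M * (1.0 - p) - p),
                -d + b * x * (M * (1.0 - p) - p) - b * (1.0 + M) * x * z * pz,
            ],
        ]
    )


def jacobian(model: ModelSpec, state, params: Params) -> np.ndarray:
    """Analytic Jacobian matrix of :func:`rhs` at ``state``."""
    model.validate_params(params)
    state = _check_state(model, state)
    return _jacobian_unchecked(model, np.maximum(state, 0.0), params)
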