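"""Named parameter scenarios.

Each scenario bundles a model variant, its parameter vector, an initial
condition recipe and a default horizon.  The virus death rate defaults to
d = 1 wherever a scenario's source figure leaves it unprinted; the
provenance string on each scenario records where its numbers come from.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .equilibria import interior_equilibria
from .model import ModelSpec, Params

__all__ = ["Scenario", "scenario", "scenario_names", "SCENARIOS"]


@dataclass(frozen=True)
class Scenario:
    name: str
    model: ModelSpec
    params: Params
    init: tuple[float, ...] | str  # explicit state or "at_equilibrium"
    t_end: float
    perturbation: float = 0.0  # relative, applied when init is "at_equilibrium"
    provenance: str = ""

    def resolve_init(self) -> np.ndarray:
        """Concrete initial state (computes the interior equilibrium and
        applies the relative perturbation when init is 'at_equilibrium')."""
        if isinstance(self.init, str):
            if self.init != "at_equilibrium":
                raise ValueError(f"unknown init recipe {self.init!r}")
            eqs = interior_equilibria(self.model, self.params)
            if not eqs:
                raise ValueError(f"scenario {self.name}: no interior equilibrium")
            return eqs[0].state * (1.0 + self.perturbation)
        return np.asarray(self.init, dtype=float)

    def to_config(self) -> str:
        """Flat JSON serialization (round-trips losslessly)."""
        d = {
            "name": self.name,
            "components": self.model.components,
            "growth": self.model.growth,
            "immunity_mode": self.model.immunity_mode,
            **{k: v for k, v in asdict(self.params).items()},
            "init": list(self.init) if not isinstance(self.init, str) else self.init,
            "t_end": self.t_end,
            "perturbation": self.perturbation,
            "provenance": self.provenance,
        }
        return json.dumps(d, indent=1, sort_keys=True)

    @staticmethod
    def from_config(text: str) -> "Scenario":
        d = json.loads(text)
        model = ModelSpec(d.pop("components"), d.pop("growth"), d.pop("immunity_mode"))
        init = d.pop("init")
        if not isinstance(init, str):
            init = tuple(float(v) for v in init)
        params = Params(**{k: d.pop(k) for k in
                           ("l", "e", "d", "M", "b", "a", "k", "s", "p_const")})
        return Scenario(name=d.pop("name"), model=model, params=params, init=init,
                        t_end=float(d.pop("t_end")),
                        perturbation=float(d.pop("perturbation", 0.0)),
                        provenance=d.pop("provenance", ""))


_FIG2_PARAMS = Params(l=0.1, e=0.5, d=1.0, M=98.225, b=0.05, a=1.0, k=0.1, s=0.2)
_AF1_PARAMS = Params(l=0.0, e=0.0, d=1.0, M=12.0, b=0.1, a=1.0, k=1.0, s=0.15)

SCENARIOS: dict[str, Scenario] = {}


def _register(sc: Scenario) -> None:
    SCENARIOS[sc.name] = sc


_register(Scenario(
    name="fig1",
    model=ModelSpec("three", "malthusian", "virus_dependent"),
    params=Params(l=0.9, e=0.1, d=1.0, M=100.0, b=0.01, a=0.0, k=0.5, s=0.1),
    init=(0.07, 0.15, 22.25),
    t_end=10000.0,
    provenance="Figure 1: Malthusian three-component, l=0.9, e=0.1, M=100, "
               "d=1, b=0.01, k=0.5, s=0.1; init close to the equilibrium",
))
_register(Scenario(
    name="fig2",
    model=ModelSpec("three", "logistic", "virus_dependent"),
    params=_FIG2_PARAMS,
    init="at_equilibrium",
    perturbation=0.01,
    t_end=20000.0,
    provenance="Figure 2: logistic three-component, M=98.225 below the Hopf "
               "threshold; k=0.1, s=0.2, b=0.05, l=0.1, e=0.5, d=1 (default)",
))
_register(Scenario(
    name="fig3",
    model=ModelSpec("three", "logistic", "virus_dependent"),
    params=_FIG2_PARAMS.replace(M=98.226),
    init=(0.4, 0.05, 35.0),
    t_end=20000.0,
    provenance="Figure 3: as fig2 with M=98.226; the displayed attractor is "
               "the large stable limit cycle that coexists with the locally "
               "stable equilibrium, so the start is placed in the cycle's basin",
))
_register(Scenario(
    name="fig4",
    model=ModelSpec("three", "logistic", "virus_dependent"),
    params=_FIG2_PARAMS.replace(M=98.226),
    init=(0.4, 0.05, 35.0),
    t_end=20000.0,
    provenance="Figure 4: established limit cycle of fig3 (late-time window)",
))
_register(Scenario(
    name="fig5_6",
    model=ModelSpec("three", "logistic", "virus_dependent"),
    params=_FIG2_PARAMS.replace(M=500.0),
    init="at_equilibrium",
    perturbation=0.01,
    t_end=40000.0,
    provenance="Figures 5-6: as fig2 with M=500, quasi-chaotic oscillations "
               "(the amplitude modulation of the virus peaks develops slowly, "
               "hence the long horizon)",
))
for _name, _M in (("af1_domain0", 12.0), ("af1_domain1", 25.0), ("af1_domain2", 100.0)):
    _register(Scenario(
        name=_name,
        model=ModelSpec("two", "logistic", "virus_dependent"),
        params=_AF1_PARAMS.replace(M=_M),
        init=(0.5, 1.0),
        t_end=3000.0,
        provenance=f"Additional file 1: two-component logistic, a=1, b=0.1, "
                   f"d=1, k=1, s=0.15, M={_M:g}",
    ))
for _name, _free, _pp in (
    ("af4_eH", "e", Params(l=0.1, e=0.5, d=1.0, M=100.0, b=0.05, a=1.0, k=0.2, s=0.2)),
    ("af4_lH", "l", Params(l=0.1, e=0.5, d=1.0, M=100.0, b=0.05, a=1.0, k=0.2, s=0.2)),
    ("af4_sH", "s", Params(l=0.1, e=0.5, d=1.0, M=100.0, b=0.05, a=1.0, k=0.2, s=0.2)),
):
    _register(Scenario(
        name=_name,
        model=ModelSpec("three", "logistic", "virus_dependent"),
        params=_pp,
        init="at_equilibrium",
        t_end=10000.0,
        provenance=f"Additional file 4: Hopf curve {_free}_H(M), fixed "
                   f"b=0.05, k=0.2 (free parameter {_free})",
    ))
_register(Scenario(
    name="conservative_demo",
    model=ModelSpec("two", "malthusian", "constant"),
    params=Params(l=0.0, e=0.0, d=1.0, M=100.0, b=0.01, a=0.0, k=0.1, s=0.2,
                  p_const=0.5),
    init=(2.5, 180.0),
    t_end=10000.0,
    provenance="Conservative two-component Malthusian constant-immunity demo; "
               "center at (d/(b(M(1-p)-p)), 1/(b(1-p))) = (2.0202, 200)",
))


def scenario_names() -> list[str]:
    return sorted(SCENARIOS)


def scenario(name: str) -> Scenario:
    """Look up a named scenario; raises KeyError listing the registry."""
    try:
        return SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(scenario_names())}"
        ) from None
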