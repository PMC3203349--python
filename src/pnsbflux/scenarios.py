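"""Environmental scenarios as declarative constraint sets.

A scenario fixes a set of reaction rates (mostly to zero, encoding
closed exchanges and regulatorily silent pathways), normalizes one
substrate uptake to 1 mmol/(gDW*h), and closes the remaining substrate
uptakes.  Scenario definitions live in a shipped, human-editable YAML
file; this module turns them into :class:`Scenario` objects and applies
single-reaction overrides (knockouts, deregulations, perturbations).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import yaml

__all__ = ["Scenario", "make_scenario", "apply_override", "scenario_table", "FREE"]

#: Sentinel accepted by :func:`apply_override` to un-fix a reaction.
FREE = "free"


def _load_yaml():
    path = resources.files("pnsbflux.data").joinpath("scenarios.yaml")
    with path.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class Scenario:
    """A named constraint set.

    ``fixed_fluxes`` maps reaction id -> fixed rate (zeros encode closed
    pathways and exchanges).  ``substrate`` is the uptake reaction
    normalized to ``substrate_rate`` (1 by default); it is merged into
    the effective fixes.  ``open_excretions`` documents gates left open.
    """

    name: str
    fixed_fluxes: Mapping[str, float] = field(default_factory=dict)
    substrate: str | None = None
    substrate_rate: float = 1.0
    open_excretions: frozenset[str] = frozenset()
    species: str | None = None
    notes: str = ""

    def __post_init__(self):
        fixes = dict(self.fixed_fluxes)
        clash = set(fixes) & set(self.open_excretions)
        if clash:
            raise ValueError(f"reactions both fixed and open: {sorted(clash)}")
        if self.substrate is not None and self.substrate in fixes:
            raise ValueError(f"substrate {self.substrate} is also fixed")
        object.__setattr__(self, "fixed_fluxes", fixes)
        object.__setattr__(self, "open_excretions", frozenset(self.open_excretions))

    def effective_fixes(self) -> dict[str, float]:
        fixes = dict(self.fixed_fluxes)
        if self.substrate is not None:
            fixes[self.substrate] = self.substrate_rate
        return fixes


def scenario_table() -> dict:
    """The raw shipped scenario definitions (parsed YAML)."""
    return _load_yaml()


def make_scenario(
    name: str,
    substrate: str | None = None,
    substrate_rate: float = 1.0,
    species: str | None = None,
    extra_fixes: Mapping[str, float] | None = None,
) -> Scenario:
    """Build one of the named scenarios S1..S7 for a given substrate.

    ``substrate`` may be a substrate name ("succinate", "malate",
    "acetate", "propionate", "fructose", "hydrogen") or directly an
    uptake reaction id.  All other substrate uptakes are fixed to zero.
    """
    table = _load_yaml()
    defs = table["scenarios"]
    if name not in defs:
        raise ValueError(f"unknown scenario {name!r}; have {sorted(defs)}")
    entry = defs[name]
    fixes: dict[str, float] = {}
    if "base" in entry:
        fixes.update({k: float(v) for k, v in defs[entry["base"]].get("fix", {}).items()})
    fixes.update({k: float(v) for k, v in entry.get("fix", {}).items()})
    free = set(entry.get("free", []))
    for rid in free:
        fixes.pop(rid, None)

    substrate_id = None
    if substrate is not None:
        substrate_id = table["substrates"].get(substrate, substrate)
        if substrate_id not in table["uptakes"]:
            raise ValueError(
                f"substrate {substrate!r} is not a declared uptake "
                f"({sorted(table['substrates'])})"
            )
        for uptake in table["uptakes"]:
            if uptake != substrate_id:
                fixes.setdefault(uptake, 0.0)
    if extra_fixes:
        fixes.update({k: float(v) for k, v in extra_fixes.items()})
    return Scenario(
        name=name,
        fixed_fluxes=fixes,
        substrate=substrate_id,
        substrate_rate=substrate_rate,
        open_excretions=frozenset(free),
        species=species,
        notes=entry.get("description", ""),
    )


def apply_override(scenario: Scenario, reaction_id: str, value) -> Scenario:
    """Return a new scenario with one entry changed; original untouched.

    ``value`` is a rate (fix the reaction) or the string ``"free"``
    (remove any fix).  Overriding the substrate uptake re-normalizes it.
    """
    if reaction_id == scenario.substrate:
        if value == FREE:
            return replace(scenario, substrate=None)
        return replace(scenario, substrate_rate=float(value))
    fixes = dict(scenario.fixed_fluxes)
    open_ex = set(scenario.open_excretions)
    if value == FREE:
        fixes.pop(reaction_id, None)
    else:
        fixes[reaction_id] = float(value)
        open_ex.discard(reaction_id)
    return replace(
        scenario, fixed_fluxes=fixes, open_excretions=frozenset(open_ex)
    )
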