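"""Flux variability analysis (LP min/max per reaction).

For each reaction i the engine solves

    min / max  r_i   s.t.  N r = 0,  fixed rates,  box bounds,

with the box bounds [0, cap] for irreversible and [-cap, cap] for
reversible reactions (cap = model.default_bound).  A reaction whose
computed bounds coincide within the uniqueness tolerance is *uniquely
determined* by the scenario; the upper bound of the biomass reaction is
the optimal molar growth yield.  The LP backend is deterministic
(scipy/HiGHS with fixed settings), so results carry no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.optimize import linprog

from pnsbflux.core import FluxRange, MetabolicModel, stoich_matrix_float
from pnsbflux.scenarios import Scenario

__all__ = ["FvaError", "InfeasibleScenario", "FvaResult", "solve_fva", "max_yield",
           "classify_fluxes", "write_fva_tsv", "read_fva_tsv"]

#: |max - min| <= UNIQUE_TOL_FACTOR * default_bound => unique flux.
UNIQUE_TOL_FACTOR = 1e-6
#: reported values within ZERO_SNAP of zero are snapped for reporting.
ZERO_SNAP = 1e-9
_LP_OPTIONS = {"presolve": True}


class FvaError(RuntimeError):
    pass


class InfeasibleScenario(FvaError):
    """Raised by operations that cannot proceed on an infeasible scenario."""


@dataclass
class FvaResult:
    """Per-reaction flux ranges of one scenario.

    ``status`` is "optimal" or "infeasible"; an infeasible scenario
    carries no ranges (never partial output).
    """

    scenario: str
    status: str
    ranges: dict[str, FluxRange] = field(default_factory=dict)
    tolerance: float = 0.0

    @property
    def feasible(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rid: str) -> FluxRange:
        if not self.feasible:
            raise InfeasibleScenario(
                f"scenario {self.scenario!r} is infeasible; no flux ranges"
            )
        return self.ranges[rid]

    def unique_value(self, rid: str) -> float:
        fr = self[rid]
        if not fr.unique:
            raise FvaError(f"flux {rid} is not uniquely determined "
                           f"([{fr.min:.6g}, {fr.max:.6g}])")
        return 0.5 * (fr.min + fr.max)


def _snap(x: float) -> float:
    return 0.0 if abs(x) < ZERO_SNAP else x


def _problem(model: MetabolicModel, scenario: Scenario):
    A = stoich_matrix_float(model)
    b = np.zeros(A.shape[0])
    bounds = []
    fixes = scenario.effective_fixes()
    unknown = [rid for rid in fixes if not model.has_reaction(rid)]
    if unknown:
        raise FvaError(
            f"scenario {scenario.name!r} references unknown reactions {sorted(unknown)}"
        )
    for rxn in model.reactions:
        if rxn.id in fixes:
            v = fixes[rxn.id]
            bounds.append((v, v))
        else:
            bounds.append(model.bounds(rxn))
    return A, b, bounds, fixes


def _solve(c, A, b, bounds) -> tuple[str, float]:
    res = linprog(c, A_eq=A, b_eq=b, bounds=bounds, method="highs",
                  options=_LP_OPTIONS)
    if res.status == 0:
        return "optimal", float(res.fun)
    if res.status == 2:
        return "infeasible", float("nan")
    if res.status == 3:  # unbounded: impossible with finite caps
        raise FvaError("unbounded LP encountered despite finite flux caps")
    raise FvaError(f"LP solver failure: {res.message}")


def solve_fva(
    model: MetabolicModel,
    scenario: Scenario,
    reactions: Iterable[str] | None = None,
) -> FvaResult:
    """Run FVA for all (or a subset of) reactions under a scenario.

    Reactions fixed by the scenario are reported at their fixed value
    with ``unique=True`` without re-optimization.  An infeasible
    constraint set yields ``status="infeasible"`` with the scenario name
    echoed and no ranges.
    """
    if not model.reactions:
        raise FvaError("model has no reactions")
    A, b, bounds, fixes = _problem(model, scenario)
    tol = UNIQUE_TOL_FACTOR * model.default_bound

    # feasibility probe
    status, _ = _solve(np.zeros(len(model.reactions)), A, b, bounds)
    if status == "infeasible":
        return FvaResult(scenario=scenario.name, status="infeasible", tolerance=tol)

    if reactions is None:
        targets = model.reaction_ids()
    else:
        targets = list(reactions)
        for rid in targets:
            model.reaction(rid)  # raises on unknown id

    ranges: dict[str, FluxRange] = {}
    q = len(model.reactions)
    index = {rid: j for j, rid in enumerate(model.reaction_ids())}
    for rid in targets:
        if rid in fixes:
            v = _snap(fixes[rid])
            ranges[rid] = FluxRange(rid, v, v, True)
            continue
        c = np.zeros(q)
        c[index[rid]] = 1.0
        st_lo, lo = _solve(c, A, b, bounds)
        c[index[rid]] = -1.0
        st_hi, hi = _solve(c, A, b, bounds)
        if "infeasible" in (st_lo, st_hi):  # cannot happen after the probe
            raise FvaError(f"LP for {rid} infeasible in a feasible scenario")
        hi = -hi
        if lo > hi:  # numerical crossing of coincident bounds
            lo = hi = 0.5 * (lo + hi)
        ranges[rid] = FluxRange(rid, _snap(lo), _snap(hi), (hi - lo) <= tol)
    return FvaResult(scenario=scenario.name, status="optimal", ranges=ranges,
                     tolerance=tol)


def max_yield(model: MetabolicModel, scenario: Scenario,
              objective_reaction: str = "BIOMASS") -> float:
    """FVA maximum of one reaction; for the biomass reaction with a unit
    substrate uptake this is the optimal molar growth yield Y_X/S."""
    result = solve_fva(model, scenario, reactions=[objective_reaction])
    if not result.feasible:
        raise InfeasibleScenario(f"scenario {scenario.name!r} infeasible")
    return result[objective_reaction].max


def classify_fluxes(result: FvaResult, zero_tol: float | None = None) -> dict:
    """Partition reactions into unique / trivially-zero / free classes.

    zero-class: unique and |value| <= tolerance (a zero enforced by the
    constraints); unique-class: coincident nonzero bounds; free: the
    rest.  The three lists partition the reaction set.
    """
    if not result.feasible:
        raise InfeasibleScenario(
            f"cannot classify fluxes of infeasible scenario {result.scenario!r}"
        )
    tol = result.tolerance if zero_tol is None else zero_tol
    zero, unique, free = [], [], []
    for rid, fr in result.ranges.items():
        if fr.unique and abs(fr.min) <= tol and abs(fr.max) <= tol:
            zero.append(rid)
        elif fr.unique:
            unique.append(rid)
        else:
            free.append(rid)
    return {
        "n_unique": len(unique) + len(zero),
        "n_zero": len(zero),
        "n_free": len(free),
        "unique": sorted(unique),
        "zero": sorted(zero),
        "free": sorted(free),
    }


def write_fva_tsv(result: FvaResult, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# scenario\t{result.scenario}\n# status\t{result.status}\n")
        fh.write("reaction_id\tmin\tmax\tunique\n")
        for rid, fr in result.ranges.items():
            fh.write(f"{rid}\t{fr.min!r}\t{fr.max!r}\t{int(fr.unique)}\n")


def read_fva_tsv(path) -> FvaResult:
    scenario, status = "", "optimal"
    ranges: dict[str, FluxRange] = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    body = []
    for ln in lines:
        if ln.startswith("# scenario\t"):
            scenario = ln.split("\t", 1)[1]
        elif ln.startswith("# status\t"):
            status = ln.split("\t", 1)[1]
        elif ln and not ln.startswith("#"):
            body.append(ln)
    for ln in body[1:]:  # skip header
        rid, lo, hi, uq = ln.split("\t")
        ranges[rid] = FluxRange(rid, float(lo), float(hi), bool(int(uq)))
    return FvaResult(scenario=scenario, status=status, ranges=ranges)
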