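"""Finite-difference flux sensitivities.

The procedure mirrors how the burden on the Calvin cycle is probed:
starting from a scenario in which a key reaction is fixed to zero, the
reaction is raised to a small rate delta (0.1 by default) and the change
of a target flux bound — the FVA minimum of RubisCO, say — divided by
delta gives the locally valid sensitivity.  Because the feasible set is
a polytope, the response is piecewise linear; on a single facet the
quotient is independent of delta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from pnsbflux.core import MetabolicModel
from pnsbflux.fva import solve_fva
from pnsbflux.scenarios import Scenario, apply_override

__all__ = ["SensitivityResult", "flux_sensitivity", "multi_sensitivity"]


@dataclass(frozen=True)
class SensitivityResult:
    scenario: str
    perturbed_reaction: str
    target_reaction: str
    delta: float
    bound: str
    base_value: float | None
    perturbed_value: float | None
    base_unique: bool | None = None
    perturbed_unique: bool | None = None
    feasible: bool = True

    @property
    def sensitivity(self) -> float | None:
        if not self.feasible:
            return None
        return (self.perturbed_value - self.base_value) / self.delta


def _bound_value(fva_range, bound: str) -> float:
    if bound == "min":
        return fva_range.min
    if bound == "max":
        return fva_range.max
    raise ValueError(f"bound must be 'min' or 'max', got {bound!r}")


def multi_sensitivity(
    model: MetabolicModel,
    base_scenario: Scenario,
    perturbed_rxn: str,
    targets: Sequence[str],
    delta: float = 0.1,
    bound: str = "min",
) -> list[SensitivityResult]:
    """Sensitivity of several target bounds to one perturbation.

    A single pair of FVA solves (base and perturbed scenario) is reused
    for all targets.  The perturbed reaction must be fixed to 0 in the
    base scenario; infeasibility after the perturbation is reported, not
    raised.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    fixes = base_scenario.effective_fixes()
    if fixes.get(perturbed_rxn) != 0.0:
        raise ValueError(
            f"{perturbed_rxn} must be fixed to 0 in scenario {base_scenario.name!r}"
        )
    targets = list(targets)
    if not targets:
        return []
    for rid in targets + [perturbed_rxn]:
        model.reaction(rid)

    base = solve_fva(model, base_scenario, reactions=targets)
    pert_scenario = apply_override(base_scenario, perturbed_rxn, delta)
    pert = solve_fva(model, pert_scenario, reactions=targets)

    out = []
    for rid in targets:
        if not base.feasible or not pert.feasible:
            out.append(
                SensitivityResult(
                    scenario=base_scenario.name,
                    perturbed_reaction=perturbed_rxn,
                    target_reaction=rid,
                    delta=delta,
                    bound=bound,
                    base_value=_bound_value(base[rid], bound) if base.feasible else None,
                    perturbed_value=None,
                    feasible=False,
                )
            )
            continue
        b, p = base[rid], pert[rid]
        out.append(
            SensitivityResult(
                scenario=base_scenario.name,
                perturbed_reaction=perturbed_rxn,
                target_reaction=rid,
                delta=delta,
                bound=bound,
                base_value=_bound_value(b, bound),
                perturbed_value=_bound_value(p, bound),
                base_unique=b.unique,
                perturbed_unique=p.unique,
            )
        )
    return out


def flux_sensitivity(
    model: MetabolicModel,
    base_scenario: Scenario,
    perturbed_rxn: str,
    target_rxn: str,
    delta: float = 0.1,
    bound: str = "min",
) -> SensitivityResult:
    """Finite-difference sensitivity of one target flux bound."""
    return multi_sensitivity(
        model, base_scenario, perturbed_rxn, [target_rxn], delta=delta, bound=bound
    )[0]


def write_sensitivity_tsv(results: Iterable[SensitivityResult], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "scenario\tperturbed\ttarget\tbound\tdelta\tbase\tperturbed_value\tsensitivity\n"
        )
        for r in results:
            s = "" if r.sensitivity is None else f"{r.sensitivity:.6g}"
            fh.write(
                f"{r.scenario}\t{r.perturbed_reaction}\t{r.target_reaction}\t"
                f"{r.bound}\t{r.delta}\t{r.base_value}\t{r.perturbed_value}\t{s}\n"
            )
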