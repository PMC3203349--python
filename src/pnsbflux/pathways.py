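"""Net stoichiometries of pathway subsets and hydrogen-yield analysis.

A flux assignment over a reaction subset (e.g. one turn of the
glyoxylate cycle) has an exact net conversion N_sub * v computed in
rational arithmetic.  The optional *carrier folding* re-expresses
electrons deposited on ubiquinone or ferredoxin as NADH — electrons at
the quinone level are shuttled to NAD by pmf-driven reverse electron
flow — with the pmf involvement recorded symbolically.  This is the
bookkeeping under which the three acetate assimilation routes read

    glyoxylate / citramalate:  4 AcCoA + 4 NAD -> 2 Mal + 4 NADH + 4 CoA
    ethylmalonyl-CoA:          3 AcCoA + 2 CO2 + 2 NADPH + 2 NAD
                                 -> 2 Mal + 2 NADH + 2 NADP + 3 CoA

The module also provides the degree-of-reduction oracle for maximal
hydrogen yields and the FVA-based hydrogen yield ranges for engineered
(knockout / deregulated) strains.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping

from pnsbflux.core import (
    FluxRange,
    MetabolicModel,
    degree_of_reduction,
    parse_formula,
)
from pnsbflux.fva import InfeasibleScenario, solve_fva
from pnsbflux.scenarios import FREE, Scenario, apply_override

__all__ = [
    "NetConversion",
    "net_conversion",
    "virtual_transhydrogenase_balance",
    "max_h2_yield_theoretical",
    "h2_yield_range",
    "CANONICAL_ASSIGNMENTS",
]

_F = Fraction

#: Canonical unit-cycle flux assignments: the smallest positive-integer
#: solutions of the subnetwork balance for each pathway's textbook turn.
CANONICAL_ASSIGNMENTS: dict[str, dict[str, Fraction]] = {
    # 3 CO2 fixed, one triose phosphate exported; all six trioses pass
    # the GAP dehydrogenase, five re-enter the regeneration leg.
    "calvin": {
        "RBC": _F(3), "PGK": _F(-6), "GAPDH": _F(-6), "TPI": _F(-2),
        "FBA": _F(-1), "FBPASE": _F(1), "TKT2": _F(-1), "SBA": _F(1),
        "SBPASE": _F(1), "TKT1": _F(-1), "RPI": _F(-1), "RPE": _F(-2),
        "PRK": _F(3),
    },
    # two turns: 4 AcCoA -> 2 malate (one OAA regenerated per turn).
    "glyoxylate": {
        "CS": _F(2), "ACN": _F(2), "ICL": _F(2), "MS": _F(2),
        "SDH": _F(2), "FUM": _F(2), "MDH": _F(2),
    },
    # two turns; pyruvate resynthesized via MDH + PEP carboxykinase +
    # pyruvate kinase (ATP-neutral, matching the cycle's net balance).
    "citramalate": {
        "CMS": _F(2), "CMDH": _F(2), "MCT": _F(2), "MCH": _F(2),
        "MCL": _F(2), "MS": _F(2), "PCC": _F(2), "MCM": _F(2),
        "SCS": _F(2), "SDH": _F(2), "FUM": _F(2), "MDH": _F(2),
        "PCK": _F(2), "PYK": _F(2),
    },
    # one pass: 3 AcCoA + 2 CO2 -> 2 malate.
    "emcoa": {
        "ACAT": _F(1), "AACR": _F(1), "ECH": _F(1), "CCR": _F(1),
        "EMM": _F(1), "MSD": _F(1), "MCH": _F(1), "MCL": _F(1),
        "MS": _F(1), "PCC": _F(1), "MCM": _F(1), "SCS": _F(1),
        "SDH": _F(1), "FUM": _F(1),
    },
    # oxidative PPP + Calvin cycle as a virtual transhydrogenase:
    # 3 G6P worth of CO2 released and refixed, zero net carbon.
    "oxppp_calvin": {
        "G6PDH": _F(3), "PGD": _F(3), "PRK": _F(3), "RBC": _F(3),
        "PGK": _F(-6), "GAPDH": _F(-6), "TPI": _F(-3), "FBA": _F(-3),
        "FBPASE": _F(3), "PGI": _F(-3),
    },
    # Entner-Doudoroff cycle closed by gluconeogenesis.
    "edp_cycle": {
        "G6PDH": _F(1), "EDD": _F(1), "EDA": _F(1), "PPS": _F(1),
        "ENO": _F(-1), "PGK": _F(-1), "GAPDH": _F(-1), "TPI": _F(-1),
        "FBA": _F(-1), "FBPASE": _F(1), "PGI": _F(-1),
    },
}

#: carrier folding: reduced species -> (oxidized partner, NADH-equivalents,
#: pmf charges consumed per folding step via reverse electron flow).
_FOLD_RULES = {
    "QH2": ("Q", _F(1), _F(4)),
    "Fdred": ("Fdox", _F(1), _F(0)),
}


@dataclass(frozen=True)
class NetConversion:
    """An exact net stoichiometry: consumed and produced amount maps.

    After cancellation no metabolite appears on both sides.  ``pmf`` is
    kept apart so folded conversions can print it symbolically, the sign
    recording net consumption (>0) or generation (<0) of charges.
    """

    consumed: Mapping[str, Fraction]
    produced: Mapping[str, Fraction]
    pmf: Fraction = _F(0)
    folded: bool = False

    @staticmethod
    def from_net(net: Mapping[str, Fraction], folded: bool = False) -> "NetConversion":
        pmf = -net.get("pmf", _F(0))
        consumed = {m: -c for m, c in net.items() if c < 0 and m != "pmf"}
        produced = {m: c for m, c in net.items() if c > 0 and m != "pmf"}
        return NetConversion(consumed, produced, pmf=pmf, folded=folded)

    def coefficient(self, metabolite: str) -> Fraction:
        """Signed net coefficient (positive = produced)."""
        return self.produced.get(metabolite, _F(0)) - self.consumed.get(
            metabolite, _F(0)
        )

    def net_carbon(self, model: MetabolicModel) -> Fraction:
        total = _F(0)
        for side, sign in ((self.consumed, -1), (self.produced, 1)):
            for mid, coeff in side.items():
                f = model.metabolite(mid).formula if model.has_metabolite(mid) else None
                if f:
                    total += sign * coeff * f.get("C", 0)
        return total

    def __str__(self):
        def fmt(side):
            return " + ".join(f"{c} {m}" for m, c in sorted(side.items())) or "(nothing)"

        pmf = ""
        if self.pmf > 0:
            pmf = " + <pmf>"
        arrow = f"{fmt(self.consumed)}{pmf} -> {fmt(self.produced)}"
        if self.pmf < 0:
            arrow += " + <pmf>"
        return arrow


def _sum_assignment(
    model: MetabolicModel, assignment: Mapping[str, Fraction]
) -> dict[str, Fraction]:
    net: dict[str, Fraction] = {}
    for rid, flux in assignment.items():
        try:
            rxn = model.reaction(rid)
        except KeyError:
            raise KeyError(
                f"flux assignment references unknown reaction {rid!r}"
            ) from None
        f = Fraction(flux)
        for mid, coeff in rxn.stoich.items():
            net[mid] = net.get(mid, _F(0)) + f * coeff
    return {m: c for m, c in net.items() if c != 0}


def net_conversion(
    model: MetabolicModel,
    assignment: Mapping[str, Fraction],
    fold_carriers: bool = False,
) -> NetConversion:
    """Exact net conversion of a flux assignment over a reaction subset.

    Internal intermediates that are balanced by the assignment cancel
    exactly (rational arithmetic).  With ``fold_carriers=True``,
    quinol/ferredoxin electrons are re-expressed as NADH via reverse
    electron flow and the pmf involvement is kept symbolic.
    """
    net = _sum_assignment(model, assignment)
    if fold_carriers:
        for reduced, (oxidized, equiv, charges) in _FOLD_RULES.items():
            amount = net.get(reduced, _F(0))
            if amount == 0:
                continue
            net[reduced] = _F(0)
            net[oxidized] = net.get(oxidized, _F(0)) + amount
            net["NADH"] = net.get("NADH", _F(0)) + equiv * amount
            net["NAD"] = net.get("NAD", _F(0)) - equiv * amount
            net["pmf"] = net.get("pmf", _F(0)) - charges * amount
        net = {m: c for m, c in net.items() if c != 0}
    return NetConversion.from_net(net, folded=fold_carriers)


def virtual_transhydrogenase_balance(
    model: MetabolicModel, variant: str
) -> NetConversion:
    """Net balance of a cyclic NADH -> NADPH conversion.

    ``variant`` is ``"oxppp_calvin"`` (oxidative PPP + Calvin cycle; zero
    net carbon, CO2 released and refixed) or ``"edp_cycle"``
    (Entner-Doudoroff loop closed by gluconeogenesis; no RubisCO flux).
    Raises when the selected (species sub)model lacks a required enzyme.
    """
    if variant not in ("oxppp_calvin", "edp_cycle"):
        raise ValueError(f"unknown variant {variant!r}")
    assignment = CANONICAL_ASSIGNMENTS[variant]
    missing = [rid for rid in assignment if not model.has_reaction(rid)]
    if missing:
        names = ", ".join(missing)
        raise ValueError(
            f"variant {variant!r} unavailable in model {model.name!r}: "
            f"missing enzyme(s) {names}"
        )
    return net_conversion(model, assignment, fold_carriers=True)


def max_h2_yield_theoretical(substrate_formula) -> Fraction:
    """Maximal H2 yield from the degree of reduction: electrons / 2.

    Succinate (C4H6O4, 14 electrons) gives 7 mol H2 per mol; fructose
    gives 12.  Pseudo-species without a formula are rejected.
    """
    if isinstance(substrate_formula, str):
        substrate_formula = parse_formula(substrate_formula)
    return Fraction(degree_of_reduction(substrate_formula), 2)


def h2_yield_range(
    model: MetabolicModel,
    scenario: Scenario,
    knockouts: Iterable[str] = (),
    deregulations: Iterable[str] = (),
    biomass_zero: bool = False,
    h2_reaction: str = "H2ex",
    biomass_reaction: str = "BIOMASS",
) -> FluxRange:
    """FVA range of hydrogen release per unit substrate uptake.

    ``knockouts`` are fixed to zero (e.g. RubisCO), ``deregulations``
    are freed (e.g. the oxidative TCA key step).  Growth stays free
    (lower bound 0; scenarios that cannot balance without growth exclude
    mu = 0 by themselves) unless ``biomass_zero`` forces the
    complete-oxidation mode.  Infeasibility after a knockout — a
    lethality signal — raises :class:`InfeasibleScenario`.
    """
    sc = apply_override(scenario, h2_reaction, FREE)
    for rid in knockouts:
        sc = apply_override(sc, rid, 0.0)
    for rid in deregulations:
        sc = apply_override(sc, rid, FREE)
    if biomass_zero:
        sc = apply_override(sc, biomass_reaction, 0.0)
    result = solve_fva(model, sc, reactions=[h2_reaction])
    if not result.feasible:
        raise InfeasibleScenario(
            f"scenario {scenario.name!r} with knockouts {sorted(knockouts)} "
            "is infeasible (no balanced flux distribution exists)"
        )
    return result[h2_reaction]
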