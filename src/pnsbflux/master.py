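"""The curated PNSB master network and the biomass reaction builder.

The network covers the catabolic and amphibolic central metabolism of
*Rs. rubrum*, *Rba. sphaeroides* and *Rps. palustris*: glycolysis /
gluconeogenesis, both pentose-phosphate branches, Entner-Doudoroff,
the full TCA cycle with fumarate reductase, the Calvin cycle, the
ferredoxin-dependent reductive-TCA enzymes, anaplerotics, all three
acetate assimilation routes (glyoxylate shunt, citramalate cycle,
ethylmalonyl-CoA pathway), the propionyl-CoA/methylmalonyl-CoA branch,
pyruvate formate-lyase with formate hydrogenlyase, a lumped electron
transport chain coupled through a proton-motive-force pseudo-metabolite,
nitrogenase, uptake hydrogenase, exchanges, and lumped anabolism.

Anabolism is condensed into one lumped synthesis reaction per
macromolecule pool (per-gram precursor demands) plus a biomass
pseudo-reaction combining the pools by mass fraction, so the biomass
flux mu carries units gDW/(gDW*h) and equals the molar yield Y_X/S when
the substrate uptake is normalized to 1 mmol/(gDW*h).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from importlib import resources
from typing import Mapping

from pnsbflux.core import (
    MetabolicModel,
    ModelError,
    Reaction,
    read_model_tsv,
    _read_tsv,
)

__all__ = [
    "ACETATE_ROUTES",
    "BiomassComposition",
    "ReconstructionConfig",
    "build_biomass_reaction",
    "build_master_model",
    "load_default_composition",
]

#: Reactions specific to each acetate assimilation route, plus the
#: mesaconyl-CoA leg shared by the citramalate cycle and the
#: ethylmalonyl-CoA pathway.
ACETATE_ROUTES = {
    "glyoxylate": ("ICL",),
    "citramalate": ("CMS", "CMDH", "MCT"),
    "emcoa": ("ECH", "CCR", "EMM", "MSD"),
}
_SHARED_MESACONYL = ("MCH", "MCL")

#: Carrier completion used by the demand-table reader: consuming the key
#: species co-produces the partner (and vice versa for production).
_CARRIER_PARTNER = {
    "ATP": "ADP",
    "NADPH": "NADP",
    "NADH": "NAD",
    "AcCoA": "CoA",
    "SuccCoA": "CoA",
    "HyBuCoA": "CoA",
}

_POOL_OF = {
    "protein": "Protein",
    "lipid": "Lipid",
    "rna": "RNA",
    "dna": "DNA",
    "phb": "PHB",
    "lps": "LPS",
    "glycogen": "Glycogen",
    "peptidoglycan": "PepG",
    "polyphosphate": "PolyP",
    "bchl": "Bchl",
}


def _data_path(name: str):
    return resources.files("pnsbflux.data").joinpath(name)


@dataclass(frozen=True)
class BiomassComposition:
    """Macromolecular composition plus per-gram precursor demand table.

    ``fractions`` holds g per gDW for each macromolecule (must sum to 1);
    ``demands`` maps macromolecule -> metabolite -> mmol consumed per gram
    of that macromolecule (negative = produced; only NADH and phosphate
    may be negative).
    """

    fractions: Mapping[str, float]
    demands: Mapping[str, Mapping[str, Fraction]]

    def __post_init__(self):
        fr = {k: float(v) for k, v in self.fractions.items()}
        if any(v < 0 for v in fr.values()):
            raise ModelError("biomass mass fractions must be non-negative")
        total = sum(fr.values())
        if abs(total - 1.0) > 1e-9:
            raise ModelError(f"biomass mass fractions sum to {total}, not 1")
        object.__setattr__(self, "fractions", fr)
        dm = {
            mac: {met: Fraction(str(v)) for met, v in table.items()}
            for mac, table in self.demands.items()
        }
        for mac in fr:
            if fr[mac] > 0 and mac not in dm:
                raise ModelError(f"no demand table for macromolecule {mac!r}")
        for mac, table in dm.items():
            for met, v in table.items():
                if v < 0 and met not in ("NADH", "Pi"):
                    raise ModelError(
                        f"{mac}: negative demand for {met} (only NADH/Pi may be produced)"
                    )
        object.__setattr__(self, "demands", dm)

    def without(self, macromolecule: str) -> "BiomassComposition":
        """Drop one macromolecule and renormalize the remaining fractions."""
        fr = {k: v for k, v in self.fractions.items() if k != macromolecule}
        total = sum(fr.values())
        if total <= 0:
            raise ModelError("cannot renormalize an empty composition")
        fr = {k: v / total for k, v in fr.items()}
        return BiomassComposition(fr, self.demands)


def load_default_composition() -> BiomassComposition:
    """Composition shipped with the package: protein 50%, lipid 16%,
    RNA 16%, PHB 5%, DNA 3%, LPS 3%, glycogen 2%, peptidoglycan 2%,
    polyphosphate 2%, bacteriochlorophyll 1%."""
    fractions = {
        row["macromolecule"]: float(row["mass_fraction"])
        for row in _read_tsv(_data_path("biomass_composition.tsv"))
    }
    demands: dict[str, dict[str, Fraction]] = {}
    for row in _read_tsv(_data_path("precursor_demands.tsv")):
        demands.setdefault(row["macromolecule"], {})[row["metabolite"]] = Fraction(
            row["mmol_per_g"]
        )
    return BiomassComposition(fractions, demands)


def _demand_stoich(table: Mapping[str, Fraction]) -> dict[str, Fraction]:
    """Signed stoichiometry of one lumped synthesis reaction (per gram),
    with carrier partners completed (x ATP consumed => x ADP produced)."""
    stoich: dict[str, Fraction] = {}

    def add(met: str, coeff: Fraction):
        stoich[met] = stoich.get(met, Fraction(0)) + coeff

    for met, demand in table.items():
        add(met, -demand)
        partner = _CARRIER_PARTNER.get(met)
        if partner:
            add(partner, demand)
    return {m: c for m, c in stoich.items() if c != 0}


def build_biomass_reaction(
    comp: BiomassComposition, reaction_id: str = "BIOMASS"
) -> Reaction:
    """Fold the composition into a single biomass pseudo-reaction.

    The reaction consumes central precursors, NAD(P)H and ATP in mmol per
    gDW and produces one unit of the external biomass pseudo-metabolite.
    A composition of 100% glycogen, for example, drains only G6P and ATP
    (about 6.17 mmol G6P per gDW, one glucosyl unit per 162 g/mol).
    """
    stoich: dict[str, Fraction] = {}
    for mac, fraction in comp.fractions.items():
        if fraction == 0:
            continue
        f = Fraction(str(fraction))
        for met, coeff in _demand_stoich(comp.demands[mac]).items():
            stoich[met] = stoich.get(met, Fraction(0)) + f * coeff
    stoich = {m: c for m, c in stoich.items() if c != 0}
    stoich["Biomass_ext"] = Fraction(1)
    return Reaction(
        id=reaction_id,
        stoich=stoich,
        reversible=False,
        pathway="biomass",
        is_pseudo=True,
        name="biomass synthesis (folded precursor drains per gDW)",
    )


def _pool_reactions(comp: BiomassComposition) -> list[Reaction]:
    """One lumped building-block synthesis reaction per macromolecule,
    plus the biomass reaction combining the pools by mass fraction."""
    rxns = []
    biomass_stoich: dict[str, Fraction] = {}
    for mac, fraction in comp.fractions.items():
        pool = _POOL_OF[mac]
        if fraction == 0:
            continue
        stoich = _demand_stoich(comp.demands[mac])
        stoich[pool] = Fraction(1)
        rxns.append(
            Reaction(
                id=f"SYN_{mac}",
                stoich=stoich,
                pathway="anabolic",
                is_pseudo=True,
                name=f"lumped {mac} synthesis (1 g)",
            )
        )
        biomass_stoich[pool] = -Fraction(str(fraction))
    biomass_stoich["Biomass_ext"] = Fraction(1)
    rxns.append(
        Reaction(
            id="BIOMASS",
            stoich=biomass_stoich,
            pathway="biomass",
            is_pseudo=True,
            name="biomass synthesis from macromolecule pools",
        )
    )
    return rxns


@dataclass(frozen=True)
class ReconstructionConfig:
    """Options of the master-model builder.

    acetate_routes
        Subset of {"glyoxylate", "citramalate", "emcoa"} to include
        (default: all three; the master model is the union over species).
    pcc_reversible
        Propionyl-CoA carboxylase reversibility.  Reversible by default,
        which permits fermentative ATP gain from succinate via
        methylmalonyl-CoA; switch off to forbid it.
    fold_biomass
        Replace the macromolecule pools with a single folded biomass
        reaction (stoichiometrically equivalent).
    ndh_charges / atps_charges
        Charges translocated per NADH at NADH dehydrogenase and consumed
        per ATP at the ATP synthase.  Under phototrophy ATP supply is
        decoupled from redox, so results of the photoheterotrophic
        scenarios are insensitive to these.
    """

    acetate_routes: frozenset[str] = frozenset(ACETATE_ROUTES)
    pcc_reversible: bool = True
    fold_biomass: bool = False
    default_bound: float = 100.0
    ndh_charges: int = 4
    atps_charges: int = 4
    composition: BiomassComposition | None = None

    def __post_init__(self):
        unknown = set(self.acetate_routes) - set(ACETATE_ROUTES)
        if unknown:
            raise ModelError(f"unknown acetate routes {sorted(unknown)}")


def build_master_model(config: ReconstructionConfig | None = None) -> MetabolicModel:
    """Assemble the PNSB master model from the shipped reaction tables."""
    config = config or ReconstructionConfig()
    model = read_model_tsv(
        _data_path("reactions.tsv"),
        _data_path("metabolites.tsv"),
        default_bound=config.default_bound,
        name="pnsb_master",
    )
    drop: set[str] = set()
    for route, rids in ACETATE_ROUTES.items():
        if route not in config.acetate_routes:
            drop.update(rids)
    if not ({"citramalate", "emcoa"} & config.acetate_routes):
        drop.update(_SHARED_MESACONYL)

    reactions: list[Reaction] = []
    for rxn in model.reactions:
        if rxn.id in drop:
            continue
        if rxn.id == "PCC" and not config.pcc_reversible:
            rxn = replace(rxn, reversible=False)
        if rxn.id == "NDH" and config.ndh_charges != 4:
            st = dict(rxn.stoich)
            st["pmf"] = Fraction(config.ndh_charges)
            rxn = replace(rxn, stoich=st)
        if rxn.id == "ATPS" and config.atps_charges != 4:
            st = dict(rxn.stoich)
            st["pmf"] = -Fraction(config.atps_charges)
            rxn = replace(rxn, stoich=st)
        reactions.append(rxn)

    comp = config.composition or load_default_composition()
    if config.fold_biomass:
        reactions.append(build_biomass_reaction(comp))
    else:
        reactions.extend(_pool_reactions(comp))

    used = {mid for r in reactions for mid in r.stoich}
    metabolites = [m for m in model.metabolites if m.id in used]
    return MetabolicModel(
        metabolites, reactions, default_bound=config.default_bound, name="pnsb_master"
    )
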