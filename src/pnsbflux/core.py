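"""Domain types and stoichiometric-matrix machinery.

Coefficients are stored as exact :class:`fractions.Fraction` so that net
stoichiometries of pathway subsets can be computed without floating-point
noise; only the LP solves (:mod:`pnsbflux.fva`) work in floating point.

Protons, water and charge are not balanced.  Electron bookkeeping is done
through the explicit carrier pools (NADH, NADPH, reduced ferredoxin,
ubiquinol, proton-motive force) and through the degree-of-reduction
auditor below, which is insensitive to omitted H2O (its reduction degree
is zero).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SPECIES_TAGS",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FluxRange",
    "build_stoich_matrix",
    "species_submodel",
    "degree_of_reduction",
    "parse_formula",
    "format_formula",
    "parse_equation",
    "format_equation",
    "element_imbalances",
    "reduction_imbalance",
    "write_model_tsv",
    "read_model_tsv",
]

#: Valid organism tags of the master model: Rhodospirillum rubrum (rru),
#: Rhodobacter sphaeroides (rsp), Rhodopseudomonas palustris (rpa).
SPECIES_TAGS = ("rru", "rsp", "rpa")

ELEMENTS = ("C", "H", "O", "N", "P", "S")

#: Electrons liberated per atom on complete oxidation to the reference
#: compounds CO2, H2O, NH3, H3PO4 and H2S.
REDUCTION_WEIGHTS = {"C": 4, "H": 1, "O": -2, "N": -3, "P": 5, "S": -2}


class ModelError(ValueError):
    """Structural problem in a model definition."""


# ---------------------------------------------------------------------------
# formulas


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse an elemental formula such as ``C4H6O4`` into a count map."""
    text = text.strip()
    if not text:
        raise ValueError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(text):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r}")
        pos = m.end()
        el, n = m.group(1), int(m.group(2) or 1)
        if el not in ELEMENTS:
            raise ValueError(f"unsupported element {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + n
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r}")
    if not counts or all(v == 0 for v in counts.values()):
        raise ValueError(f"formula {text!r} has no atoms")
    if any(v < 0 for v in counts.values()):
        raise ValueError(f"negative atom count in {text!r}")
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    return "".join(
        f"{el}{counts[el] if counts[el] != 1 else ''}"
        for el in ELEMENTS
        if counts.get(el)
    )


def degree_of_reduction(formula: Mapping[str, int] | str | None) -> int:
    """Electrons available per mole on complete oxidation.

    Computed as ``4*C + H - 2*O - 3*N + 5*P - 2*S`` relative to the
    reference state CO2/H2O/NH3/H3PO4/H2S.  Succinate (C4H6O4) gives 14,
    which bounds the hydrogen yield at 7 mol H2 per mol; the reference
    CO2 gives 0.
    """
    if formula is None:
        raise ValueError(
            "metabolite has no elemental formula; pseudo-species (biomass, "
            "pmf, photon, ...) have no degree of reduction"
        )
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return sum(REDUCTION_WEIGHTS[el] * n for el, n in formula.items())


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Metabolite:
    """A chemical species.

    External species (``external=True``) live on the exchange boundary and
    are not balanced, i.e. they contribute no row to the stoichiometric
    matrix.  ``formula`` may be absent for lumped pseudo-species such as
    biomass, pmf or photons.
    """

    id: str
    name: str = ""
    external: bool = False
    formula: Mapping[str, int] | None = None

    def __post_init__(self):
        if not self.id:
            raise ModelError("metabolite id must be non-empty")
        if self.formula is not None:
            f = dict(self.formula)
            if not f or all(v == 0 for v in f.values()):
                raise ModelError(f"metabolite {self.id}: empty formula")
            if any(v < 0 for v in f.values()):
                raise ModelError(f"metabolite {self.id}: negative atom count")
            object.__setattr__(self, "formula", f)


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric map over metabolites.

    ``stoich`` maps metabolite id to a signed rational coefficient
    (negative = consumed).  ``species`` is the subset of organisms that
    possess the reaction.  Exchange reactions connect exactly one internal
    metabolite to the boundary; pseudo-reactions (biomass, ATP drain,
    photon capture, lumped anabolism) are exempt from elemental auditing.
    """

    id: str
    stoich: Mapping[str, Fraction]
    reversible: bool = False
    species: frozenset[str] = frozenset(SPECIES_TAGS)
    pathway: str = ""
    is_exchange: bool = False
    is_pseudo: bool = False
    name: str = ""

    def __post_init__(self):
        if not self.id:
            raise ModelError("reaction id must be non-empty")
        st = {m: Fraction(c) for m, c in self.stoich.items() if Fraction(c) != 0}
        if not st:
            raise ModelError(f"reaction {self.id}: empty stoichiometry")
        object.__setattr__(self, "stoich", st)
        sp = frozenset(self.species)
        if not sp:
            raise ModelError(f"reaction {self.id}: empty species set")
        unknown = sp - set(SPECIES_TAGS)
        if unknown:
            raise ModelError(f"reaction {self.id}: unknown species tags {sorted(unknown)}")
        object.__setattr__(self, "species", sp)

    def reactants(self) -> dict[str, Fraction]:
        return {m: -c for m, c in self.stoich.items() if c < 0}

    def products(self) -> dict[str, Fraction]:
        return {m: c for m, c in self.stoich.items() if c > 0}


@dataclass(frozen=True)
class FluxRange:
    """Feasible [min, max] interval of one reaction rate.

    Units are mmol/(gDW*h); the biomass reaction carries gDW/(gDW*h).
    ``unique`` flags coincident bounds (the rate is calculable).
    """

    reaction_id: str
    min: float
    max: float
    unique: bool

    def __post_init__(self):
        if self.min > self.max + 1e-6:
            raise ValueError(
                f"{self.reaction_id}: min {self.min} exceeds max {self.max}"
            )

    @property
    def width(self) -> float:
        return self.max - self.min


class MetabolicModel:
    """An assembled network: ordered metabolites and reactions.

    The stoichiometric matrix N has one row per *internal* metabolite and
    one column per reaction.  ``default_bound`` is the generic flux cap
    (100 mmol/(gDW*h)): irreversible reactions are bounded to
    [0, default_bound], reversible ones to [-default_bound, default_bound].
    """

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        default_bound: float = 100.0,
        name: str = "",
    ):
        if default_bound <= 0:
            raise ModelError("default_bound must be positive")
        self.metabolites: list[Metabolite] = list(metabolites)
        self.reactions: list[Reaction] = list(reactions)
        self.default_bound = float(default_bound)
        self.name = name
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        if len(self._met_index) != len(self.metabolites):
            raise ModelError("duplicate metabolite ids")
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if len(self._rxn_index) != len(self.reactions):
            raise ModelError("duplicate reaction ids")
        for r in self.reactions:
            for mid in r.stoich:
                if mid not in self._met_index:
                    raise ModelError(
                        f"reaction {r.id} references unknown metabolite {mid!r}"
                    )
            if r.is_exchange:
                internal = [
                    m for m in r.stoich if not self.metabolite(m).external
                ]
                if len(internal) != 1:
                    raise ModelError(
                        f"exchange reaction {r.id} must touch exactly one "
                        f"internal metabolite, touches {sorted(internal)}"
                    )

    # -- lookup -------------------------------------------------------

    def metabolite(self, mid: str) -> Metabolite:
        return self.metabolites[self._met_index[mid]]

    def reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rid]]
        except KeyError:
            raise KeyError(f"no reaction {rid!r} in model {self.name!r}") from None

    def has_reaction(self, rid: str) -> bool:
        return rid in self._rxn_index

    def has_metabolite(self, mid: str) -> bool:
        return mid in self._met_index

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def internal_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if not m.external]

    def bounds(self, reaction: Reaction) -> tuple[float, float]:
        b = self.default_bound
        return (-b if reaction.reversible else 0.0, b)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.internal_metabolites()), len(self.reactions))

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            self.metabolites, self.reactions, self.default_bound, self.name
        )

    def __repr__(self):
        m, q = self.shape
        return f"<MetabolicModel {self.name!r}: {q} reactions, {m} internal metabolites>"


# ---------------------------------------------------------------------------
# operations


def build_stoich_matrix(model: MetabolicModel) -> list[list[Fraction]]:
    """The m x q matrix N of Fractions over internal metabolites.

    Row order follows the model's internal-metabolite order, column order
    the reaction order.  External metabolites are omitted (they are not
    balanced).  An empty model yields a 0 x 0 matrix.
    """
    internal = model.internal_metabolites()
    row_of = {m.id: i for i, m in enumerate(internal)}
    N = [[Fraction(0)] * len(model.reactions) for _ in internal]
    for j, rxn in enumerate(model.reactions):
        for mid, coeff in rxn.stoich.items():
            if mid not in row_of:
                if mid not in model._met_index:
                    raise ModelError(
                        f"reaction {rxn.id} references unknown metabolite {mid!r}"
                    )
                continue  # external
            N[row_of[mid]][j] = coeff
    return N


def stoich_matrix_float(model: MetabolicModel):
    """N as a float numpy array (LP input)."""
    import numpy as np

    N = build_stoich_matrix(model)
    m, q = model.shape
    A = np.zeros((m, q))
    for i in range(m):
        for j in range(q):
            if N[i][j]:
                A[i, j] = float(N[i][j])
    return A


def species_submodel(model: MetabolicModel, species: str) -> MetabolicModel:
    """Restrict the master model to one organism.

    Keeps exactly the reactions whose species set contains ``species``;
    metabolites orphaned by the filter are dropped.  The master model is
    left untouched.
    """
    if species not in SPECIES_TAGS:
        raise ValueError(
            f"unknown species tag {species!r}; expected one of {SPECIES_TAGS}"
        )
    reactions = [r for r in model.reactions if species in r.species]
    used = {mid for r in reactions for mid in r.stoich}
    metabolites = [m for m in model.metabolites if m.id in used]
    return MetabolicModel(
        metabolites, reactions, model.default_bound, f"{model.name}[{species}]"
    )


def element_imbalances(
    model: MetabolicModel, elements: Sequence[str] = ("C", "N", "P", "S")
) -> dict[str, dict[str, Fraction]]:
    """Per-reaction elemental imbalances (products minus substrates).

    Pseudo-reactions and reactions touching a formula-less metabolite are
    skipped — they cannot be audited.  For a mass-consistent model every
    reported imbalance is exactly zero.
    """
    out: dict[str, dict[str, Fraction]] = {}
    for rxn in model.reactions:
        if rxn.is_pseudo or rxn.is_exchange:
            continue
        formulas = {}
        auditable = True
        for mid in rxn.stoich:
            f = model.metabolite(mid).formula
            if f is None:
                auditable = False
                break
            formulas[mid] = f
        if not auditable:
            continue
        bal = {}
        for el in elements:
            total = sum(
                coeff * formulas[mid].get(el, 0) for mid, coeff in rxn.stoich.items()
            )
            bal[el] = Fraction(total)
        out[rxn.id] = bal
    return out


def reduction_imbalance(model: MetabolicModel, rxn: Reaction) -> Fraction | None:
    """Degree-of-reduction imbalance of a reaction (products - substrates).

    Returns None when the reaction involves a formula-less species.  Zero
    for every correctly written redox reaction: the electron carriers are
    given bookkeeping formulas in which the reduced form carries two more
    hydrogens than the oxidized form, so NAD(P)H, quinol and reduced
    ferredoxin each count as a two-electron package, and omitted H2O/H+
    never matter (their reduction degree is zero or absorbed).
    """
    total = Fraction(0)
    for mid, coeff in rxn.stoich.items():
        f = model.metabolite(mid).formula
        if f is None:
            return None
        total += coeff * degree_of_reduction(f)
    return total


# ---------------------------------------------------------------------------
# TSV dialect


def _coeff_str(c: Fraction) -> str:
    return str(c)  # Fraction prints as "3" or "1/2"


def _parse_coeff(tok: str) -> Fraction:
    return Fraction(tok)


def format_equation(rxn: Reaction) -> str:
    """Render ``1 A + 2 B = 1 C`` (substrates = products)."""
    def side(items: Mapping[str, Fraction]) -> str:
        return " + ".join(
            f"{_coeff_str(c)} {m}" for m, c in sorted(items.items())
        )

    return f"{side(rxn.reactants())} = {side(rxn.products())}"


def parse_equation(text: str) -> dict[str, Fraction]:
    """Parse the TSV equation dialect into a signed stoichiometry map."""
    if "=" not in text:
        raise ValueError(f"equation {text!r} lacks '='")
    lhs, rhs = text.split("=", 1)
    stoich: dict[str, Fraction] = {}

    def add(side: str, sign: int):
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 1:
                coeff, mid = Fraction(1), parts[0]
            elif len(parts) == 2:
                coeff, mid = _parse_coeff(parts[0]), parts[1]
            else:
                raise ValueError(f"cannot parse term {term!r} in {text!r}")
            stoich[mid] = stoich.get(mid, Fraction(0)) + sign * coeff

    add(lhs, -1)
    add(rhs, +1)
    return stoich


def write_model_tsv(model: MetabolicModel, reactions_path, metabolites_path) -> None:
    """Write the model in the two-file TSV dialect (UTF-8, tab-separated)."""
    with open(metabolites_path, "w", encoding="utf-8") as fh:
        fh.write("id\tname\texternal\tformula\n")
        for m in model.metabolites:
            formula = format_formula(m.formula) if m.formula else ""
            fh.write(f"{m.id}\t{m.name}\t{int(m.external)}\t{formula}\n")
    with open(reactions_path, "w", encoding="utf-8") as fh:
        fh.write("id\tequation\treversible\tspecies\tpathway\tflags\tname\n")
        for r in model.reactions:
            flags = ",".join(
                k for k, v in (("exchange", r.is_exchange), ("pseudo", r.is_pseudo)) if v
            )
            fh.write(
                f"{r.id}\t{format_equation(r)}\t{int(r.reversible)}\t"
                f"{','.join(sorted(r.species))}\t{r.pathway}\t{flags}\t{r.name}\n"
            )


def _read_tsv(path) -> list[dict[str, str]]:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    rows = []
    for ln in lines[1:]:
        vals = ln.split("\t")
        vals += [""] * (len(header) - len(vals))
        rows.append(dict(zip(header, vals)))
    return rows


def read_model_tsv(
    reactions_path, metabolites_path, default_bound: float = 100.0, name: str = ""
) -> MetabolicModel:
    """Read a model from the TSV dialect; inverse of :func:`write_model_tsv`."""
    mets = []
    for row in _read_tsv(metabolites_path):
        mets.append(
            Metabolite(
                id=row["id"],
                name=row.get("name", ""),
                external=bool(int(row.get("external", "0") or 0)),
                formula=parse_formula(row["formula"]) if row.get("formula") else None,
            )
        )
    rxns = []
    for row in _read_tsv(reactions_path):
        flags = {f.strip() for f in row.get("flags", "").split(",") if f.strip()}
        species = [s.strip() for s in row.get("species", "").split(",") if s.strip()]
        rxns.append(
            Reaction(
                id=row["id"],
                stoich=parse_equation(row["equation"]),
                reversible=bool(int(row.get("reversible", "0") or 0)),
                species=frozenset(species) if species else frozenset(SPECIES_TAGS),
                pathway=row.get("pathway", ""),
                is_exchange="exchange" in flags,
                is_pseudo="pseudo" in flags,
                name=row.get("name", ""),
            )
        )
    return MetabolicModel(mets, rxns, default_bound=default_bound, name=name)
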