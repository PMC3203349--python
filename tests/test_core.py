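"""Domain types, stoichiometric matrix, elemental/electron auditing, TSV I/O."""

from fractions import Fraction

import pytest

from pnsbflux.core import (
    Metabolite,
    MetabolicModel,
    ModelError,
    Reaction,
    build_stoich_matrix,
    degree_of_reduction,
    element_imbalances,
    format_equation,
    parse_equation,
    parse_formula,
    read_model_tsv,
    reduction_imbalance,
    species_submodel,
    write_model_tsv,
)

F = Fraction


def toy_chain_model():
    mets = [
        Metabolite("A_ext", external=True),
        Metabolite("A"),
        Metabolite("B"),
        Metabolite("B_ext", external=True),
    ]
    rxns = [
        Reaction("up", {"A_ext": F(-1), "A": F(1)}, is_exchange=True),
        Reaction("v1", {"A": F(-1), "B": F(1)}),
        Reaction("ex", {"B": F(-1), "B_ext": F(1)}, is_exchange=True),
    ]
    return MetabolicModel(mets, rxns, name="toy")


class TestStoichMatrix:
    def test_linear_chain(self):
        N = build_stoich_matrix(toy_chain_model())
        assert N == [[F(1), F(-1), F(0)], [F(0), F(1), F(-1)]]

    def test_empty_model(self):
        assert build_stoich_matrix(MetabolicModel([], [], name="empty")) == []

    def test_unknown_metabolite_named_in_error(self):
        mets = [Metabolite("A")]
        with pytest.raises(ModelError, match="v1.*ghost"):
            MetabolicModel(mets, [Reaction("v1", {"A": F(-1), "ghost": F(1)})])

    def test_external_metabolites_have_no_row(self, master):
        N = build_stoich_matrix(master)
        m, q = master.shape
        assert (len(N), len(N[0])) == (m, q)
        assert all(not met.external for met in master.internal_metabolites())


class TestInvariants:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ModelError):
            MetabolicModel([Metabolite("A"), Metabolite("A")], [])

    def test_exchange_touching_two_internals_rejected(self):
        mets = [Metabolite("A"), Metabolite("B")]
        with pytest.raises(ModelError, match="exactly one"):
            MetabolicModel(
                mets, [Reaction("x", {"A": F(-1), "B": F(1)}, is_exchange=True)]
            )

    def test_zero_coefficients_dropped_and_empty_rejected(self):
        r = Reaction("r", {"A": F(1), "B": F(0)})
        assert "B" not in r.stoich
        with pytest.raises(ModelError):
            Reaction("r", {"B": F(0)})

    def test_empty_species_set_rejected(self):
        with pytest.raises(ModelError):
            Reaction("r", {"A": F(1)}, species=frozenset())


class TestSpeciesSubmodel:
    def test_rru_lacks_g6p_dehydrogenase_branches(self, master):
        sub = species_submodel(master, "rru")
        for rid in ("G6PDH", "PGD", "EDD", "EDA", "ICL"):
            assert not sub.has_reaction(rid)
        for rid in ("AKGS", "PYS", "CMS", "ECH"):
            assert sub.has_reaction(rid)

    def test_rpa_has_glyoxylate_but_not_edp_or_reductive_tca(self, master):
        sub = species_submodel(master, "rpa")
        assert sub.has_reaction("ICL")
        assert sub.has_reaction("PGD")
        for rid in ("EDD", "EDA", "AKGS", "PYS", "CMS", "ECH"):
            assert not sub.has_reaction(rid)

    def test_all_species_tagged_model_is_identity(self):
        model = toy_chain_model()
        sub = species_submodel(model, "rsp")
        assert sub.reaction_ids() == model.reaction_ids()
        assert [m.id for m in sub.metabolites] == [m.id for m in model.metabolites]

    def test_unknown_tag_rejected(self, master):
        with pytest.raises(ValueError, match="unknown species"):
            species_submodel(master, "eco")

    def test_each_species_misses_exactly_two_unique_reactions(self, master):
        # every organism possesses two reactions absent from both others
        only = {tag: [] for tag in ("rru", "rsp", "rpa")}
        for rxn in master.reactions:
            if len(rxn.species) == 1:
                only[next(iter(rxn.species))].append(rxn.id)
        assert sorted(only["rru"]) == ["AKGS", "PYS"]
        assert sorted(only["rsp"]) == ["EDA", "EDD"]
        assert sorted(only["rpa"]) == ["ICL", "PGD"]


class TestDegreeOfReduction:
    @pytest.mark.parametrize(
        "formula,expected",
        [
            ("C4H6O4", 14),   # succinate: 14 electrons -> 7 H2
            ("CO2", 0),       # reference state
            ("C6H12O6", 24),  # fructose
            ("C4H6O5", 12),   # malate
            ("C3H6O2", 14),   # propionate
            ("C2H4O2", 8),    # acetate
            ("H2", 2),
            ("CH2O2", 2),     # formate
            ("NH3", 0),       # nitrogen reference
            ("H2SO4", -8),    # sulfate: 8 electrons to assimilate
        ],
    )
    def test_known_values(self, formula, expected):
        assert degree_of_reduction(parse_formula(formula)) == expected

    def test_missing_formula_mentions_pseudo_species(self):
        with pytest.raises(ValueError, match="pseudo-species"):
            degree_of_reduction(None)

    def test_string_input_accepted(self):
        assert degree_of_reduction("C4H6O4") == 14


class TestMasterAudits:
    def test_carbon_nitrogen_phosphorus_sulfur_balance(self, master):
        """Every auditable (formula-complete, non-pseudo) reaction is
        exactly element-balanced."""
        imbalances = element_imbalances(master)
        assert len(imbalances) > 60  # the audit actually covers the core
        offenders = {
            rid: bal
            for rid, bal in imbalances.items()
            if any(v != 0 for v in bal.values())
        }
        assert offenders == {}

    def test_degree_of_reduction_additivity(self, master):
        """Electron conservation holds reaction-wise: with carriers counted
        as 2-electron packages the reduction degree of substrates equals
        that of products for every formula-complete reaction."""
        checked = 0
        for rxn in master.reactions:
            if rxn.is_pseudo or rxn.is_exchange:
                continue
            d = reduction_imbalance(master, rxn)
            if d is not None:
                assert d == 0, f"{rxn.id}: electron imbalance {d}"
                checked += 1
        assert checked > 60


class TestTsvDialect:
    def test_equation_round_trip(self):
        eq = "1 SuccCoA + 1 CO2 + 1 Fdred = 1 aKG + 1 CoA + 1 Fdox"
        st = parse_equation(eq)
        assert st["SuccCoA"] == F(-1) and st["aKG"] == F(1)
        r = Reaction("AKGS", st)
        assert parse_equation(format_equation(r)) == st

    def test_fractional_coefficients(self):
        st = parse_equation("1 QH2 + 1/2 O2 = 1 Q")
        assert st["O2"] == F(-1, 2)  # consumed

    def test_model_round_trip_bit_identical(self, master, tmp_path):
        r1, m1 = tmp_path / "r1.tsv", tmp_path / "m1.tsv"
        write_model_tsv(master, r1, m1)
        model2 = read_model_tsv(r1, m1, name=master.name)
        r2, m2 = tmp_path / "r2.tsv", tmp_path / "m2.tsv"
        write_model_tsv(model2, r2, m2)
        assert r1.read_bytes() == r2.read_bytes()
        assert m1.read_bytes() == m2.read_bytes()
        assert build_stoich_matrix(model2) == build_stoich_matrix(master)
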