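"""FVA engine: oracle equivalence, uniqueness classification, invariants."""

import pytest

from pnsbflux.fva import (
    FvaError,
    InfeasibleScenario,
    classify_fluxes,
    max_yield,
    read_fva_tsv,
    solve_fva,
    write_fva_tsv,
)
from pnsbflux.scenarios import Scenario, apply_override, make_scenario
from pnsbflux.synth import ToySpec, brute_force_fva, make_toy


class TestToyNetworks:
    def test_linear_chain_all_unique(self):
        model, sc, _ = make_toy(ToySpec("chain", size=3))
        res = solve_fva(model, sc)
        for rid in model.reaction_ids():
            fr = res[rid]
            assert fr.unique and fr.min == pytest.approx(1.0, abs=1e-8)
        cls = classify_fluxes(res)
        assert (cls["n_unique"], cls["n_zero"], cls["n_free"]) == (3, 0, 0)

    def test_diamond_branches_free(self):
        model, sc, _ = make_toy(ToySpec("diamond"))
        res = solve_fva(model, sc)
        for rid in ("b1", "b2"):
            fr = res[rid]
            assert not fr.unique
            assert (fr.min, fr.max) == (pytest.approx(0.0, abs=1e-8),
                                        pytest.approx(1.0, abs=1e-8))
        cls = classify_fluxes(res)
        assert set(cls["free"]) == {"b1", "b2"}

    def test_chain_terminal_excretion_equals_uptake(self):
        model, sc, _ = make_toy(ToySpec("chain", size=4))
        assert max_yield(model, sc, "ex") == pytest.approx(1.0, abs=1e-8)

    def test_infeasible_scenario_reports_status_not_partial_output(self):
        model, sc, _ = make_toy(ToySpec("chain", size=3))
        bad = apply_override(sc, "ex", 2.0)  # conflicts with uptake 1
        res = solve_fva(model, bad)
        assert not res.feasible and res.ranges == {}
        with pytest.raises(InfeasibleScenario):
            res["up"]
        with pytest.raises(InfeasibleScenario):
            classify_fluxes(res)

    def test_unknown_reaction_in_scenario_rejected(self):
        model, sc, _ = make_toy(ToySpec("chain", size=3))
        with pytest.raises(FvaError, match="unknown reactions"):
            solve_fva(model, apply_override(sc, "ghost", 0.0))


class TestOracleEquivalence:
    @pytest.mark.parametrize("topology,kwargs", [
        ("chain", {"size": 3}),
        ("diamond", {}),
        ("redox_toy", {}),
        ("redox_toy", {"h2_valve_open": True}),
    ])
    def test_lp_matches_vertex_enumeration(self, topology, kwargs):
        model, sc, expected = make_toy(ToySpec(topology, **kwargs))
        lp = solve_fva(model, sc)
        bf = brute_force_fva(model, sc)
        for rid in model.reaction_ids():
            lo, hi = bf[rid]
            assert lp[rid].min == pytest.approx(float(lo), abs=1e-7)
            assert lp[rid].max == pytest.approx(float(hi), abs=1e-7)
            elo, ehi = expected[rid]
            assert float(lo) == pytest.approx(elo, abs=1e-9)
            assert float(hi) == pytest.approx(ehi, abs=1e-9)

    @pytest.mark.parametrize("seed", range(50))
    def test_random_dag_property(self, seed):
        """Across 50 random acyclic networks the LP engine agrees with
        exact vertex enumeration on every reaction range."""
        model, sc, expected = make_toy(ToySpec("random_dag", size=5, seed=seed))
        lp = solve_fva(model, sc)
        for rid, (lo, hi) in expected.items():
            assert lp[rid].min == pytest.approx(lo, abs=1e-7)
            assert lp[rid].max == pytest.approx(hi, abs=1e-7)


class TestMasterInvariants:
    def test_monotone_narrowing_s2_within_s1(self, master):
        """Adding fixed-flux constraints never widens a range."""
        s1 = solve_fva(master, make_scenario("S1", "succinate"))
        s2 = solve_fva(master, make_scenario("S2", "succinate"))
        for rid in master.reaction_ids():
            assert s2[rid].min >= s1[rid].min - 1e-6
            assert s2[rid].max <= s1[rid].max + 1e-6

    def test_yield_scale_invariance(self, master):
        """Doubling the uptake doubles the flux bounds; yield ratios are
        unchanged."""
        s1 = make_scenario("S1", "succinate")
        s2x = make_scenario("S1", "succinate", substrate_rate=2.0)
        a = solve_fva(master, s1, reactions=["BIOMASS", "CO2ex", "RBC"])
        b = solve_fva(master, s2x, reactions=["BIOMASS", "CO2ex", "RBC"])
        for rid in ("BIOMASS", "CO2ex"):
            assert b[rid].min == pytest.approx(2 * a[rid].min, abs=1e-6)
            assert b[rid].max == pytest.approx(2 * a[rid].max, abs=1e-6)
        # maxima limited by the global flux cap do not scale; the
        # cap-free minimum of RubisCO does
        assert b["RBC"].min == pytest.approx(2 * a["RBC"].min, abs=1e-6)
        # yield ratio unchanged
        assert b["BIOMASS"].max / 2 == pytest.approx(a["BIOMASS"].max, abs=1e-9)

    def test_fixing_inside_range_keeps_feasibility(self, master):
        sc = make_scenario("S2", "succinate")
        res = solve_fva(master, sc, reactions=["GAPDH"])
        fr = res["GAPDH"]
        mid = 0.5 * (fr.min + fr.max)
        pinned = apply_override(sc, "GAPDH", mid)
        assert solve_fva(master, pinned, reactions=["BIOMASS"]).feasible

    def test_classification_partitions_reactions(self, master):
        res = solve_fva(master, make_scenario("S2", "succinate"))
        cls = classify_fluxes(res)
        ids = sorted(cls["unique"] + cls["zero"] + cls["free"])
        assert ids == sorted(master.reaction_ids())
        # the redox coupling pins a large unique core, with trivially
        # zero fluxes downstream of the closed pathways
        assert cls["n_unique"] > 60 and cls["n_zero"] >= 15 and cls["n_free"] > 0

    def test_results_independent_of_reaction_subset_order(self, master):
        sc = make_scenario("S2", "succinate")
        fwd = solve_fva(master, sc, reactions=["RBC", "BIOMASS"])
        rev = solve_fva(master, sc, reactions=["BIOMASS", "RBC"])
        assert fwd["RBC"].min == rev["RBC"].min
        assert fwd["BIOMASS"].max == rev["BIOMASS"].max


class TestCobraCrossCheck:
    def test_master_fva_matches_cobrapy(self, master):
        """Independent implementation check: the same LPs solved through
        cobrapy (GLPK) give the same ranges on a spot-check panel."""
        cobra = pytest.importorskip("cobra")
        from cobra.flux_analysis import flux_variability_analysis

        cm = cobra.Model("master")
        mets = {
            m.id: cobra.Metabolite(m.id)
            for m in master.internal_metabolites()
        }
        sc = make_scenario("S2", "succinate")
        fixes = sc.effective_fixes()
        rxns = []
        for rxn in master.reactions:
            cr = cobra.Reaction(rxn.id)
            cr.add_metabolites(
                {mets[mid]: float(c) for mid, c in rxn.stoich.items()
                 if mid in mets}
            )
            if rxn.id in fixes:
                cr.bounds = (fixes[rxn.id], fixes[rxn.id])
            else:
                cr.bounds = master.bounds(rxn)
            rxns.append(cr)
        cm.add_reactions(rxns)
        panel = ["BIOMASS", "CO2ex", "RBC", "SDH", "MDH", "THD", "GAPDH"]
        df = flux_variability_analysis(
            cm, reaction_list=panel, fraction_of_optimum=0
        )
        ours = solve_fva(master, sc, reactions=panel)
        for rid in panel:
            assert ours[rid].min == pytest.approx(df.loc[rid, "minimum"], abs=1e-5)
            assert ours[rid].max == pytest.approx(df.loc[rid, "maximum"], abs=1e-5)


class TestRoundTrip:
    def test_fva_tsv_round_trip(self, master, tmp_path):
        res = solve_fva(master, make_scenario("S2", "succinate"),
                        reactions=["BIOMASS", "RBC", "SDH"])
        path = tmp_path / "fva.tsv"
        write_fva_tsv(res, path)
        back = read_fva_tsv(path)
        assert back.scenario == res.scenario
        for rid in ("BIOMASS", "RBC", "SDH"):
            assert back.ranges[rid].min == res[rid].min
            assert back.ranges[rid].max == res[rid].max
            assert back.ranges[rid].unique == res[rid].unique
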