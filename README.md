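# pnsbflux

Stoichiometric modeling of redox balancing and biohydrogen production in
purple nonsulfur bacteria (PNSB).

PNSB such as *Rhodospirillum rubrum*, *Rhodobacter sphaeroides* and
*Rhodopseudomonas palustris* grow photoheterotrophically: an organic
acid or sugar supplies both carbon and electrons, while cyclic
photophosphorylation supplies ATP without consuming or producing
electrons.  With no external electron acceptor, the cell must balance
reducing equivalents entirely against carbon metabolism — which is why
these organisms run a CO2-fixing Calvin cycle even on substrates from
which they release CO2, and why an engineered cell can be pushed to
dump its excess electrons as H2 instead.  `pnsbflux` packages a curated
stoichiometric "master" model of the shared central metabolism of the
three species together with the analyses that make these effects
quantitative.

## The method

At steady state the flux vector r satisfies `N·r = 0` for the m×q
stoichiometric matrix N over the balanced metabolites, with box bounds
(cap 100 mmol/(gDW·h); irreversible reactions non-negative) and
scenario-fixed rates r_mi = v_mi.  **Flux variability analysis** (FVA)
computes, for each reaction,

    r_i,min = min r_i   and   r_i,max = max r_i
              s.t. N·r = 0, fixed rates, bounds,

without assuming growth optimality.  Coincident bounds mean the rate is
uniquely determined by stoichiometry and environment alone; with the
substrate uptake normalized to 1 mmol/(gDW·h), the upper bound of the
biomass flux is the optimal molar yield Y_X/S (gDW/mmol).  On top of
FVA the package provides finite-difference flux sensitivities,
exact-rational net stoichiometries of pathway subsets (with quinone/
ferredoxin electrons foldable into NADH via reverse electron flow), and
degree-of-reduction electron accounting (γ = 4C + H − 2O − 3N + 5P − 2S;
maximal H2 yield = γ/2).

## Worked example

```python
from pnsbflux import (build_master_model, make_scenario, solve_fva,
                      classify_fluxes, flux_sensitivity)

model = build_master_model()                 # 102 reactions, 76 metabolites
s1 = make_scenario("S1", "succinate")        # photoheterotrophic, uptake = 1
res = solve_fva(model, s1)
bm, co2, rbc = res["BIOMASS"], res["CO2ex"], res["RBC"]
print(f"biomass yield  Y_X/S = {bm.max:.4f} gDW/mmol (unique: {bm.unique})")
print(f"net CO2 release      = {co2.max:.4f} mmol/mmol (unique: {co2.unique})")
print(f"RubisCO flux range   = [{rbc.min:.4f}, {rbc.max:.4f}]")

s2 = make_scenario("S2", "succinate")        # silent pathways closed
print(f"S2 minimal RubisCO flux = {solve_fva(model, s2, ['RBC'])['RBC'].min:.4f}")
s = flux_sensitivity(model, s2, "AKGS", "RBC", delta=0.1)
print(f"sensitivity d(minRubisCO)/d(aKG synthase) = {s.sensitivity:.2f}")
```

prints

```
biomass yield  Y_X/S = 0.0857 gDW/mmol (unique: True)
net CO2 release      = 0.6605 mmol/mmol (unique: True)
RubisCO flux range   = [0.3793, 20.3993]
S2 minimal RubisCO flux = 0.6847
sensitivity d(minRubisCO)/d(aKG synthase) = -3.00
```

Even though the general scenario S1 leaves 31 degrees of freedom open,
the biomass and CO2 yields are pinned uniquely: the cell must match the
oxidation state of succinate to that of biomass, and CO2 is the only
vent.  A substantial RubisCO flux is *required* (min 0.38, and 0.68
once the silent pathways are closed) despite net CO2 release — the
Calvin cycle acts as an electron sink.  The −3 sensitivity says each
unit of ferredoxin-dependent α-ketoglutarate synthase flux relieves the
Calvin cycle threefold.  Absolute yields depend on the shipped
(standard, Neidhardt-type) biomass table — see `docs/methods.md`;
structural results (sensitivities, net balances, H2 ceilings) do not.

The same analyses are scriptable from the shell:

```sh
pnsbflux fva --scenario S2 --substrate succinate --out runs/s2
pnsbflux net-stoich --pathway emcoa
pnsbflux h2 --substrate succinate --knockout RBC --deregulate AKGDH
pnsbflux table t3 --out tables/
pnsbflux build-model --species rru --out rru_model/   # TSV + SBML export
```

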