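# Methods

## The model

`pnsbflux` ships a manually curated stoichiometric "master" model of the
central metabolism of purple nonsulfur bacteria (PNSB), integrating the
pathway repertoires of *Rhodospirillum rubrum* (rru), *Rhodobacter
sphaeroides* (rsp) and *Rhodopseudomonas palustris* (rpa) into one
network.  Reactions present in only some organisms carry species tags;
`species_submodel` restricts the master to one organism.  The shipped
reconstruction has 102 reactions over 76 balanced (internal)
metabolites.  Pathway coverage: glycolysis/gluconeogenesis, both
pentose-phosphate branches (the oxidative branch tagged rpa-only, since
rru lacks glucose-6-phosphate dehydrogenase and rsp routes
6-phosphogluconate into the Entner-Doudoroff pathway instead), the
Entner-Doudoroff pathway (rsp), the full TCA cycle plus fumarate
reductase, the Calvin cycle (RubisCO, phosphoribulokinase and the
sedoheptulose-bisphosphate leg), the ferredoxin-dependent reductive-TCA
enzymes α-ketoglutarate synthase and pyruvate synthase (rru),
anaplerotics (pyruvate carboxylase, NADP malic enzyme, PEP
carboxykinase), all three acetate assimilation routes — glyoxylate shunt
(rpa), citramalate cycle and ethylmalonyl-CoA pathway (rru/rsp) — the
propionyl-CoA/methylmalonyl-CoA branch, pyruvate formate-lyase with
formate hydrogenlyase, a lumped electron transport chain, nitrogenase
(including a hydrogenase-only mode), a reversible ATP-independent uptake
hydrogenase, substrate uptakes (succinate, malate, acetate, propionate,
fructose via PTS, H2, CO2 reversible, NH4, SO4, Pi, N2, O2, photons),
product excretions (succinate, acetate, propionate, formate, H2), an ATP
maintenance drain, and lumped anabolism.

### Steady state and flux bounds

At steady state the internal metabolite balances read `N·r = 0` with the
m×q stoichiometric matrix N.  Fluxes are capped at 100 mmol/(gDW·h)
(irreversible: [0, 100]; reversible: [−100, 100]); the cap is
configurable (`default_bound`).  A *scenario* fixes selected rates —
mostly to zero, encoding closed exchanges and regulatorily silent
pathways — and normalizes one substrate uptake to 1 mmol/(gDW·h), so
the biomass flux μ equals the molar yield Y_X/S in gDW/mmol and all
reported yields are per mmol substrate.  Flux variability analysis
(FVA) then minimizes and maximizes each flux over the polytope; a flux
whose bounds coincide is uniquely determined by the constraints alone —
no growth-optimality or other objective is ever assumed.

### Elemental and electron bookkeeping

Coefficients are exact rationals (`fractions.Fraction`), so net
stoichiometries of pathway subsets cancel without floating-point noise;
only the LPs run in floating point.  Protons, water and charge are not
balanced.  Every non-pseudo metabolite carries an elemental formula over
{C,H,O,N,P,S} with two bookkeeping conventions: acyl-CoA thioesters are
written as acid + CoA − H2O, and each two-electron carrier's reduced
form is its oxidized form + H2 (NADH, NADPH, ubiquinol, and reduced
ferredoxin, which gets the formal pair S2/H2S2).  Under these
conventions every formula-complete reaction balances C, N, P and S
exactly *and* balances the degree of reduction
γ = 4C + H − 2O − 3N + 5P − 2S (reference states CO2, H2O, NH3, H3PO4,
H2S), because γ(H2O) = 0 and the hydrogens of omitted protons ride on
the carriers.  Both audits run over the whole network in the test suite.
The degree of reduction also yields the theoretical hydrogen ceiling of
a substrate, γ/2 mol H2 per mol (succinate 14 electrons → 7 H2,
fructose 24 → 12).

### Electron transport chain and energy

The ETC is lumped through a proton-motive-force (pmf) pseudo-metabolite
counting translocated charges: NADH dehydrogenase pumps 4 charges per
NADH (reversible — its reverse direction is pmf-driven reverse electron
flow, which is how electrons delivered to ubiquinone by succinate or
methylsuccinyl-CoA dehydrogenase are counted as NADH in net balances);
the bc1 complex pumps 4 charges per quinol and cytochrome-c oxidase 2
more (10 per NADH through the cytochrome branch), against 6 through the
lower-yield quinol oxidase; the ATP synthase converts 4 charges per ATP;
cyclic photophosphorylation (reaction center + bc1) turns 2 photons into
4 charges without consuming or producing electrons.  These
stoichiometries are configurable; under phototrophy ATP production is
decoupled from redox (photons are free within the flux cap), so the
photoheterotrophic results are insensitive to them, and the aerobic
scenario is treated qualitatively.  The membrane transhydrogenase is
modeled *reversible* (pmf-coupled, 1 charge per hydride): PntAB-type
enzymes equilibrate with the pmf, and the reverse direction is required
so that NADPH formed by isocitrate dehydrogenase can be discharged in
complete-oxidation (biomass = 0) hydrogen-yield calculations.  PEP
synthetase and the acyl-CoA synthetases are lumped to whole-ATP
equivalents (AMP/PPi recycling folded in).

### Biomass

Anabolism is condensed into one lumped synthesis reaction per
macromolecule pool — protein 50%, lipid 16%, RNA 16%, PHB 5%, DNA 3%,
LPS 3%, glycogen 2%, peptidoglycan 2%, polyphosphate 2%,
bacteriochlorophyll 1% by mass — plus a biomass pseudo-reaction
combining the pools by mass fraction (equivalently, a single folded
biomass reaction; both architectures give identical FVA results and the
equivalence is tested).  The per-gram precursor demands are standard
Gram-negative (Neidhardt-type) coefficients scaled to the PNSB mass
fractions and shipped as an editable TSV.  The implied biomass carries
≈ 39 mmol C and ≈ 160 electron-mmol per gDW.  Consequently *all
biomass-coefficient-dependent numbers — absolute growth and CO2 yields,
minimal RubisCO fluxes, RubisCO-knockout H2 yields, the
transhydrogenase flux, the CO2/biomass responses to H2 release — are
biomass-sensitive and flagged as such in the reports*; their signs,
substrate orderings and uniqueness structure are structural and are the
properties the tests pin.  Structural quantities (pathway net balances,
electron-count H2 maxima, the RubisCO sensitivities to the reductive and
oxidative TCA, oxPPP and EDP) are biomass-independent.

## Scenarios

The environmental scenarios live in `data/scenarios.yaml`, one section
per condition (S1 general photoheterotrophic; S2 adds the closed
"silent" pathways; S3/S4/S5 re-enable exactly one acetate route each and
keep pyruvate synthase closed; S6 dark anaerobic with the four organic
excretion gates open; S7 dark aerobic with photosynthesis, Calvin cycle,
fumarate reductase, reductive TCA and nitrogenase closed and O2 free).
Blank table cells mean "free": anaerobiosis of S1–S5 comes from the O2
uptake being zero, not from a photosynthesis constraint.  Single-entry
overrides (`apply_override`) express knockouts (fix 0), deregulations
(free) and sensitivity perturbations (fix δ) without touching the base
scenario.

## Analyses

**Sensitivities** are finite differences: with a key reaction fixed at 0
in the base scenario, raise it to δ = 0.1, re-solve the FVA bound of the
target (minimum by default) and divide the change by δ.  The LP response
is piecewise linear, so on a facet the quotient is δ-independent (tested
with δ = 0.05 vs 0.1).  Non-unique targets are reported against the
chosen bound, never hidden.

**Net conversions** sum N·v over a rational flux assignment; canonical
unit cycles (smallest positive-integer balanced assignments) are shipped
for the Calvin cycle, the three acetate routes, and the two virtual
transhydrogenase cycles.  Carrier folding (optional, off by default)
re-expresses quinol and reduced ferredoxin as NADH via reverse electron
flow and records the pmf symbolically.  The Calvin unit cycle passes all
six trioses through the GAP dehydrogenase and exports one
glyceraldehyde-3-phosphate: net 3 CO2 + 6 NADH + 9 ATP → triose-P +
8 Pi, which is the electron-exact form of the textbook balance (a C3
product at the 3-phosphoglycerate oxidation level would hold 10 rather
than 12 electrons).  The Entner-Doudoroff transhydrogenase loop costs
2 ATP per NADPH in this network (PEP synthetase + phosphoglycerate
kinase); no mass-balanced route through a kinased GAP dehydrogenase can
do it for less, which is why the acceptance test asserting a 1-ATP cost
is expected to fail and is left failing.

**Hydrogen yields** free the H2 gate, fix knockouts to zero, free
deregulated reactions, and FVA the H2 excretion.  Growth keeps its free
lower bound of 0 — scenarios that cannot balance without growth exclude
μ = 0 on their own — unless the complete-oxidation mode pins biomass to
zero, in which case the LP maximum equals the degree-of-reduction
ceiling exactly (tested for all substrates).

## Numerics and degenerate inputs

LPs are solved with scipy's HiGHS interface, deterministic settings,
feasibility tolerance at solver default (~1e-9).  Uniqueness:
|max − min| ≤ 1e-6 × default_bound (1e-4 flux units).  Reported values
within 1e-9 of zero are snapped to zero for reporting only.  Scenario
infeasibility is an explicit result status (never partial output);
"growth impossible" can also surface as a zero maximal yield when an
open excretion gate lets the substrate cycle out, as for dark anaerobic
acetate.  Scale invariance of yields holds below the flux cap; maxima
that touch the cap (e.g. the upper RubisCO bound) do not scale with the
uptake normalization.  Empty models, empty flux assignments and empty
target lists return empty results rather than errors.

## Fixture networks and the oracle

`synth.make_toy` generates chains (all fluxes unique), diamonds
(parallel branches span [0, uptake]), a five-reaction redox toy that
reproduces the uniqueness mechanism of photoheterotrophy (a closed H2
valve pins the biomass-like drain; opening it widens the drain to a
proper interval), and seeded random acyclic networks.  The LP engine is
validated against `brute_force_fva`, an independent exact-rational
vertex enumeration of the constrained flux polytope (all basic
solutions from pinning free coordinates to box bounds), across 50 seeds.
These fixtures emulate conservative small networks with closed-form
answers; they do not emulate degenerate thermodynamic loops or
genome-scale degeneracy, so passing them certifies the LP plumbing, not
biological realism — the master-model tests carry that weight, with
cobrapy (GLPK) as a second, independent FVA implementation on a
spot-check panel.

## Known limitations

- Kinetics, regulation and ΔG-based feasibility are out of scope; only
  reversibility signs constrain directions.
- The biomass precursor table is a scaled standard table, not an
  organism-measured one; absolute yields shift with it (structure does
  not).
- The aerobic scenario S7 is qualitative (maintenance unspecified, ATP
  yields of the two oxidase branches untested against data).
- CO-linked hydrogenase and genome-scale coverage are deliberately
  excluded.
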