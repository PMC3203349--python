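# Environmental scenarios as declarative constraint sets.
#
# Each scenario lists the reaction rates fixed to zero for that
# condition; the substrate uptake is normalized to 1 mmol/(gDW*h) and
# all other substrate uptakes are closed by the scenario builder.
# "free" lists product excretions that stay open (fermentation).
# Blank cells of the published constraint table mean "free": the
# anaerobiosis of the phototrophic scenarios comes from O2up = 0, not
# from a constraint on photosynthesis.

substrates:
  succinate: SUCup
  malate: MALup
  acetate: ACup
  propionate: PROPup
  fructose: FRUup
  hydrogen: H2up

# every substrate uptake reaction; those not chosen are fixed to zero
uptakes: [SUCup, MALup, ACup, PROPup, FRUup, H2up]

scenarios:
  S1:
    description: general photoheterotrophic growth (anaerobic, light, no excretion)
    fix:
      N2up: 0
      O2up: 0
      SUCex: 0
      PROPex: 0
      ACex: 0
      FORMex: 0
      H2ex: 0
  S2:
    description: constrained photoheterotrophic growth (regulatorily silent pathways closed)
    base: S1
    fix:
      PGD: 0
      EDD: 0
      AKGDH: 0
      AKGS: 0
      PYS: 0
      ICL: 0
      CMS: 0
      ECH: 0
  S3:
    description: photoheterotrophic growth on acetate via the glyoxylate shunt
    base: S1
    fix:
      PGD: 0
      EDD: 0
      AKGDH: 0
      AKGS: 0
      PYS: 0
      CMS: 0
      ECH: 0
  S4:
    description: photoheterotrophic growth on acetate via the citramalate cycle
    base: S1
    fix:
      PGD: 0
      EDD: 0
      AKGDH: 0
      AKGS: 0
      PYS: 0
      ICL: 0
      ECH: 0
  S5:
    description: photoheterotrophic growth on acetate via the ethylmalonyl-CoA pathway
    base: S1
    fix:
      PGD: 0
      EDD: 0
      AKGDH: 0
      AKGS: 0
      PYS: 0
      ICL: 0
      CMS: 0
  S6:
    description: anaerobic growth in the dark (fermentation; product gates open)
    fix:
      N2up: 0
      O2up: 0
      H2ex: 0
      RC: 0
    free: [SUCex, PROPex, ACex, FORMex]
  S7:
    description: aerobic growth in the dark (respiration)
    fix:
      N2up: 0
      RC: 0
      RBC: 0
      AKGS: 0
      PYS: 0
      FRD: 0
      NIT: 0
      NITH2: 0
      SUCex: 0
      PROPex: 0
      ACex: 0
      FORMex: 0
      H2ex: 0
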