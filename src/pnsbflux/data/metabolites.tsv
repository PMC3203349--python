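id	name	external	formula
G6P	glucose 6-phosphate	0	C6H13O9P
F6P	fructose 6-phosphate	0	C6H13O9P
F1P	fructose 1-phosphate	0	C6H13O9P
FBP	fructose 1,6-bisphosphate	0	C6H14O12P2
DHAP	dihydroxyacetone phosphate	0	C3H7O6P
GAP	glyceraldehyde 3-phosphate	0	C3H7O6P
BPG	1,3-bisphosphoglycerate	0	C3H8O10P2
PG3	3-phosphoglycerate	0	C3H7O7P
PEP	phosphoenolpyruvate	0	C3H5O6P
Pyr	pyruvate	0	C3H4O3
PGluc	6-phosphogluconate	0	C6H13O10P
KDPG	2-keto-3-deoxy-6-phosphogluconate	0	C6H11O9P
Ru5P	ribulose 5-phosphate	0	C5H11O8P
R5P	ribose 5-phosphate	0	C5H11O8P
X5P	xylulose 5-phosphate	0	C5H11O8P
S7P	sedoheptulose 7-phosphate	0	C7H15O10P
E4P	erythrose 4-phosphate	0	C4H9O7P
SBP	sedoheptulose 1,7-bisphosphate	0	C7H16O13P2
RuBP	ribulose 1,5-bisphosphate	0	C5H12O11P2
Fru	fructose (intracellular, pre-PTS)	0	C6H12O6
Ac	acetate	0	C2H4O2
Prop	propionate	0	C3H6O2
Form	formate	0	CH2O2
Succ	succinate	0	C4H6O4
Fum	fumarate	0	C4H4O4
Mal	malate	0	C4H6O5
OAA	oxaloacetate	0	C4H4O5
Cit	citrate	0	C6H8O7
ICit	isocitrate	0	C6H8O7
aKG	alpha-ketoglutarate	0	C5H6O5
Glyox	glyoxylate	0	C2H2O3
CitMal	citramalate	0	C5H8O5
Mesac	mesaconate	0	C5H6O4
CoA	coenzyme A	0	C21H36N7O16P3S
AcCoA	acetyl-CoA	0	C23H38N7O17P3S
SuccCoA	succinyl-CoA	0	C25H40N7O19P3S
PropCoA	propionyl-CoA	0	C24H40N7O17P3S
MMCoA	methylmalonyl-CoA	0	C25H40N7O19P3S
AcacCoA	acetoacetyl-CoA	0	C25H40N7O18P3S
HyBuCoA	3-hydroxybutyryl-CoA	0	C25H42N7O18P3S
CrotCoA	crotonyl-CoA	0	C25H40N7O17P3S
EMCoAm	ethylmalonyl-CoA	0	C26H42N7O19P3S
MesucCoA	methylsuccinyl-CoA	0	C26H42N7O19P3S
MesacCoA	mesaconyl-CoA	0	C26H40N7O19P3S
MMalCoA	beta-methylmalyl-CoA	0	C26H42N7O20P3S
NAD	NAD (oxidized)	0	C21H27N7O14P2
NADH	NADH (reduced; carries 2 electrons as +H2)	0	C21H29N7O14P2
NADP	NADP (oxidized)	0	C21H28N7O17P3
NADPH	NADPH (reduced; carries 2 electrons as +H2)	0	C21H30N7O17P3
Q	ubiquinone	0	C49H74O4
QH2	ubiquinol	0	C49H76O4
Fdox	ferredoxin (oxidized; bookkeeping formula)	0	S2
Fdred	ferredoxin (reduced; 2-electron carrier, bookkeeping formula)	0	H2S2
ATP	ATP	0	C10H16N5O13P3
ADP	ADP	0	C10H15N5O10P2
Pi	inorganic phosphate	0	H3PO4
Cytc	cytochrome c2 (oxidized)	0
Cytcred	cytochrome c2 (reduced; 1-electron carrier)	0
pmf	proton motive force (membrane charge translocation unit)	0
Photon	photon (captured light quantum)	0
CO2	carbon dioxide	0	CO2
O2	molecular oxygen	0	O2
H2	molecular hydrogen (intracellular)	0	H2
NH4	ammonium (electron bookkeeping as NH3)	0	NH3
SO4	sulfate (electron bookkeeping as H2SO4)	0	H2SO4
N2	dinitrogen	0	N2
Protein	protein pool (1 g)	0
Lipid	lipid pool (1 g)	0
RNA	RNA pool (1 g)	0
DNA	DNA pool (1 g)	0
PHB	poly-beta-hydroxybutyrate pool (1 g)	0
LPS	lipopolysaccharide pool (1 g)	0
Glycogen	glycogen pool (1 g)	0
PepG	peptidoglycan pool (1 g)	0
PolyP	polyphosphate pool (1 g)	0
Bchl	bacteriochlorophyll pool (1 g)	0
Succ_ext	succinate (medium)	1	C4H6O4
Mal_ext	malate (medium)	1	C4H6O5
Ac_ext	acetate (medium)	1	C2H4O2
Prop_ext	propionate (medium)	1	C3H6O2
Fru_ext	fructose (medium)	1	C6H12O6
Form_ext	formate (medium)	1	CH2O2
H2_ext	hydrogen (gas phase)	1	H2
CO2_ext	carbon dioxide (gas phase)	1	CO2
O2_ext	oxygen (gas phase)	1	O2
NH4_ext	ammonium (medium)	1	NH3
SO4_ext	sulfate (medium)	1	H2SO4
Pi_ext	phosphate (medium)	1	H3PO4
N2_ext	dinitrogen (gas phase)	1	N2
Photon_ext	light	1
Biomass_ext	biomass (1 gDW)	1
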