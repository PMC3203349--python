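# Precursor, cofactor and inorganic demands per gram of macromolecule
# (mmol/g).  Positive = consumed, negative = produced.  Standard
# Gram-negative (Neidhardt-type) coefficients; carrier counterparts
# (ADP for ATP, NAD for NADH, CoA for acyl-CoA) are completed by the
# biomass builder.  Phosphate rows close the P balance of each lumped
# synthesis reaction.
macromolecule	metabolite	mmol_per_g
protein	PG3	2.0
protein	PEP	0.7
protein	Pyr	2.4
protein	OAA	2.1
protein	aKG	2.2
protein	AcCoA	0.3
protein	E4P	0.65
protein	R5P	0.55
protein	NH4	12.0
protein	SO4	0.27
protein	NADPH	18.0
protein	NADH	-3.0
protein	ATP	40.0
lipid	AcCoA	20.8
lipid	GAP	1.3
lipid	PG3	0.9
lipid	NH4	0.9
lipid	NADPH	36.4
lipid	NADH	1.3
lipid	ATP	20.0
lipid	Pi	1.3
rna	R5P	3.09
rna	PG3	1.9
rna	OAA	1.55
rna	CO2	3.1
rna	NH4	11.7
rna	NADPH	1.0
rna	NADH	-1.5
rna	ATP	15.0
rna	Pi	3.09
dna	R5P	3.24
dna	PG3	2.0
dna	OAA	1.62
dna	CO2	3.2
dna	NH4	12.0
dna	NADPH	4.5
dna	NADH	-1.0
dna	ATP	16.0
dna	Pi	3.24
phb	HyBuCoA	11.62
lps	G6P	2.0
lps	F6P	0.5
lps	AcCoA	4.0
lps	PEP	0.3
lps	R5P	0.3
lps	NH4	0.6
lps	NADPH	6.0
lps	ATP	6.0
lps	Pi	0.5
glycogen	G6P	6.17
glycogen	ATP	6.17
glycogen	Pi	-12.34
peptidoglycan	F6P	2.0
peptidoglycan	PEP	1.0
peptidoglycan	AcCoA	2.0
peptidoglycan	Pyr	2.0
peptidoglycan	OAA	1.0
peptidoglycan	NH4	4.0
peptidoglycan	NADPH	3.0
peptidoglycan	ATP	8.0
polyphosphate	ATP	12.5
bchl	aKG	8.8
bchl	Pyr	4.4
bchl	GAP	4.4
bchl	NH4	4.4
bchl	NADPH	20.0
bchl	ATP	15.0
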