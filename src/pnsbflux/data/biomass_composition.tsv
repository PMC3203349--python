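macromolecule	mass_fraction
protein	0.50
lipid	0.16
rna	0.16
phb	0.05
dna	0.03
lps	0.03
glycogen	0.02
peptidoglycan	0.02
polyphosphate	0.02
bchl	0.01
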