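SMILES	InChI	CompoundName	Species	Citation	DOI
	InChI=1S/C10H14O/c1-7(2)9-5-4-8(3)6-10(9)11/h4-5,7,10-11H,6H2,1-3H3		Mentha arvensis	Someone A. B., Phytochemistry, 12, 100-104 (1973).
CC(=O)Oc1ccccc1C(=O)O		aspirin	Salix alba		10.1000/DEMO.1
		ß-sitosterol	Stem bark of Cyathocalyx zeylanica	Wijeratne E. M. K., J. Nat. Prod., 58, 459-462 (1995).
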