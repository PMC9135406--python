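# Counterion / crystallization-solvent fragments removed during sanitization.
# Format: name<TAB>SMARTS (the layout rdMolStandardize.FragmentRemoverFromData
# expects). Adapted from the open MolVS/ChEMBL salt lists.
fluorine	[F]
chlorine	[Cl]
bromine	[Br]
iodine	[I]
sodium	[Na]
potassium	[K]
lithium	[Li]
calcium	[Ca]
magnesium	[Mg]
zinc	[Zn]
ammonium	[#7H4+]
hydroxide	[#8H1-]
water	[#8H2]
nitrate	[#7+](=[#8])([#8-])[#8-]
sulfate	[#8]=[#16](=[#8])([#8-,#8H1])[#8-,#8H1]
hydrogensulfate	[#8]S(=O)(=O)[#8H1]
phosphate	[#8]=[#15]([#8-,#8H1])([#8-,#8H1])[#8-,#8H1]
perchlorate	[#8]=[Cl+3]([#8-])([#8-])[#8-]
acetate	[#6H3]-[#6](=[#8])[#8-,#8H1]
trifluoroacetate	[#8-,#8H1]-[#6](=[#8])-[#6](-[#9])(-[#9])-[#9]
formate	[#6H1](=[#8])[#8-,#8H1]
oxalate	[#8-,#8H1]-[#6](=[#8])-[#6](=[#8])-[#8-,#8H1]
methanesulfonate	[#6H3]S(=O)(=O)[#8-,#8H1]
toluenesulfonate	[#6H3]-[#6]1:[#6]:[#6]:[#6](:[#6]:[#6]:1)S(=O)(=O)[#8-,#8H1]
benzenesulfonate	[#6]1:[#6]:[#6]:[#6](:[#6]:[#6]:1)S(=O)(=O)[#8-,#8H1]
methanol	[#6H3]-[#8H1]
ethanol	[#6H3]-[#6H2]-[#8H1]
isopropanol	[#6H3]-[#6H1](-[#6H3])-[#8H1]
acetone	[#6H3]-[#6](=[#8])-[#6H3]
acetonitrile	[#6H3]-[#6]#[#7]
diethyl ether	[#6H3]-[#6H2]-[#8]-[#6H2]-[#6H3]
tetrahydrofuran	[#6H2]1-[#6H2]-[#6H2]-[#6H2]-[#8]-1
dichloromethane	[#6H2](-[Cl])-[Cl]
chloroform	[#6H1](-[Cl])(-[Cl])-[Cl]
dmso	[#6H3]-[#16](=[#8])-[#6H3]
dmf	[#6H3]-[#7](-[#6H3])-[#6H1]=[#8]
hexane	[#6H3]-[#6H2]-[#6H2]-[#6H2]-[#6H2]-[#6H3]
benzene	[#6H1]1:[#6H1]:[#6H1]:[#6H1]:[#6H1]:[#6H1]:1
toluene	[#6H3]-[#6]1:[#6H1]:[#6H1]:[#6H1]:[#6H1]:[#6H1]:1
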