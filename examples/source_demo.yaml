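# Per-source column mapping for the demo table (examples/source_demo.tsv).
# Each raw column is declared as a structure descriptor (with an optional
# subcategory hint), the organism field, or one of the ten reference
# subcategories.
source_id: DEMO
structure_columns:
  SMILES: smiles
  InChI: inchi
  CompoundName: name
organism_column: Species
reference_columns:
  Citation: original
  DOI: doi
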