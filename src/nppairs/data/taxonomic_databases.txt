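# Accepted taxonomic databases for taxon identifiers.
ITIS
NCBI
Index Fungorum
GRIN Taxonomy for Plants
The Interim Register of Marine and Nonmarine Genera
World Register of Marine Species
WoRMS
GBIF Backbone Taxonomy
Encyclopedia of Life
AmphibiaWeb
ARKive
ZooBank
Database of Vascular Plants of Canada (VASCAN)
Phasmida Species File
USDA NRCS PLANTS Database
FishBase
EUNIS
IUCN Red List of Threatened Species
BioLib.cz
Tropicos - Missouri Botanical Garden
The International Plant Names Index
uBio NameBank
The Mammal Species of The World
BirdLife International
Open Tree of Life
iNaturalist
The eBird/Clements Checklist of Birds of the World
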