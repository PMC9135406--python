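# Latin-genitive drug-name element -> canonical genus, for TCM/pharmacognostic
# names such as "Ginseng Radix" or "Radix Glycyrrhizae".
ginseng	Panax ginseng
glycyrrhizae	Glycyrrhiza uralensis
ephedrae	Ephedra sinica
angelicae sinensis	Angelica sinensis
astragali	Astragalus mongholicus
rhei	Rheum palmatum
salviae miltiorrhizae	Salvia miltiorrhiza
scutellariae	Scutellaria baicalensis
coptidis	Coptis chinensis
curcumae longae	Curcuma longa
zingiberis	Zingiber officinale
citri reticulatae	Citrus reticulata
paeoniae	Paeonia lactiflora
bupleuri	Bupleurum chinense
artemisiae annuae	Artemisia annua
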