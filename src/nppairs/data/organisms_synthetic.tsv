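canonical	synonyms	vernaculars	db	taxon_id	rank	family	domain	kingdom	ott_id
Arabidopsis thaliana		Mouse-ear cress|Thale cress	NCBI	3702	species	Brassicaceae	Eukaryota	Archaeplastida	309263
Cyathocalyx zeylanicus	Cyathocalyx zeylanica		GBIF Backbone Taxonomy	5407765	species	Annonaceae	Eukaryota	Archaeplastida	563121
Crataegus monogyna		Common hawthorn	GBIF Backbone Taxonomy	3013250	species	Rosaceae	Eukaryota	Archaeplastida	563122
Crataegus oxyacantha	Crataegus laevigata		GBIF Backbone Taxonomy	3013252	species	Rosaceae	Eukaryota	Archaeplastida	563123
Crataegus stevenii			GBIF Backbone Taxonomy	3013260	species	Rosaceae	Eukaryota	Archaeplastida	563124
Panax ginseng		Ginseng|Asian ginseng	NCBI	4054	species	Araliaceae	Eukaryota	Archaeplastida	563125
Panax quinquefolius		American ginseng|Red ginseng	NCBI	44588	species	Araliaceae	Eukaryota	Archaeplastida	563126
Mangifera indica		Mango	NCBI	29780	species	Anacardiaceae	Eukaryota	Archaeplastida	563127
Bromus mango			GBIF Backbone Taxonomy	2703664	species	Poaceae	Eukaryota	Archaeplastida	563128
Actinidia deliciosa		Kiwi fruit|Kiwifruit	NCBI	3627	species	Actinidiaceae	Eukaryota	Archaeplastida	563129
Nelumbo nucifera		Sacred lotus	NCBI	4432	species	Nelumbonaceae	Eukaryota	Archaeplastida	563130
Lotus japonicus			NCBI	34305	species	Fabaceae	Eukaryota	Archaeplastida	563131
Citrus reticulata		Mandarin orange	NCBI	85571	species	Rutaceae	Eukaryota	Archaeplastida	563132
Camellia sinensis		Tea plant	NCBI	4442	species	Theaceae	Eukaryota	Archaeplastida	563133
Coffea arabica		Arabica coffee	NCBI	13443	species	Rubiaceae	Eukaryota	Archaeplastida	563134
Artemisia annua		Sweet wormwood	NCBI	35608	species	Asteraceae	Eukaryota	Archaeplastida	563135
Papaver somniferum		Opium poppy	NCBI	3469	species	Papaveraceae	Eukaryota	Archaeplastida	563136
Catharanthus roseus		Madagascar periwinkle	NCBI	4058	species	Apocynaceae	Eukaryota	Archaeplastida	563137
Taxus brevifolia		Pacific yew	NCBI	46220	species	Taxaceae	Eukaryota	Archaeplastida	563138
Glycyrrhiza uralensis		Chinese licorice	NCBI	74613	species	Fabaceae	Eukaryota	Archaeplastida	563139
Curcuma longa		Turmeric	NCBI	136217	species	Zingiberaceae	Eukaryota	Archaeplastida	563140
Zingiber officinale		Ginger	NCBI	94328	species	Zingiberaceae	Eukaryota	Archaeplastida	563141
Capsicum annuum		Chili pepper	NCBI	4072	species	Solanaceae	Eukaryota	Archaeplastida	563142
Nicotiana tabacum		Tobacco	NCBI	4097	species	Solanaceae	Eukaryota	Archaeplastida	563143
Vitis vinifera		Grapevine	NCBI	29760	species	Vitaceae	Eukaryota	Archaeplastida	563144
Punica granatum		Pomegranate	NCBI	22663	species	Lythraceae	Eukaryota	Archaeplastida	563145
Rheum palmatum		Chinese rhubarb	NCBI	137221	species	Polygonaceae	Eukaryota	Archaeplastida	563146
Simarouba amara			GBIF Backbone Taxonomy	7911539	species	Simaroubaceae	Eukaryota	Archaeplastida	563147
Quassia amara		Bitterwood	GBIF Backbone Taxonomy	3190495	species	Simaroubaceae	Eukaryota	Archaeplastida	563148
Hypericum perforatum		St John's wort	NCBI	65561	species	Hypericaceae	Eukaryota	Archaeplastida	563149
Salvia miltiorrhiza		Danshen	NCBI	226208	species	Lamiaceae	Eukaryota	Archaeplastida	563150
Ephedra sinica		Ma huang	NCBI	33152	species	Ephedraceae	Eukaryota	Archaeplastida	563151
Penicillium chrysogenum	Penicillium notatum		Index Fungorum	170789	species	Aspergillaceae	Eukaryota	Fungi	563160
Aspergillus niger			Index Fungorum	284614	species	Aspergillaceae	Eukaryota	Fungi	563161
Ganoderma lucidum		Reishi|Lingzhi	Index Fungorum	191306	species	Ganodermataceae	Eukaryota	Fungi	563162
Amanita muscaria		Fly agaric	Index Fungorum	335633	species	Amanitaceae	Eukaryota	Fungi	563163
Claviceps purpurea		Ergot fungus	Index Fungorum	222678	species	Clavicipitaceae	Eukaryota	Fungi	563164
Psilocybe cubensis			Index Fungorum	314377	species	Hymenogastraceae	Eukaryota	Fungi	563165
Squatina squatina		Angelshark	WoRMS	105837	species	Squatinidae	Eukaryota	Metazoa	563170
Squatina australis		Australian angelshark	WoRMS	282972	species	Squatinidae	Eukaryota	Metazoa	563171
Apteryx australis		Kiwi|Southern brown kiwi	NCBI	8822	species	Apterygidae	Eukaryota	Metazoa	563172
Bufo bufo		Common toad	NCBI	8384	species	Bufonidae	Eukaryota	Metazoa	563173
Conus magus		Magical cone	WoRMS	215499	species	Conidae	Eukaryota	Metazoa	563174
Tethya aurantium		Golf ball sponge	WoRMS	134313	species	Tethyidae	Eukaryota	Metazoa	563175
Dendrobates tinctorius		Dyeing poison frog	NCBI	92724	species	Dendrobatidae	Eukaryota	Metazoa	563176
Streptomyces griseus			NCBI	1911	species	Streptomycetaceae	Bacteria	NA	563180
Streptomyces coelicolor			NCBI	1902	species	Streptomycetaceae	Bacteria	NA	563181
Bacillus subtilis			NCBI	1423	species	Bacillaceae	Bacteria	NA	563182
Pseudomonas fluorescens			NCBI	294	species	Pseudomonadaceae	Bacteria	NA	563183
Nostoc punctiforme			NCBI	272131	species	Nostocaceae	Bacteria	NA	563184
Chlorella vulgaris			NCBI	3077	species	Chlorellaceae	Eukaryota	NA	563190
Fucus vesiculosus		Bladder wrack	WoRMS	145548	species	Fucaceae	Eukaryota	NA	563191
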