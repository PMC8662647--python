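species	family	clade	assembly	status	invasive	fusion
Muscardinus avellanarius	Gliridae	Sciuromorpha	MusAve_v1_BIUU	intact	0	0
Glis glis	Gliridae	Sciuromorpha	GliGli_v1_BIUU	intact	0	0
Graphiurus murinus	Gliridae	Sciuromorpha	GraMur_v1_BIUU	intact	0	0
Xerus inauris	Sciuridae	Sciuromorpha	XerIna_v1_BIUU	pseudogene	0	0
Ictidomys tridecemlineatus	Sciuridae	Sciuromorpha	SpeTri2.0	pseudogene	0	0
Cynomys gunnisoni	Sciuridae	Sciuromorpha	ASM1131664v1	pseudogene	0	0
Spermophilus dauricus	Sciuridae	Sciuromorpha	ASM240643v1	pseudogene	0	0
Urocitellus parryii	Sciuridae	Sciuromorpha	ASM342692v1	pseudogene	0	0
Marmota himalayana	Sciuridae	Sciuromorpha	ASM528016v1	pseudogene	0	0
Marmota marmota	Sciuridae	Sciuromorpha	marMar	pseudogene	0	0
Marmota monax	Sciuridae	Sciuromorpha	MONAX5	pseudogene	0	0
Aplodontia rufa	Aplodontiidae	Sciuromorpha	AplRuf_v1_BIUU	intact	0	0
Pedetes capensis	Pedetidae	Supramyomorpha	PedCap_v1_BIUU	intact	0	0
Castor canadensis	Castoridae	Supramyomorpha	C.can_genome_v1.0	intact	1	0
Dipodomys ordii	Heteromyidae	Supramyomorpha	Dord_2.0	absent	0	0
Jaculus jaculus	Dipodidae	Supramyomorpha	JacJac1.0	pseudogene	0	0
Allactaga bullata	Dipodidae	Supramyomorpha	AllBul_v1_BIUU	pseudogene	0	0
Zapus hudsonius	Zapodidae	Supramyomorpha	ZapHud_v1_BIUU	intact	0	0
Nannospalax galili	Spalacidae	Supramyomorpha	S.galili_v1.0	intact	0	0
Cricetomys gambianus	Nesomyidae	Supramyomorpha	CriGam_v1_BIUU	pseudogene	1	0
Microtus ochrogaster	Cricetidae	Supramyomorpha	MicOch1.0	pseudogene	0	0
Cricetulus griseus	Cricetidae	Supramyomorpha	CriGri_1.0	pseudogene	0	0
Peromyscus maniculatus	Cricetidae	Supramyomorpha	Pman_1.0	pseudogene	1	0
Peromyscus leucopus	Cricetidae	Supramyomorpha	UCI_PerLeu_2.1	pseudogene	0	0
Mesocricetus auratus	Cricetidae	Supramyomorpha	MesAur1.0	pseudogene	0	0
Rattus norvegicus	Muridae	Supramyomorpha	Rnor_6.0	pseudogene	1	0
Rattus rattus	Muridae	Supramyomorpha	Rrattus_CSIRO_v1	pseudogene	1	0
Grammomys dolichurus	Muridae	Supramyomorpha	NIH_TR_1.0	pseudogene	0	0
Mus musculus	Muridae	Supramyomorpha	GRCm39	pseudogene	1	0
Mus caroli	Muridae	Supramyomorpha	CAROLI_EIJ_v1.1	pseudogene	0	0
Mastomys coucha	Muridae	Supramyomorpha	UCSF_Mcou_1	pseudogene	0	0
Mus pahari	Muridae	Supramyomorpha	PAHARI_EIJ_v1.1	pseudogene	0	0
Ctenodactylus gundi	Ctenodactylidae	Hystricomorpha	CteGun_v1_BIUU	intact	0	0
Hystrix cristata	Hystricidae	Hystricomorpha	HysCri_v1_BIUU	intact	0	1
Fukomys damarensis	Bathyergidae	Hystricomorpha	DMR_v1.0	intact	0	1
Heterocephalus glaber	Heterocephalidae	Hystricomorpha	HetGla_female_1.0	intact	0	1
Petromus typicus	Petromuridae	Hystricomorpha	PetTyp_v1_BIUU	intact	0	1
Thryonomys swinderianus	Thryonomyidae	Hystricomorpha	ThrSwi_v1_BIUU	intact	0	1
Erethizon dorsatus	Erethizontidae	Hystricomorpha	GSC_porc_1.0	intact	0	1
Dolichotis patagonum	Caviidae	Hystricomorpha	DolPat_v1_BIUU	pseudogene	0	0
Hydrochoerus hydrochaeris	Caviidae	Hystricomorpha	HydHyd_v1_BIUU	intact	0	1
Cavia porcellus	Caviidae	Hystricomorpha	Cavpor3.0	intact	1	1
Cavia tschudii	Caviidae	Hystricomorpha	CavTsc_v1_BIUU	intact	0	1
Dasyprocta punctata	Dasyproctidae	Hystricomorpha	DasPun_v1_BIUU	intact	0	1
Cuniculus paca	Cuniculidae	Hystricomorpha	CunPac_v1_BIUU	intact	0	1
Chinchilla lanigera	Chinchillidae	Hystricomorpha	ChiLan1.0	intact	0	1
Dinomys branickii	Dinomyidae	Hystricomorpha	DinBra_v1_BIUU	intact	0	1
Capromys pilorides	Echimyidae	Hystricomorpha	CapPil_v1_BIUU	intact	0	1
Myocastor coypus	Echimyidae	Hystricomorpha	MyoCoy_v1_BIUU	intact	1	1
Octodon degus	Octodontidae	Hystricomorpha	OctDeg1.0	intact	0	1
Ctenomys sociabilis	Ctenomyidae	Hystricomorpha	CteSoc_v1_BIUU	intact	0	1
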