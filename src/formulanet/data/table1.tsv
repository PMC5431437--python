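id	name	ob	dl	herbs	rescued
M001	gymconopin B	44.85	0.54	Gymnadenia Conopsea	0
M002	1-(4-hydroxybenzyl)-4-methoxy-9,10-dihydrophenanthrene-2,7-diol	44.08	0.55	Gymnadenia Conopsea	0
M003	3,3'-dihydroxy-2-(4-hydroxybenzyl)-5-methoxybibenzyl	43.80	0.38	Gymnadenia Conopsea	0
M004	1-(4-hydroxybenzyl)-4-methoxyphenanthrene-2,7-diol	38.97	0.55	Gymnadenia Conopsea	0
M005	gymconopin A	38.69	0.38	Gymnadenia Conopsea	0
M006	gymnosides II	35.24	0.59	Gymnadenia Conopsea	0
M007	3',5-dihydroxy-2-(4-hydroxybenzyl)-3-methoxybibenzyl	34.42	0.38	Gymnadenia Conopsea	0
M008	2-methoxy-9,10-dihydrophenanthrene-4,5-diol	33.31	0.18	Gymnadenia Conopsea	0
M009	coelovirin A	31.07	0.59	Gymnadenia Conopsea	0
M010	coelovirin B	31.07	0.60	Gymnadenia Conopsea	0
M011	coelovirin E	4.33	0.23	Gymnadenia Conopsea	1
M012	n-heptanal	79.74	0.59	Stigma Croci	0
M013	isorhamnetin	49.60	0.31	Stigma Croci,Rhizoma Alpiniae Officinarum	0
M014	quercetin	46.43	0.28	Stigma Croci,Syringa Oblata	0
M015	crocetin	35.30	0.26	Stigma Croci	0
M016	kaempferol	41.88	0.24	Stigma Croci,Syringa Oblata,Rhizoma Alpiniae Officinarum	0
M017	safranal	39.56	0.04	Stigma Croci	1
M018	picrocrocin_qt	33.71	0.04	Stigma Croci	1
M019	methyllinolenate	46.15	0.18	Stigma Croci	0
M020	beta-sitosterol	36.91	0.75	Myristica Semena,Syringa Oblata,Rhizoma Alpiniae Officinarum	0
M021	galbacin	61.00	0.53	Myristica Semena	0
M022	licarin B	53.11	0.40	Myristica Semena	0
M023	cis-permethrin	45.06	0.38	Myristica Semena	0
M024	saucernetindiol	41.85	0.32	Myristica Semena	0
M025	isonectandrin B	62.86	0.32	Myristica Semena	0
M026	threo-austrobailignan-5	49.49	0.32	Myristica Semena	0
M027	isoguaiacin	48.78	0.31	Myristica Semena	0
M028	dihydroguaiaretic acid	31.32	0.26	Myristica Semena	0
M029	macelignan	23.60	0.32	Myristica Semena	1
M030	myristicin	17.99	0.07	Myristica Semena	1
M031	(S)-stylopine	51.15	0.85	Semen Strychni	0
M032	isostrychnine N-oxide (II)	37.33	0.80	Semen Strychni	0
M033	isostrychnine N-oxide (I)	35.45	0.80	Semen Strychni	0
M034	isobrucine	33.58	0.80	Semen Strychni	0
M035	lokundjoside_qt	32.82	0.76	Semen Strychni	0
M036	stigmasterol	43.83	0.76	Semen Strychni,Syringa Oblata	0
M037	vomicine	47.56	0.65	Semen Strychni	0
M038	ziziphin_qt	66.95	0.62	Semen Strychni	0
M039	icaride A	48.74	0.43	Semen Strychni	0
M040	brucine N-oxide	52.63	0.38	Semen Strychni	0
M041	(2R)-naringenin	42.36	0.21	Semen Strychni	0
M042	brucine	7.60	0.41	Semen Strychni	1
M043	3-oxo-tirucallic acid	42.86	0.81	Boswellia	0
M044	alpha-boswellic acid	39.32	0.75	Boswellia	0
M045	boswellic acid	39.55	0.75	Boswellia	0
M046	tirucallol	42.12	0.75	Boswellia	0
M047	11-Keto-beta-boswellic acid	29.82	0.74	Boswellia	1
M048	o-acetyl-alpha-boswellic acid	42.73	0.70	Boswellia	0
M049	acetyl-alpha-boswellic acid	42.73	0.70	Boswellia	0
M050	phyllocladene	33.40	0.27	Boswellia	0
M051	incensole	45.59	0.22	Boswellia	0
M052	strictosamide_qt	76.30	0.76	Syringa Oblata	0
M053	Di (2-ethylhexyl) phthalate	43.59	0.35	Syringa Oblata	0
M054	eugenol	56.24	0.04	Syringa Oblata	1
M055	curcumin	4.37	0.41	Rhizoma Alpiniae Officinarum	1
M056	chrysin	22.61	0.18	Rhizoma Alpiniae Officinarum	1
M057	sitosterol	36.91	0.75	Rhizoma Alpiniae Officinarum	0
M058	clionasterol	36.91	0.75	Rhizoma Alpiniae Officinarum	0
M059	(2S,3R)-2-(3,4-dimethoxyphenyl)-5,7-dimethoxychroman-3-ol	51.89	0.37	Rhizoma Alpiniae Officinarum	0
M060	medicarpin	49.22	0.33	Rhizoma Alpiniae Officinarum	0
M061	butyl-2-ethylhexyl phthalate	44.52	0.22	Rhizoma Alpiniae Officinarum	0
M062	7-Methoxy-8-(2'-ethoxy-3'-hydroxy-3'-methybutyl)coumarin	40.36	0.21	Rhizoma Alpiniae Officinarum	0
M063	galangin	45.55	0.21	Rhizoma Alpiniae Officinarum	0
M064	5-methoxy-1,7-diphenyl-3-heptanone	68.29	0.20	Rhizoma Alpiniae Officinarum	0
M065	1,7-diphenyl-5-hydroxy-3-heptanone	61.90	0.18	Rhizoma Alpiniae Officinarum	0
M066	pinocembrin	46.08	0.18	Rhizoma Alpiniae Officinarum	0
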