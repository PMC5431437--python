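id	name	ob	dl	herbs	rescued
S01	methyl palmitate			Moschus	0
S02	triolein			Moschus	0
S03	methyl-9-octadecenoate			Moschus	0
S04	normuscone			Moschus	0
S05	cholest-4-ene-3-one			Moschus	0
S06	delta4-cholestenone-3			Moschus	0
S07	cholestanol			Moschus	0
S08	cholic acid			Moschus	0
S09	3alpha-hydroxyandrostan-4-en-17beta-one			Moschus	0
S10	3alpha-hydroxy-5alpha-androstan-17-one			Moschus	0
S11	hydroxymuscopyridine A			Moschus	0
S12	androstan-4,6-dien-3,17-dione			Moschus	0
S13	androst-4-en-3,17-dione			Moschus	0
S14	5beta-androstane-3,17-dione			Moschus	0
S15	5beta-androstane-3alpha,17beta-diol			Moschus	0
S16	5alpha-androstane-3beta,17alpha-diol			Moschus	0
S17	musclide A1			Moschus	0
S18	muscopyridine			Moschus	0
S19	muscone			Moschus	0
S20	hydroxymuscopyridine B			Moschus	0
S21	3beta-hydroxy-androst-5-en-17-one			Moschus	0
L01	dihydroionone			Ambra Grisea	0
L02	alpha-ambrinol			Ambra Grisea	0
L03	ambrein			Ambra Grisea	0
L04	(-)-a-Ambreinolide			Ambra Grisea	0
L05	(+)-amber aldehyde			Ambra Grisea	0
L06	(-)-Ambrox			Ambra Grisea	0
L07	gamma-homocyclogeranyl chloride			Ambra Grisea	0
L08	epicoprosterol			Ambra Grisea	0
L09	ambrein			Ambra Grisea	0
N01	dihydrotestosterone			Bullwhip	0
N02	undecanoic acid			Bullwhip	0
N03	heptadecenoic acid			Bullwhip	0
N04	caproic acid			Bullwhip	0
N05	estradiol			Bullwhip	0
N06	testosterone			Bullwhip	0
N07	cholesterol			Bullwhip,Myristicae Semena,Moschus	0
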