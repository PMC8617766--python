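OC(=O)c1ccccc1	benzoic acid
O=Cc1ccc(O)cc1	4-hydroxybenzaldehyde
Cc1cccc(O)c1O	3-methylcatechol
O[C@H]1Cc2c(O)cc(O)cc2O[C@@H]1c1ccc(O)c(O)c1	catechin
O[C@@H]1[C@H](c2ccc(O)c(O)c2)Oc2cc(O)cc(O)c2C1=O	dihydroquercetin
COc1cc(-c2oc3cc(O)cc(O)c3c(=O)c2O)ccc1O	isorhamnetin
O=c1cc(-c2ccc(O)cc2)oc2cc(OC)c(OC)c(O)c12	cirsimaritin
O=c1c(-c2ccc(O)c(O)c2)coc2cc(O)ccc12	3',4',7-trihydroxyisoflavone
COc1cc(O)c(CC=C(C)C)c2c1C(=O)C[C@@H](c1ccc(O)cc1)O2	isoxanthohumol
COc1ccc(C2COc3cc(O)ccc3C2=O)c(OC)c1OC	3'-O-methylviolanone
C[C@H]1Cc2cccc(O)c2C(=O)O1	mellein
COc1ccc(-c2cc(=O)c3c(OC)c(OC)c(OC)cc3o2)cc1OC	sinensetin
CC1OC(OCC2OC(Oc3cc(O)c4c(c3)OC(c3ccc(OC)c(O)c3)CC4=O)C(O)C(O)C2O)C(O)C(O)C1O	hesperidin
OCC1OC(Oc2c(-c3ccc(O)c(O)c3)oc3cc(O)cc(O)c3c2=O)C(O)C(O)C1O	isoquercetin
OCC1OC(c2c(O)cc3oc(-c4ccc(O)cc4)cc(=O)c3c2O)C(O)C(O)C1O	apigenin 6-C-glucoside
CC1OC(OC2C(O)C(CO)OC(Oc3cc(O)c4c(c3)OC(c3ccc(OC5OC(CO)C(O)C(O)C5O)cc3)CC4=O)C2O)C(O)C(O)C1O	naringin 4'-glucoside
OC1Cc2c(O)cc(O)cc2OC1c1cc(O)c(OC)c(OC2OC(C(=O)O)C(O)C(O)C2O)c1	4'-methylepigallocatechin 3'-O-glucuronide
OC1Cc2c(O)cc(O)cc2OC1c1ccc(OC)c(OC2OC(C(=O)O)C(O)C(O)C2O)c1	4'-O-methylepicatechin 3'-O-glucuronide
CC1OC(Oc2cc(O)c3c(=O)c(OC4OC(CO)C(O)C(O)C4O)c(-c4ccc(O)c(OC)c4)oc3c2)C(O)C(O)C1O	isorhamnetin 3-O-glucoside 7-O-rhamnoside
OCC1OC(OC(=O)/C=C/c2ccc(O)c(OC)c2)C(O)C(O)C1O	1-O-feruloyl-beta-D-glucose
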