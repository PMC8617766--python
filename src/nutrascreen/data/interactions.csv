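compound,target,raw_text
"3',4',7-trihydroxyisoflavone",amylase,"GLU233, ASP197 (H bonds), ASP300 (Pi anion)"
"3',4',7-trihydroxyisoflavone",glucosidase,"ARG400 (H bond), ASP333 (Halogen, Pi-anion, Pi sulfur), PHE147 (Pi sulfur), TYR65 (alkyl), PHE166 (Pi sigma), GLU271 (H bond)"
"3',4',7-trihydroxyisoflavone",dppiv,"TYR666 (H bond), TYR662 TYR631, PHE357 (Alkyl), SER209, GLU205, GLU206, TYR547 (H bond)"
"3',4',7-trihydroxyisoflavone",ptp1b,"CYS215, ASP181, SER216 (C-H bonds), TYR46 (C-H bond & Pi-alkyl bond), ARG221 (C-H bond & alkyl interaction), GLN262 (halogen (fluorine bond), ILE219, PHE182 (Pi alkyl), ALA217 (Pi-Alkyl and Pi-Sigma)"
"3',4',7-trihydroxyisoflavone",irs,"ASP 1083 (l H bond), MET1079 (H bond), GLU1077 (Halogen fluorine)"
3'-O-methylviolanone,amylase,GLU233 (H bond)
3'-O-methylviolanone,glucosidase,"GLY228, PHE147, PHE166, ARG400, ASP333, PHE297 (Van der Waals)"
3'-O-methylviolanone,dppiv,"TYR631, TRP659, VAL656, VAL711, ASN710, GLU205 (Van der Waal)ARG358, SER630, TYR662 (H bond) TYR547, SER209 (C-H bond)GLU206 (Pi-donor H bond), PHE357 (Pi-alkyl bond)"
3'-O-methylviolanone,ptp1b,"PHE182, ILE219, GLN262, ARG221 (Van der Waals), ALA217 (Pi donor H bond), CYS215 (Pi alkyl bond), ASP181 (Pi anion)"
3'-O-methylviolanone,irs,"GLU1077 (Conv. H bond), ASP1083 (Carbon H bond), MET1079 (Pi-alkyl bond)"
catechin,amylase,"GLU233, ASP197 (H bonds), ASP300 (Pi anion)"
catechin,glucosidase,"GLY228 (H bond), ARG400 (Pi cation), GLU271, PHE147, ASP202, HIS105 (Van der Waals)"
catechin,dppiv,"GLU205, GLU206, SER209, TYR662, SER630 (H bonds), TYR547 (Pi donor H bond)"
catechin,ptp1b,"PHE182 (Pi alkyl), SER216, CYS215, TYR46 (C-H bond), ILE219 (Alkyl and C-H bond)"
catechin,irs,"ASP1083, MET1079, GLU1077, ASP1150 (Conventional H bonds)"
cirsimaritin,amylase,"GLU233 (H bond), ASP300 (Pi anion)"
cirsimaritin,glucosidase,"HIS105, ASP202, GLY228, ARG400 (H bonds), PHE166, TYR65 (Pi-Pi stacked), PHE297 (Alkyl)"
cirsimaritin,dppiv,"GLU205, SER209, ARG358, TYR547, SER630 (H bonds), ASN710, HIS740 (C-H bond), TYR631, VAL656, TYR662, VAL711 (Alkyl bonds), GLU206 (Pi anion)"
cirsimaritin,ptp1b,"ARG221, CYS215 (H bond), (Van der Waals), ASP181 (Pi anion bond), TYR46 (Pi-Pi stacked), ALA217 (Pi alkyl bond)"
cirsimaritin,irs,"MET1079 (Conv. H bond), ASP1083 (Carbon H bond)"
dihydroquercetin,amylase,"GLU233 (H bond), ASP300 (Pi anion)"
dihydroquercetin,glucosidase,"GLY228 (H bond), PHE147, THR203, GLU271, ASP62 (Van der Waals), ASP202, ARG200, (H bond), ASP333 (Pi anion), TYR65 (Pi-Pi T shaped)"
dihydroquercetin,dppiv,"GLU206 (Pi anion), ARG358, TYR631, ASN710 (Van der Waals), GLU205, SER209, SER630, TYR662, TYR666 (H bond), TYR547 (Pi donor H bond), PHE357 (Pi-Pi T shaped)"
dihydroquercetin,ptp1b,Nil
dihydroquercetin,irs,"GLU1077, MET1079 (Conv. H bond)"
isorhamnetin,amylase,"GLU233, ASP197 (H bonds)"
isorhamnetin,glucosidase,"ASP202, GLY228, ASP333, ARG400 (H bond), TYR65, PHE147, (Pi-Pi T shaped), PHE166 (Pi sigma), HIS105 (Pi alkyl)"
isorhamnetin,dppiv,"GLU205, SER209, GLU206 (H bonds), SER630, TYR547 (Pi-donor bonds), TYR631 (Pi alkyl bond)"
isorhamnetin,ptp1b,"SER216 (Van der Waals), ARG221 (H bond), PHE182 (Pi sigma), TYR46 (Pi stacked), CYS215 (Pi-alkyl) ASP181 (Pi-anion)"
isorhamnetin,irs,"GLU1077, MET1079 (Conv. H bond), LYS1030 (alkyl)"
isoxanthohumol,amylase,"ASP300 (H bond), GLU233 (Pi anion)"
isoxanthohumol,glucosidase,"GLU271, ASP333 (Pi anion), GLY228 (Pi sigma), PHE147, ASP202 (C-H bond), PHE166 (Alkyl), PHE297 (Pi-Pi T shaped)"
isoxanthohumol,dppiv,"SER209, TYR662, TYR666 (H bonds), VAL656 (Pi alkyl), GLU206 (Pi anion), TYR547 (Pi donor), PHE357 (Pi-Pi T shaped bond)"
isoxanthohumol,ptp1b,"ASP181 (H bond), SER216 (C-H bond), ALA217, CYS215, ARG221 (alkyl), TYR46, PHE182 (Pi-Pi T shaped)"
isoxanthohumol,irs,"MET1079 (Conventional H bond), ASP1150 (Pi-sigma), ASP1083 (Carbon H bond)"
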