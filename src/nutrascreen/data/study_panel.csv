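sample_id,endpoint_id,mean,sd,n,unit,nd_flag,role,source
Kattuyanam,amylase_ic50,2.75,0.09,3,IC50 µg/mL,False,sample,table1:Kattuyanam
Kattuyanam,glucosidase_ic50,22.39,0.08,3,IC50 µg/mL,False,sample,table1:Kattuyanam
Kattuyanam,dppiv_ic50,2.18,0.08,3,IC50 µg/mL,False,sample,table1:Kattuyanam
Kattuyanam,ptp1b_ic50,31.39,0.18,3,IC50 µg/mL,False,sample,table1:Kattuyanam
Chennangi,amylase_ic50,5.71,0.07,3,IC50 µg/mL,False,sample,table1:Chennangi
Chennangi,glucosidase_ic50,18.51,0.13,3,IC50 µg/mL,False,sample,table1:Chennangi
Chennangi,dppiv_ic50,5.68,0.14,3,IC50 µg/mL,False,sample,table1:Chennangi
Chennangi,ptp1b_ic50,38.57,0.21,3,IC50 µg/mL,False,sample,table1:Chennangi
Karungkuruvai,amylase_ic50,4.28,0.11,3,IC50 µg/mL,False,sample,table1:Karungkuruvai
Karungkuruvai,glucosidase_ic50,24.62,0.12,3,IC50 µg/mL,False,sample,table1:Karungkuruvai
Karungkuruvai,dppiv_ic50,1.66,0.06,3,IC50 µg/mL,False,sample,table1:Karungkuruvai
Karungkuruvai,ptp1b_ic50,30.89,0.16,3,IC50 µg/mL,False,sample,table1:Karungkuruvai
Sona masuri,amylase_ic50,58.64,1.15,3,IC50 µg/mL,False,sample,table1:Sona masuri
Sona masuri,glucosidase_ic50,82.35,0.19,3,IC50 µg/mL,False,sample,table1:Sona masuri
Sona masuri,dppiv_ic50,72.57,1.3,3,IC50 µg/mL,False,sample,table1:Sona masuri
Sona masuri,ptp1b_ic50,ND,0.0,3,IC50 µg/mL,True,sample,table1:Sona masuri
Acarbose,amylase_ic50,2.67,0.08,3,IC50 µg/mL,False,positive_control,table1:positive control
Acarbose,glucosidase_ic50,11.24,0.12,3,IC50 µg/mL,False,positive_control,table1:positive control
Sitagliptin,dppiv_ic50,1.19,0.14,3,IC50 µg/mL,False,positive_control,table1:positive control
Sodium orthovanadate,ptp1b_ic50,28.41,0.19,3,IC50 µg/mL,False,positive_control,table1:positive control
Kattuyanam,dpph_pct,94.89,0.16,3,% inhibition,False,sample,table2:Kattuyanam
Kattuyanam,frap,118.68,0.3,3,µmol Fe2+/g,False,sample,table2:Kattuyanam
Kattuyanam,teac,24.48,0.21,3,µmol TE/g,False,sample,table2:Kattuyanam
Kattuyanam,ages_pct,68.17,0.43,3,% inhibition,False,sample,table2:Kattuyanam
Chennangi,dpph_pct,92.11,0.08,3,% inhibition,False,sample,table2:Chennangi
Chennangi,frap,99.68,0.18,3,µmol Fe2+/g,False,sample,table2:Chennangi
Chennangi,teac,7.56,0.03,3,µmol TE/g,False,sample,table2:Chennangi
Chennangi,ages_pct,55.3,0.21,3,% inhibition,False,sample,table2:Chennangi
Karungkuruvai,dpph_pct,86.31,0.21,3,% inhibition,False,sample,table2:Karungkuruvai
Karungkuruvai,frap,112.65,0.2,3,µmol Fe2+/g,False,sample,table2:Karungkuruvai
Karungkuruvai,teac,9.94,0.04,3,µmol TE/g,False,sample,table2:Karungkuruvai
Karungkuruvai,ages_pct,65.9,0.79,3,% inhibition,False,sample,table2:Karungkuruvai
Sona masuri,dpph_pct,5.21,0.08,3,% inhibition,False,sample,table2:Sona masuri
Sona masuri,frap,7.61,0.21,3,µmol Fe2+/g,False,sample,table2:Sona masuri
Sona masuri,teac,0.67,0.03,3,µmol TE/g,False,sample,table2:Sona masuri
Sona masuri,ages_pct,5.35,0.19,3,% inhibition,False,sample,table2:Sona masuri
Ascorbic acid,dpph_pct,89.16,0.11,3,% inhibition,False,positive_control,table2:positive control
Ascorbic acid,frap,123.27,0.16,3,µmol Fe2+/g,False,positive_control,table2:positive control
Butylated hydroxytoluene,teac,18.71,0.06,3,µmol TE/g,False,positive_control,table2:positive control
Aminoguanidine,ages_pct,91.21,0.81,3,% inhibition,False,positive_control,table2:positive control
Kattuyanam,tp,731.41,0.25,3,mg GAE/100 g,False,sample,table3:Kattuyanam
Kattuyanam,tf,246.13,0.19,3,mg QE/100 g,False,sample,table3:Kattuyanam
Chennangi,tp,499.01,0.22,3,mg GAE/100 g,False,sample,table3:Chennangi
Chennangi,tf,243.14,0.55,3,mg QE/100 g,False,sample,table3:Chennangi
Karungkuruvai,tp,510.96,0.41,3,mg GAE/100 g,False,sample,table3:Karungkuruvai
Karungkuruvai,tf,235.24,0.11,3,mg QE/100 g,False,sample,table3:Karungkuruvai
Sona masuri,tp,92.34,0.56,3,mg GAE/100 g,False,sample,table3:Sona masuri
Sona masuri,tf,73.88,0.75,3,mg QE/100 g,False,sample,table3:Sona masuri
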