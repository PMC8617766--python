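compound,mw,logp,hbd,hba,tpsa,wlogp,charge_class,abundance
benzoic acid,122.12,1.38,1,1,37.3,1.38,acid,100
4-hydroxybenzaldehyde,122.12,1.2,1,2,37.3,1.2,neutral,85
3-methylcatechol,124.14,1.41,2,2,40.46,1.41,neutral,95
catechin,290.27,1.55,5,6,110.38,1.55,neutral,70
dihydroquercetin,304.25,1.19,5,7,127.45,1.19,neutral,60
isorhamnetin,316.26,2.29,4,7,120.36,2.29,neutral,55
cirsimaritin,314.29,2.89,2,6,89.13,2.89,neutral,65
"3',4',7-trihydroxyisoflavone",270.24,2.58,3,5,90.9,2.58,neutral,80
isoxanthohumol,354.4,4.32,2,5,75.99,4.32,neutral,90
3'-O-methylviolanone,330.34,2.78,1,6,74.22,2.78,neutral,75
mellein,178.19,1.49,1,3,46.53,1.49,neutral,40
sinensetin,372.37,3.5,0,7,76.36,3.5,neutral,35
hesperidin,610.57,-1.16,8,15,234.29,-1.16,neutral,48
isoquercetin,464.38,-0.54,8,12,210.51,-0.54,neutral,50
apigenin 6-C-glucoside,432.38,0.09,7,10,181.05,0.09,neutral,46
naringin 4'-glucoside,742.68,-3.69,11,19,304.21,-3.69,neutral,44
4'-methylepigallocatechin 3'-O-glucuronide,496.42,-0.88,8,12,215.83,-0.88,neutral,58
4'-O-methylepicatechin 3'-O-glucuronide,480.42,-0.59,7,11,195.6,-0.59,neutral,42
isorhamnetin 3-O-glucoside 7-O-rhamnoside,624.55,-1.74,9,16,258.43,-1.74,neutral,52
1-O-feruloyl-beta-D-glucose,356.33,-1.24,5,9,145.91,-1.24,neutral,88
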