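compound,amylase,glucosidase,dppiv,ptp1b,irs
"3',4',7-trihydroxyisoflavone",−5.27,−6.84,−6.89,−7.89,−5.05
3-methylcatechol,−4.44,−5.43,−5.17,−5.14,−4.33
3'-O-methylviolanone,−7.13,−7.84,−6.95,−7.31,−7.00
4-hydroxybenzaldehyde,−4.14,−4.76,−4.30,−4.99,−4.32
benzoic acid,−4.66,−4.54,−5.00,−4.87,−3.25
catechin,−6.72,−8.67,−7.81,−7.17,−7.41
cirsimaritin,−6.41,−7.86,−9.79,−7.46,−8.00
dihydroquercetin,−7.91,−7.91,−7.43,−6.89,−7.25
isorhamnetin,−5.62,−7.89,−7.75,−7.65,−6.93
isoxanthohumol,−7.64,−9.26,−9.49,−8.72,−8.42
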