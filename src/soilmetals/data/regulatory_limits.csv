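authority,medium,parameter,low,high
WHO,tissue,Pb,0.3,0.3
WHO,tissue,Hg,0.05,0.5
WHO,tissue,Cd,0.2,0.2
WHO,tissue,Cu,73,73
WHO,tissue,Zn,100,100
USEPA,soil,Pb,300,300
USEPA,soil,Cd,70,70
USEPA,soil,Cu,250,250
USEPA,soil,Zn,300,300
DPR,soil,Pb,85,85
DPR,soil,Hg,0.3,0.3
DPR,soil,Cd,0.8,0.8
DPR,soil,Cu,36,36
DPR,soil,Zn,140,140
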