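site_id,Pb,Hg,Cd,Cu,Zn
S1,2.9,1.7,2.0,5.1,9.2
S2,3.2,1.7,2.8,7.1,8.6
S3,3.9,2.3,3.7,3.7,2.7
S4,4.3,1.8,2.5,5.2,0.8
S5,2.6,2.9,5.7,21.1,30.0
S6,3.1,3.1,4.2,12.6,20.9
S7,3.6,2.1,9.4,17.9,32.5
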