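rank,lower,upper,label
1,0,0.10,Very slight contamination
2,0.10,0.25,Slight contamination
3,0.26,0.5,Moderate contamination
4,0.51,0.75,Severe contamination
5,0.76,1.00,Very severe contamination
6,1.10,2.0,Slight pollution
7,2.1,4.0,Moderate pollution
8,4.1,9.0,Severe pollution
9,9.1,16.0,Very severe pollution
10,16.0,,Excessive pollution
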