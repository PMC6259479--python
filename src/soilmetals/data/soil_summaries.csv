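site_scope,plot_class,medium,tissue,parameter,n,mean,sd,min,max
all,test,soil,none,pH,7,4.7,0.7,3.7,5.4
all,control,soil,none,pH,7,6.6,0.2,6.4,6.9
all,test,soil,none,EC,7,1662.3,76.4,1050.0,5240.0
all,control,soil,none,EC,7,417.0,13.5,360.0,708.0
all,test,soil,none,Pb,7,73.6,12.7,56.9,93.4
all,control,soil,none,Pb,7,21.9,7.2,15.8,36.7
all,test,soil,none,Hg,7,38.4,9.8,29.6,53.1
all,control,soil,none,Hg,7,17.1,1.2,5.9,36.2
all,test,soil,none,Cd,7,20.3,1.2,9.2,44.1
all,control,soil,none,Cd,7,4.7,0.3,1.1,10.4
all,test,soil,none,Cu,7,56.1,3.7,20.1,114.0
all,control,soil,none,Cu,7,5.4,0.2,2.8,9.4
all,test,soil,none,Zn,7,47.8,4.1,2.5,104.0
all,control,soil,none,Zn,7,3.2,0.8,2.5,5.0
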