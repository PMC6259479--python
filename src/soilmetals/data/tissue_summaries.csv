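site_scope,plot_class,medium,tissue,parameter,n,mean,sd,min,max
all,test,tissue,root,pH,7,5.67,0.43,5.00,6.10
all,test,tissue,leaf,pH,7,5.56,0.40,5.10,6.00
all,test,tissue,fruit,pH,7,5.67,0.46,5.00,6.20
all,test,tissue,stem,pH,7,5.81,0.44,5.20,6.30
all,control,tissue,root,pH,7,8.09,0.18,7.80,8.30
all,control,tissue,leaf,pH,7,8.16,0.26,7.90,8.70
all,control,tissue,fruit,pH,7,8.19,0.25,7.80,8.40
all,control,tissue,stem,pH,7,8.17,0.25,7.80,8.60
all,test,tissue,root,EC,7,1386.1,389.0,868.0,2120.0
all,test,tissue,leaf,EC,7,1580.2,466.2,724.0,2123.0
all,test,tissue,fruit,EC,7,1451.4,428.8,893.0,2111.0
all,test,tissue,stem,EC,7,1401.1,433.5,853.0,2146.0
all,control,tissue,root,EC,7,357.7,106.7,43.0,570.0
all,control,tissue,leaf,EC,7,419.4,64.4,310.0,504.0
all,control,tissue,fruit,EC,7,439.7,109.7,275.0,610.0
all,control,tissue,stem,EC,7,390.3,71.5,280.0,506.0
all,test,tissue,root,Pb,7,51.4,14.1,37.50,75.10
all,test,tissue,leaf,Pb,7,43.4,19.3,21.30,80.30
all,test,tissue,fruit,Pb,7,41.8,16.6,18.40,65.20
all,test,tissue,stem,Pb,7,43.2,15.4,25.30,70.50
all,control,tissue,root,Pb,7,18.5,5.3,10.80,26.00
all,control,tissue,leaf,Pb,7,17.6,7.1,8.20,28.50
all,control,tissue,fruit,Pb,7,14.8,5.8,7.30,20.40
all,control,tissue,stem,Pb,7,14.9,4.4,8.60,19.60
all,test,tissue,root,Hg,7,26.7,11.4,3.9,36.7
all,test,tissue,leaf,Hg,7,32.0,2.3,28.3,34.8
all,test,tissue,fruit,Hg,7,30.2,5.9,19.2,38.6
all,test,tissue,stem,Hg,7,30.2,6.7,18.6,41.0
all,control,tissue,root,Hg,7,12.6,5.1,6.5,19.5
all,control,tissue,leaf,Hg,7,11.2,3.6,6.7,17.2
all,control,tissue,fruit,Hg,7,9.7,2.9,5.1,13.7
all,control,tissue,stem,Hg,7,9.7,3.1,6.5,15.1
all,test,tissue,root,Cd,7,11.1,4.9,2.3,16.5
all,test,tissue,leaf,Cd,7,12.7,2.5,9.0,17.1
all,test,tissue,fruit,Cd,7,11.9,3.6,5.5,15.0
all,test,tissue,stem,Cd,7,13.6,3.1,8.0,18.0
all,control,tissue,root,Cd,7,3.4,0.6,1.5,6.3
all,control,tissue,leaf,Cd,7,2.8,0.4,1.3,4.8
all,control,tissue,fruit,Cd,7,2.8,0.3,9.0,4.0
all,control,tissue,stem,Cd,7,2.0,0.2,1.0,3.2
all,test,tissue,root,Cu,7,37.1,2.1,18.7,73.2
all,test,tissue,leaf,Cu,7,38.3,2.2,19.0,70.4
all,test,tissue,fruit,Cu,7,40.8,2.3,17.5,79.1
all,test,tissue,stem,Cu,7,39.2,2.8,15.6,88.0
all,control,tissue,root,Cu,7,2.1,1.6,1.6,6.5
all,control,tissue,leaf,Cu,7,3.5,1.4,2.0,5.1
all,control,tissue,fruit,Cu,7,3.0,1.3,1.8,5.5
all,control,tissue,stem,Cu,7,2.9,1.2,1.5,4.9
all,test,tissue,root,Zn,7,21.5,2.0,2.6,63.0
all,test,tissue,leaf,Zn,7,19.8,1.8,2.3,57.0
all,test,tissue,fruit,Zn,7,26.4,1.9,3.1,49.0
all,test,tissue,stem,Zn,7,23.3,1.4,1.8,44.2
all,control,tissue,root,Zn,7,2.9,2.5,1.7,6.7
all,control,tissue,leaf,Zn,7,2.2,0.6,1.6,3.4
all,control,tissue,fruit,Zn,7,2.2,0.5,1.40,3.1
all,control,tissue,stem,Zn,7,2.3,0.8,1.7,4.0
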