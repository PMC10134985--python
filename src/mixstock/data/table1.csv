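haplotype,BRA,ACR,FLA,DR,STX,TRI,GUI,FWI,GHA,GAB,SAF,ES,SBR,BA,UR
Dc1.1,20,119,209,38,98,65,115,23,47,178,34,4,63,26,43
Dc1.3,0,0,0,0,0,0,0,0,11,12,0,0,8,4,8
Dc1.4,0,0,0,0,0,0,0,0,1,0,7,0,2,1,0
Dc1.7,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
Dc2.1,0,0,0,0,21,0,0,0,0,0,0,0,0,0,0
Dc3.1,15,10,10,4,4,11,28,5,0,5,0,3,2,0,2
Dc3.2,0,2,0,0,0,11,26,1,0,0,0,0,0,0,0
Dc4.1,0,0,0,0,0,0,0,0,1,2,0,1,3,0,0
Dc9.1,0,0,0,0,0,0,0,0,0,0,0,0,2,0,1
Dc13.1,1,0,0,0,0,0,0,0,1,35,0,0,14,2,4
Dc17.1,0,0,3,0,0,0,0,0,0,0,0,0,0,0,0
Dc19.1,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0
DcA5,0,0,0,0,0,0,6,0,0,0,0,0,0,0,0
DcC3,0,0,0,0,0,0,2,0,0,0,0,0,0,0,0
N,36,132,222,42,123,87,177,29,61,232,41,8,94,33,59
NFpy,50,2500,75,35,250,3000,5000,55,100,5000,50,,,,
role,rookery,rookery,rookery,rookery,rookery,rookery,rookery,rookery,rookery,rookery,rookery,foraging,foraging,foraging,foraging
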