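id,pH,conductivity,turbidity,tn_n,nh4_n,nh3_n,po4_p,cod,scod,scod_n,tss,vss,colour_index,colour_note
SM,7.7,4,NA,330,210,8,5.6,NA,78,4.2,NA,NA,NA,NA
MBBM,7.2,2.44,NA,200,200,1.8,53.2,NA,80,2.5,NA,NA,NA,NA
TW1,8.7,1.9,228,190,163,27,1.9,874,590,3.1,220,173,0.29,purple
TW2,8.4,3.23,105,181,168,16,2.0,708,472,2.6,118,103,0.174,green/cyano
TW3,8.7,2.97,92,291,170,28,2.0,794,556,1.9,115,90,0.245,green/cyano
TW4,8.6,2.8,71,243,182,27,1.9,802,587,2.4,100,77,0.232,green/cyano
TW5,8.5,2.19,60,145,139,15,1.9,696,538,3.7,97,88,0.139,green/cyano
TW6,8.3,2.64,134,169,150,12,1.6,858,532,3.1,115,85,0.182,green/cyano
TW7,8.6,2.53,79,156,155,21,2.0,862,454,2.9,90,78,0.237,green/cyano
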