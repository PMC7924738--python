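id,K,Mg,Ca,Si,Fe,Na,Zn,Mn,Mo,Al,Cr,Ni,Pb,Cu,Cd
SM,7.2,10.2,42.3,ND,2.2,ND,0.12,0.35,0.02,ND,ND,70,ND,80,ND
MBBM,88,7.4,5.4,0.23,0.05,78,0.01,0.07,0.03,ND,ND,ND,ND,4,ND
TW1,4.6,8.1,37.9,2.21,0.08,280,0.09,0.012,0.001,0.03,29.0,2.2,0.045,25.0,0.001
TW2,3.5,4.3,18.0,9.04,0.10,228,0.08,0.012,0.001,0.03,43.4,1.7,0.045,66.4,0.001
TW3,4.3,6.9,31.3,3.83,0.16,302,0.11,0.016,0.001,0.03,94.3,2.1,0.045,29.6,0.001
TW4,2.6,6.2,31.2,0.11,0.04,210,0.05,0.007,0.001,0.03,11.4,14.2,0.045,17.9,0.001
TW5,3.9,6.7,31.0,2.15,0.06,247,0.06,0.013,0.001,0.03,24.3,9.2,0.045,34.2,0.001
TW6,4.7,8.1,35.2,1.55,0.08,278,0.07,0.016,0.001,0.03,15.2,7.4,0.045,20.5,0.001
TW7,3.4,6.8,31.5,0.67,0.06,259,0.08,0.011,0.001,0.03,19.7,5.4,0.045,19.3,0.001
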