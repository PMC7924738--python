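sample_id,biomass,biomass_sd,ph_5d,ph_5d_sd,ph_10d,ph_10d_sd,ph_14d,ph_14d_sd,laccase_5d,laccase_5d_sd,laccase_10d,laccase_10d_sd,laccase_14d,laccase_14d_sd,colour_removal_5d,colour_removal_5d_sd,colour_removal_10d,colour_removal_10d_sd,colour_removal_14d,colour_removal_14d_sd
TW1,10.48,0.68,4.21,0.13,4.55,0.10,5.07,0.18,<0.5,NA,<0.5,NA,<0.5,NA,8.1,4.0,10.2,1.5,10.6,0.6
TW2,8.45,0.78,4.31,0.04,3.97,0.04,2.76,0.13,<0.5,NA,<0.5,NA,<0.5,NA,1.1,0.9,8.7,5.0,11.2,1.0
TW3,8.14,0.51,6.02,0.08,2.85,0.11,2.94,0.06,<0.5,NA,<0.5,NA,<0.5,NA,4.2,0.9,6.9,2.6,8.3,1.8
TW4,7.80,0.57,4.34,0.08,3.92,0.06,2.71,0.13,<0.5,NA,<0.5,NA,<0.5,NA,8.7,2.1,7.2,3.9,8.0,2.0
TW5,8.13,0.38,4.33,0.08,4.06,0.08,2.89,0.08,<0.5,NA,<0.5,NA,0.5,NA,1.5,1.9,3.5,0.9,4.3,0.6
TW6,7.86,0.62,4.32,0.35,3.40,0.42,3.09,0.01,<0.5,NA,<0.5,NA,<0.5,NA,1.1,1.2,6.2,0.8,1.3,0.5
TW7,8.41,0.62,4.42,0.30,3.12,0.10,3.02,0.18,<0.5,NA,<0.5,NA,0.7,NA,4.3,0.6,7.0,4.1,9.7,4.1
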