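sample_id,biomass,biomass_sd,ph_5d,ph_5d_sd,ph_10d,ph_10d_sd,ph_14d,ph_14d_sd,laccase_5d,laccase_5d_sd,laccase_10d,laccase_10d_sd,laccase_14d,laccase_14d_sd,colour_removal_5d,colour_removal_5d_sd,colour_removal_10d,colour_removal_10d_sd,colour_removal_14d,colour_removal_14d_sd
TW1,9.10,0.57,4.9,0.14,4.9,0.11,5.39,0.27,136.0,8.5,32.0,4.2,25.0,4.0,29.6,2.3,49.3,2.5,62.0,2.4
TW2,10.07,0.38,7.25,0.21,4.49,0.16,3.15,0.21,126.7,5.0,23.8,2.3,<0.5,NA,28.0,5.1,37.4,5.1,52.7,2.3
TW3,9.79,0.30,7.11,0.08,4.79,0.14,3.14,0.08,195.0,7.1,193.3,2.4,<0.5,NA,25.1,8.2,38.5,2.3,54.0,1.1
TW4,10.12,0.18,7.22,0.11,4.10,0.14,3.24,0.17,87.5,3.5,89.4,3.9,<0.5,NA,24.5,4.1,33.3,6.3,43.6,5.4
TW5,9.56,0.20,7.17,0.08,3.52,0.17,3.14,0.06,190.0,7.1,184.7,6.0,<0.5,NA,28.5,1.4,35.5,5.7,20.2,8.9
TW6,9.80,0.28,7.16,0.06,3.5,0.07,3.25,0.21,395.6,12.1,376.4,5.1,<0.5,NA,31.3,1.5,51.7,3.0,46.9,3.7
TW7,9.43,0.17,7.26,0.11,3.34,0.06,3.24,0.13,349.4,16.2,333.9,8.6,<0.5,NA,23.0,3.5,46.3,1.0,40.4,6.0
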