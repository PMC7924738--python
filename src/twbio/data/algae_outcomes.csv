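culture_id,vss_t15,eta_nh4
TW1,133,76
TW2,113,81
TW3,133,71
TW4,110,74
TW5,173,72
TW6,203,69
TW7,163,73
C,403,35
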