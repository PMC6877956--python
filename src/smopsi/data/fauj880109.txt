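H FAUJ880109
D Number of hydrogen bond donors (Fauchere et al., 1988)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.      4.      2.      1.      0.      2.      1.      0.      1.      0.
     0.      2.      0.      0.      0.      1.      1.      1.      1.      0.
//
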