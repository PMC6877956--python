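H HOPT810101
D Hydrophilicity value (Hopp-Woods, 1981)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    -0.5     3.0     0.2     3.0    -1.0     0.2     3.0     0.0    -0.5    -1.8
    -1.8     3.0    -1.3    -2.5     0.0     0.3    -0.4    -3.4    -2.3    -1.5
//
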