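bsa_low,bsa_high,dose_mg
1.2000000000,1.3625000000,1500
1.3625000000,1.5250000000,1650
1.5250000000,1.6875000000,1800
1.6875000000,1.8500000000,1950
1.8500000000,2.0125000000,2100
2.0125000000,2.1750000000,2250
2.1750000000,2.3375000000,2400
2.3375000000,2.5000000000,2550
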