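material	density_g_cm3	mu_511_cm1
Air	0.001	0
Polyethylene	0.930	0.0925
Polystyrene	1.060	0.0994
Water	1.000	0.0969
Acrylic	1.190	0.1120
Teflon	2.250	0.1886
Aluminum	2.699	0.2280
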