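# Mass attenuation coefficients, adipose tissue (ICRU-44 composition)
# Source: NIST X-ray mass attenuation coefficient tables (Hubbell & Seltzer),
# transcribed to the standard published grid; values in cm^2/g.
# columns: energy_keV	mu_over_rho_cm2_g
10	3.268
15	1.083
20	0.5577
30	0.3003
40	0.2396
50	0.2123
60	0.1974
80	0.1800
100	0.1688
150	0.1500
200	0.1368
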