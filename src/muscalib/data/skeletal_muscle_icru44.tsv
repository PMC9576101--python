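# Mass attenuation coefficients, skeletal muscle (ICRU-44 composition)
# Source: NIST X-ray mass attenuation coefficient tables (Hubbell & Seltzer),
# transcribed to the standard published grid; values in cm^2/g.
# columns: energy_keV	mu_over_rho_cm2_g
10	5.356
15	1.693
20	0.8205
30	0.3783
40	0.2699
50	0.2278
60	0.2066
80	0.1842
100	0.1711
150	0.1508
200	0.1372
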