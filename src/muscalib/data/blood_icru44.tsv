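# Mass attenuation coefficients, whole blood (ICRU-44 composition)
# Source: NIST X-ray mass attenuation coefficient tables (Hubbell & Seltzer),
# transcribed to the standard published grid; values in cm^2/g.
# columns: energy_keV	mu_over_rho_cm2_g
10	5.571
15	1.753
20	0.8428
30	0.3880
40	0.2751
50	0.2313
60	0.2093
80	0.1862
100	0.1728
150	0.1522
200	0.1384
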