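# Mass attenuation coefficients, dry air (near sea level)
# Source: NIST X-ray mass attenuation coefficient tables (Hubbell & Seltzer),
# transcribed to the standard published grid; values in cm^2/g.
# columns: energy_keV	mu_over_rho_cm2_g
10	5.120
15	1.614
20	0.7779
30	0.3538
40	0.2485
50	0.2080
60	0.1875
80	0.1662
100	0.1541
150	0.1356
200	0.1233
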