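# CSDA range of alpha particles in liquid water (unit density, 1 g/cm^3).
# Approximate compilation in the ICRU Report 90 / NIST ASTAR lineage:
# values above 1 MeV follow the published helium-ion CSDA tabulation for
# liquid water (converted from g/cm^2 to micrometres at unit density and
# rounded); rows below 1 MeV are smoothed approximations consistent with
# the Bragg-peak stopping-power plateau. Intended for cellular dosimetry
# modelling, not for metrology.
# columns: energy_MeV	csda_range_um
0.1	1.72
0.2	2.22
0.3	2.70
0.4	3.18
0.5	3.68
0.75	4.77
1.0	5.93
1.5	8.21
2.0	10.92
2.5	13.95
3.0	17.29
3.5	21.04
4.0	25.09
4.5	29.51
5.0	34.27
5.5	39.36
6.0	44.79
6.5	50.55
7.0	56.61
7.5	62.99
8.0	69.71
8.5	76.72
9.0	84.04
9.5	91.67
10.0	99.59
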