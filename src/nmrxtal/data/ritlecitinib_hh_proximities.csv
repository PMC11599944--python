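# H-H proximities (< 3.5 A) in the geometry-optimised crystal structure of
# ritlecitinib tosylate with the corresponding observed 1H DQ frequencies.
# sq1/sq2 are the single-quantum 1H shifts (ppm), dq = sq1 + sq2, and
# separations lists every contributing periodic-image distance (A),
# semicolon-separated.  The self-pair row H32/H32 is an inter-image methyl
# contact.  Intra-CH2/CH3 contacts of sites 12, 13 and 17 are not listed.
proton1,sq1,proton2,sq2,dq,separations
H13b,0.2,H14,3.3,3.5,2.49
H17,0.6,H14,3.3,3.9,2.47;2.47;3.07
H17,0.6,H16b,3.5,4.1,2.42;3.31
H12b,0.7,H16b,3.5,4.2,2.65
H13a,1.0,H14,3.3,4.3,2.36
H17,0.6,H21b,3.8,4.4,2.47;2.70
H32,2.4,H32,2.4,4.8,1.78;1.78
H12a,0.7,H11,4.3,5.0,2.50
H12b,0.7,H11,4.3,5.0,3.07
H13a,1.0,H11,4.3,5.3,2.49
H32,2.4,H11,4.3,6.7,2.97
H16b,3.5,H11,4.3,7.8,3.05
H14,3.3,H20,4.4,7.7,1.88
H32,2.4,H16a,5.3,7.7,3.21;2.80;2.64
H32,2.4,H21a,5.4,7.8,3.16
H21b,3.8,H20,4.4,8.2,2.43
H17,0.6,H26,7.6,8.2,2.77
H32,2.4,H25,6.2,8.6,2.53;3.00
H12a,0.7,H22,7.8,8.5,3.09
H13a,1.0,H22,7.8,8.8,2.93
H16b,3.5,H16a,5.3,8.8,1.77
H21b,3.8,H21a,5.4,9.2,1.87
H11,4.3,H16a,5.3,9.6,2.43
H32,2.4,H23,7.5,9.9,2.45;3.31
H32,2.4,H8,8.4,10.8,2.90;2.69
H32,2.4,H9,8.5,10.9,3.02;2.96
H26,7.6,H16b,3.5,11.1,2.70
H32,2.4,H2,9.2,11.6,2.63;3.17
H32,2.4,H10,9.2,11.6,3.20;3.34
H16b,3.5,H8,8.4,11.9,2.63
H16b,3.5,H10,9.2,12.7,2.31
H11,4.3,H10,9.2,13.5,2.95
H16a,5.3,H8,8.4,13.7,2.17
H25,6.2,H26,7.6,13.8,2.48
H21a,5.4,H8,8.4,13.8,3.43
H25,6.2,H22,7.8,14.0,2.71
H16a,5.3,H2,9.2,14.5,2.90
H16a,5.3,H10,9.2,14.5,2.71
H23,7.5,H22,7.8,15.3,2.49
H26,7.6,H22,7.8,15.4,2.71
H8,8.4,H9,8.5,16.9,2.70
H9,8.5,H10,9.2,17.7,2.56
H9,8.5,H2,9.2,17.7,3.18
H11,4.3,H1,13.6,17.9,2.13
H8,8.4,H7,12.8,21.2,2.51
H2,9.2,H1,13.6,22.8,2.25
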