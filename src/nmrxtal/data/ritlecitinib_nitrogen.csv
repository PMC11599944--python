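# Nitrogen sites of ritlecitinib tosylate: experimental 15N chemical shifts
# (ppm, CH3NO2 scale), GIPAW-calculated 15N shifts (sigma_ref = -160 ppm),
# observed 14N shifts at nu0(14N) = 43.3 MHz, experimental and calculated
# quadrupolar products (MHz).  The sign of the calculated P_Q belongs to
# V_zz; experimentally the sign is not observable.
site,d15n_exp,d15n_calc,d14n_exp,pq_exp,pq_calc
N1,-228.3,-227.2,-45,2.6,-2.2
N3,-148.8,-147.5,,,-4.0
N7,-237.1,-227.3,-40,2.5,-2.1
N10,-277.1,-278.3,278,3.8,-3.8
N15,-256.1,-249.3,,,-4.2
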