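# Intermolecular NH...O hydrogen bonds in the geometry-optimised crystal
# structure of ritlecitinib tosylate (acceptors are tosylate sulfonate
# oxygens), with the experimental and GIPAW-calculated NH 1H shifts (ppm).
donor,hydrogen,acceptor,d_DA,d_HA,angle_DHA,exp_1h,calc_1h
N10,H10,O29,2.85,1.84,166.2,9.2,9.9
N1,H1,O31,2.73,1.71,164.6,13.6,14.3
N7,H7,O31,2.78,1.74,176.0,12.8,14.7
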