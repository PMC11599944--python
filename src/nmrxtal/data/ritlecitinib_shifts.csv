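# Assigned 1H and 13C chemical shifts (ppm) of ritlecitinib tosylate:
# solution state (DMSO; solution_alt = trans-rotamer value where distinct),
# solid state (exp), and GIPAW-calculated (calc; 1H sigma_ref 31 ppm, 13C
# piecewise 172/175 ppm split at 45 ppm; methyl 1H values are the average
# over the three protons).  Diastereotopic CH2 protons are rows a/b.
site,nucleus,solution,solution_alt,exp,calc
H1,1H,13.44,,13.6,14.3
H2,1H,8.39,,9.2,9.0
H7,1H,12.67,,12.8,14.7
H8,1H,7.44,,8.4,9.1
H9,1H,6.93,,8.5,8.6
H10,1H,9.19,,9.2,9.9
H11,1H,3.97,4.00,4.3,4.6
H12a,1H,,,0.7,0.9
H12b,1H,,,0.7,0.7
H13a,1H,,,1.0,1.2
H13b,1H,,,0.2,0.2
H14,1H,4.41,4.81,3.3,3.6
H16a,1H,4.54,4.11,5.3,5.3
H16b,1H,2.80,3.14,3.5,3.9
H17,1H,1.23,1.16,0.6,0.5
H20,1H,6.85,,4.4,4.3
H21a,1H,6.12,6.12,5.4,5.4
H21b,1H,5.72,5.87,3.8,3.8
H22,1H,7.49,,7.8,8.0
H23,1H,7.12,,7.5,7.8
H25,1H,7.12,,6.2,6.1
H26,1H,7.49,,7.6,7.8
H32,1H,2.29,,2.4,2.5
C2,13C,142.7,,143.6,143.6
C4,13C,149.9,,147.9,145.8
C5,13C,101.7,,102.3,105.6
C6,13C,145.0,,149.5,148.4
C8,13C,124.4,,127.9,129.7
C9,13C,101.5,,105.6,106.6
C11,13C,48.2,48.9,51.0,51.1
C12,13C,24.7,,26.6,27.4
C13,13C,28.8,27.8,28.7,29.8
C14,13C,46.6,42.3,46.5,48.5
C16,13C,39.3,43.3,41.6,42.9
C17,13C,16.4,14.9,17.3,17.4
C18,13C,165.0,164.5,165.4,166.5
C20,13C,128.9,128.7,126.1,128.0
C21,13C,127.2,127.4,127.5,136.5
C22,13C,125.4,,124.3,124.1
C23,13C,128.0,,131.6,131.1
C24,13C,145.4,,149.6,147.8
C25,13C,128.0,,127.9,135.8
C26,13C,125.4,,125.3,125.6
C27,13C,137.6,,141.8,144.8
C32,13C,20.7,,21.3,20.0
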