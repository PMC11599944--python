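"""Physical constants and field defaults used across the package.

The EFG-to-frequency conversion turns a principal EFG component in atomic
units (E_h e^-1 a_0^-2) into a quadrupolar coupling constant in MHz via
C_Q = e Q V_zz / h.  Folding the fundamental constants together gives a
single factor in MHz per (barn x a.u.).
"""

#: e / h x (E_h / a_0^2) expressed in MHz per barn per atomic unit of EFG.
EFG_AU_TO_MHZ_PER_BARN: float = 234.9647

#: Nuclear electric quadrupole moment of 14N in barn (Pyykko 2008 compilation).
Q_14N_BARN: float = 0.02044

#: Default 14N Larmor frequency in MHz (600 MHz 1H spectrometer).
NU0_14N_MHZ: float = 43.3

#: Default reference shieldings, ppm.  13C uses a piecewise scheme: one
#: reference for shifts above 45 ppm, another below (see referencing module).
SIGMA_REF_1H: float = 31.0
SIGMA_REF_15N: float = -160.0
SIGMA_REF_13C_ABOVE: float = 172.0
SIGMA_REF_13C_BELOW: float = 175.0
SIGMA_REF_13C_THRESHOLD: float = 45.0
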