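"""Second-order quadrupolar shift arithmetic for 14N.

The observed 14N shift under MAS is the isotropic chemical shift (shared,
to a good approximation, with 15N) plus the isotropic second-order
quadrupolar shift

    delta_Q_iso = (3/40) (P_Q / nu0)^2 x 10^6   [ppm]

where P_Q = |C_Q| sqrt(1 + eta^2/3) is the quadrupolar product (MHz) and
nu0 the 14N Larmor frequency (MHz).  The shift is positive (to high
frequency) and scales as nu0^-2, so the quadrupolar contribution shrinks
at higher magnetic field.  Its sign convention here is the spin-1
single-quantum case with the printed 3/40 prefactor and no further
transition-dependent factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import NU0_14N_MHZ


@dataclass(frozen=True)
class FieldContext:
    """Magnetic-field context: 14N Larmor frequency in MHz."""

    nu0_mhz: float = NU0_14N_MHZ
    b0_label: str = "600 MHz 1H"

    def __post_init__(self):
        if self.nu0_mhz <= 0:
            raise ValueError("Larmor frequency must be positive")


@dataclass(frozen=True)
class QuadShiftResult:
    """delta_Q (ppm) and the P_Q (MHz) inverted from it; P_Q is NaN when
    delta_Q < 0, where the formula has no real solution."""

    delta_q_iso: float
    p_q: float

    @property
    def p_q_defined(self) -> bool:
        return math.isfinite(self.p_q)


def second_order_shift(p_q: float, field: FieldContext) -> float:
    """Isotropic second-order quadrupolar shift (ppm) for P_Q in MHz."""
    if p_q < 0:
        raise ValueError("P_Q is non-negative by convention")
    return (3.0 / 40.0) * (p_q / field.nu0_mhz) ** 2 * 1e6


def pq_from_shift_difference(
    delta_14n: float, delta_15n: float, field: FieldContext
) -> QuadShiftResult:
    """Invert an observed 14N/15N shift pair to (delta_Q, P_Q).

    delta_Q = delta(14N) - delta(15N); P_Q = nu0 sqrt(40 delta_Q / 3e6).
    A negative delta_Q (observed 14N below the chemical shift) cannot come
    from the second-order formula; it is returned with P_Q = NaN.
    """
    delta_q = delta_14n - delta_15n
    if delta_q < 0:
        return QuadShiftResult(delta_q, math.nan)
    p_q = field.nu0_mhz * math.sqrt(delta_q * 40.0 / 3.0e6)
    return QuadShiftResult(delta_q, p_q)


def observed_14n_shift(delta_15n: float, p_q: float, field: FieldContext) -> float:
    """Predicted 14N shift: chemical shift plus quadrupolar shift (ppm)."""
    return delta_15n + second_order_shift(p_q, field)


def round_report_ppm(value: float) -> int:
    """Report rounding for 14N-related ppm values: nearest integer ppm."""
    return int(round(value))
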