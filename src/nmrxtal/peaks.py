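"""Predicted 2D correlation peak lists from structure-derived pair lists.

Three experiment classes are modelled, all as pure functions of the pair
list, the shift table and (for HMQC) the field:

* 1H-1H DQ-SQ: a proton pair within the dipolar proximity cutoff gives
  peaks at (delta_a + delta_b, delta_a) and (delta_a + delta_b, delta_b);
  a proton close to its own periodic image gives one diagonal peak at
  (2 delta, delta).
* 1H-13C HETCOR at short contact time: one (delta_C, delta_H) cross peak
  per directly bonded C-H pair.
* 14N-1H HMQC: one (delta_14N, delta_H) peak per recoupled N-H pair, the
  14N coordinate carrying the second-order quadrupolar shift.

Intensity is represented only as a qualitative strong/weak class from the
internuclear distance; quantitative intensities depend on recoupling and
CP dynamics, which are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .geometry import ProximityPair, Site
from .quadrupolar import FieldContext, second_order_shift

#: Distance (A) at or below which a peak is classed "strong".
STRONG_CUTOFF = {"DQ": 2.6, "HETCOR": 1.2, "HMQC": 1.3}


@dataclass(frozen=True)
class Peak2D:
    """One predicted cross peak.

    f1: indirect dimension (DQ sum, 13C shift or 14N shift, ppm);
    f2: 1H SQ shift (ppm); pair: generating site labels; distance (A);
    kind in {DQ, HETCOR, HMQC}; intensity_class in {strong, weak};
    flags: e.g. 'no-quadrupolar-correction'.
    """

    f1: float
    f2: float
    pair: tuple[str, str]
    distance: float
    kind: str
    intensity_class: str = "strong"
    flags: tuple[str, ...] = ()


def _classify(kind: str, distance: float) -> str:
    return "strong" if distance <= STRONG_CUTOFF[kind] else "weak"


def _dedupe(peaks: list[Peak2D]) -> list[Peak2D]:
    """Merge peaks identical in (f1, f2, unordered pair)."""
    seen = {}
    for p in peaks:
        key = (round(p.f1, 9), round(p.f2, 9), tuple(sorted(p.pair)))
        if key not in seen:
            seen[key] = p
    return list(seen.values())


def predict_dq_sq(
    proximities: Iterable[ProximityPair],
    h_shifts: Mapping[str, float],
) -> tuple[list[Peak2D], list[str]]:
    """DQ-SQ peak list from H-H proximities and a 1H shift map.

    Returns (peaks, skipped site labels).  Hydrogens without a shift are
    collected in the skip list rather than raising: partial assignment is
    the common case.
    """
    peaks: list[Peak2D] = []
    skipped: set[str] = set()
    for pp in proximities:
        la, lb = pp.h1.label, pp.h2.label
        missing = [l for l in (la, lb) if l not in h_shifts]
        if missing:
            skipped.update(missing)
            continue
        da, db = h_shifts[la], h_shifts[lb]
        dq = da + db
        cls = _classify("DQ", pp.min_distance)
        if la == lb:
            peaks.append(Peak2D(dq, da, (la, lb), pp.min_distance, "DQ", cls))
        else:
            peaks.append(Peak2D(dq, da, (la, lb), pp.min_distance, "DQ", cls))
            peaks.append(Peak2D(dq, db, (la, lb), pp.min_distance, "DQ", cls))
    return _dedupe(peaks), sorted(skipped)


def predict_hetcor(
    ch_pairs: Iterable[tuple[Site, Site, float]],
    c_shifts: Mapping[str, float],
    h_shifts: Mapping[str, float],
) -> tuple[list[Peak2D], list[str]]:
    """HETCOR peaks from (C site, H site, distance) bonded pairs."""
    peaks: list[Peak2D] = []
    skipped: set[str] = set()
    for c, h, dist in ch_pairs:
        if c.label not in c_shifts or h.label not in h_shifts:
            skipped.update(l for l, m in ((c.label, c_shifts), (h.label, h_shifts))
                           if l not in m)
            continue
        peaks.append(Peak2D(c_shifts[c.label], h_shifts[h.label],
                            (c.label, h.label), dist, "HETCOR",
                            _classify("HETCOR", dist)))
    return _dedupe(peaks), sorted(skipped)


def predict_hmqc(
    nh_pairs: Iterable[tuple[Site, Site, float]],
    n15_shifts: Mapping[str, float],
    h_shifts: Mapping[str, float],
    p_q: Mapping[str, float],
    field: FieldContext,
) -> tuple[list[Peak2D], list[str]]:
    """14N-1H HMQC peaks from (N site, H site, distance) pairs.

    f1 = delta(15N-equivalent) + second-order quadrupolar shift from the
    site's P_Q.  A nitrogen lacking a P_Q entry still produces a peak at
    the bare chemical shift, flagged 'no-quadrupolar-correction'.
    """
    peaks: list[Peak2D] = []
    skipped: set[str] = set()
    for n, h, dist in nh_pairs:
        if n.label not in n15_shifts or h.label not in h_shifts:
            skipped.update(l for l, m in ((n.label, n15_shifts), (h.label, h_shifts))
                           if l not in m)
            continue
        flags: tuple[str, ...] = ()
        f1 = n15_shifts[n.label]
        if n.label in p_q:
            f1 += second_order_shift(p_q[n.label], field)
        else:
            flags = ("no-quadrupolar-correction",)
        peaks.append(Peak2D(f1, h_shifts[h.label], (n.label, h.label), dist,
                            "HMQC", _classify("HMQC", dist), flags))
    return _dedupe(peaks), sorted(skipped)


def peaks_to_text(peaks: Iterable[Peak2D]) -> str:
    """Delimited-text peak list (tab-separated, deterministic order)."""
    header = "kind\tf1_ppm\tf2_ppm\tsite1\tsite2\tdistance_A\tclass\tflags"
    rows = [header]
    for p in sorted(peaks, key=lambda p: (p.kind, p.f1, p.f2, p.pair)):
        rows.append(f"{p.kind}\t{p.f1:.4f}\t{p.f2:.4f}\t{p.pair[0]}\t{p.pair[1]}"
                    f"\t{p.distance:.4f}\t{p.intensity_class}\t{','.join(p.flags)}")
    return "\n".join(rows) + "\n"
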