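"""Shielding-to-shift referencing and shift tables.

A calculated isotropic shielding sigma_iso becomes a calculated chemical
shift through a reference shielding: delta_iso = sigma_ref - sigma_iso.
sigma_ref may be a single per-nucleus constant, fitted to experiment, or
— for 13C — a piecewise scheme using one reference above a shift
threshold and another below it, which compensates the slope != -1 of the
shielding/shift correlation across the aliphatic/aromatic divide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import constants
from .errors import ConfigurationError, DegenerateFitError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SingleReference:
    sigma_ref: float


@dataclass(frozen=True)
class PiecewiseReference:
    """Two references split at a shift threshold (ppm).

    ``sigma_ref_above`` applies to shifts at or above the threshold,
    ``sigma_ref_below`` to shifts below it.  Classification uses the
    first-pass shift computed with ``sigma_ref_above``.
    """

    sigma_ref_above: float
    sigma_ref_below: float
    threshold: float


@dataclass
class ReferencingScheme:
    """Per-nucleus referencing rules, e.g. {'1H': SingleReference(31.0)}."""

    entries: dict[str, SingleReference | PiecewiseReference]

    @classmethod
    def default(cls) -> "ReferencingScheme":
        """1H 31 ppm, 15N -160 ppm, 13C piecewise 172/175 ppm split at 45 ppm."""
        return cls({
            "1H": SingleReference(constants.SIGMA_REF_1H),
            "15N": SingleReference(constants.SIGMA_REF_15N),
            "13C": PiecewiseReference(constants.SIGMA_REF_13C_ABOVE,
                                      constants.SIGMA_REF_13C_BELOW,
                                      constants.SIGMA_REF_13C_THRESHOLD),
        })


def apply_reference(sigma_iso: float, nucleus: str, scheme: ReferencingScheme) -> float:
    """delta_iso = sigma_ref - sigma_iso, with piecewise 13C handling.

    Piecewise rule: compute a first-pass shift with the above-threshold
    reference; if it falls below the threshold, recompute with the
    below-threshold reference.  A first-pass shift within the inter-
    reference gap of the threshold is logged as classification-ambiguous.
    """
    entry = scheme.entries.get(nucleus)
    if entry is None:
        raise ConfigurationError(f"no reference shielding configured for {nucleus!r}")
    if isinstance(entry, SingleReference):
        return entry.sigma_ref - sigma_iso
    first_pass = entry.sigma_ref_above - sigma_iso
    band = abs(entry.sigma_ref_above - entry.sigma_ref_below)
    if abs(first_pass - entry.threshold) <= band:
        logger.warning("shift %.2f ppm lies within %.1f ppm of the %g ppm "
                       "reference threshold; classification is ambiguous",
                       first_pass, band, entry.threshold)
    if first_pass < entry.threshold:
        return entry.sigma_ref_below - sigma_iso
    return first_pass


def fit_reference(pairs: Iterable[tuple[float, float]]) -> float:
    """Least-squares sigma_ref from (sigma_calc, delta_exp) pairs.

    sigma_ref = mean(delta_exp + sigma_calc) is the closed-form minimiser
    of the RMSD between delta_exp and sigma_ref - sigma_calc.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise DegenerateFitError("fit_reference needs at least one pair")
    return float(np.mean(arr[:, 0] + arr[:, 1]))


def average_equivalent(
    shifts: Mapping[str, float], groups: Mapping[str, str] | None = None
) -> dict[str, float]:
    """Average shifts over groups of equivalent sites (e.g. methyl protons).

    ``groups`` maps site label -> group id; grouped sites are replaced by a
    single entry keyed by the group id carrying the arithmetic mean, while
    ungrouped sites pass through unchanged.
    """
    if not groups:
        return dict(shifts)
    out: dict[str, float] = {}
    acc: dict[str, list[float]] = {}
    for site, value in shifts.items():
        gid = groups.get(site)
        if gid is None:
            out[site] = value
        else:
            acc.setdefault(gid, []).append(value)
    for gid, values in acc.items():
        out[gid] = float(np.mean(values))
    return out


def regression_slope(pairs: Iterable[tuple[float, float]]) -> tuple[float, float]:
    """OLS of delta_exp on sigma_calc -> (slope, intercept).

    The slope of experimental shift against calculated shielding is
    conventionally close to, but not exactly, -1.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.shape[0] < 2:
        raise DegenerateFitError("regression needs at least two pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) < 1e-12:
        raise DegenerateFitError("constant abscissa: slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


_SHIFT_COLUMNS = ("exp", "calc", "solution", "solution_alt")


@dataclass
class ShiftTable:
    """Per-site, per-nucleus shifts (ppm) backed by a pandas DataFrame.

    Columns: site, nucleus, exp, calc, solution, solution_alt, group.
    (site, nucleus) pairs are unique; every row carries at least one shift.
    """

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.copy()
        for col in ("site", "nucleus"):
            if col not in df.columns:
                raise ValueError(f"shift table needs a {col!r} column")
        for col in _SHIFT_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
            df[col] = pd.to_numeric(df[col], errors="coerce")
        if "group" not in df.columns:
            df["group"] = None
        if df.duplicated(["site", "nucleus"]).any():
            dup = df[df.duplicated(["site", "nucleus"])][["site", "nucleus"]]
            raise ValueError(f"duplicate (site, nucleus) rows: {dup.values.tolist()}")
        if df[list(_SHIFT_COLUMNS)].isna().all(axis=1).any():
            raise ValueError("every row must carry at least one shift value")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path_or_buf) -> "ShiftTable":
        return cls(pd.read_csv(path_or_buf, comment="#"))

    def to_csv(self, path_or_buf=None):
        return self.df.to_csv(path_or_buf, index=False)

    def column_map(self, nucleus: str, column: str = "calc") -> dict[str, float]:
        """site label -> shift for one nucleus/column, NaNs dropped."""
        sub = self.df[self.df["nucleus"] == nucleus]
        return {r.site: float(getattr(r, column)) for r in sub.itertuples()
                if np.isfinite(getattr(r, column))}

    def sites(self, nucleus: str | None = None) -> Sequence[str]:
        df = self.df if nucleus is None else self.df[self.df["nucleus"] == nucleus]
        return list(df["site"])
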