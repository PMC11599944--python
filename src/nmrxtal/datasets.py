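"""Packaged reference tables for the two worked examples.

Case 1 is the tosylate salt of ritlecitinib, a JAK3-inhibitor API:
assigned 1H/13C/15N/14N shifts, NH...O hydrogen-bond geometries and the
H-H proximity list of its geometry-optimised crystal structure.  Case 2
is the cellulose Ialpha/Ibeta polymorph pair: 13C shifts from three
periodic DFT calculations (PBE unconverged-geometry, PBE converged,
rSCAN) against experiment.

All tables are small CSV files shipped with the package; loaders return
pandas objects or :class:`~nmrxtal.referencing.ShiftTable` instances.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .referencing import ShiftTable

#: Fitted reference shieldings (ppm) per cellulose calculation column.
CELLULOSE_SIGMA_REF = {
    ("Ialpha", "pbe_nc"): 168.1,
    ("Ialpha", "pbe_conv"): 168.1,
    ("Ialpha", "rscan"): 178.5,
    ("Ibeta", "pbe_nc"): 168.1,
    ("Ibeta", "pbe_conv"): 168.7,
    ("Ibeta", "rscan"): 178.0,
}

#: Experimental shift-table 13C threshold (ppm) separating aliphatic sites.
ALIPHATIC_13C_MAX = 55.0


def _read(name: str) -> pd.DataFrame:
    with resources.files("nmrxtal.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


def ritlecitinib_shifts() -> ShiftTable:
    """Assigned 1H/13C shifts: solution, solid-state and calculated columns."""
    return ShiftTable(_read("ritlecitinib_shifts.csv"))


def ritlecitinib_nitrogen() -> pd.DataFrame:
    """15N/14N shifts and quadrupolar products of the five nitrogen sites."""
    return _read("ritlecitinib_nitrogen.csv")


def ritlecitinib_hbonds() -> pd.DataFrame:
    """NH...O hydrogen-bond geometries with NH 1H shifts."""
    return _read("ritlecitinib_hbonds.csv")


def ritlecitinib_hh_proximities() -> pd.DataFrame:
    """H-H proximities (<3.5 A) with SQ/DQ shifts; separations split to lists."""
    df = _read("ritlecitinib_hh_proximities.csv")
    df["separations"] = df["separations"].apply(
        lambda s: [float(x) for x in str(s).split(";")])
    return df


def cellulose_13c() -> pd.DataFrame:
    """Cellulose polymorph 13C shifts: three calculations vs experiment."""
    return _read("cellulose_13c.csv")


def parent_carbon(h_label: str) -> str:
    """Carbon label a proton is attached to: 'H16b' -> 'C16'.

    NH protons (labels whose number matches a nitrogen, e.g. H1, H7, H10
    in the API) also map through this; callers filter on the carbon's
    presence in the 13C table.
    """
    core = h_label.lstrip("H").rstrip("ab")
    return f"C{core}"


def aliphatic_carbons(table: ShiftTable, threshold: float = ALIPHATIC_13C_MAX) -> list[str]:
    """13C sites with experimental solid-state shift below the threshold."""
    exp = table.column_map("13C", "exp")
    return sorted(s for s, v in exp.items() if v < threshold)


def aliphatic_protons(table: ShiftTable, threshold: float = ALIPHATIC_13C_MAX) -> list[str]:
    """1H sites attached to an aliphatic carbon (via label correspondence)."""
    aliph = set(aliphatic_carbons(table, threshold))
    return sorted(h for h in table.sites("1H") if parent_carbon(h) in aliph)
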