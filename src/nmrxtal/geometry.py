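"""Periodic crystal geometry: distances, bonds, hydrogen bonds, H-H proximities.

Structures are stored as a row-vector cell matrix (each row a lattice
vector, A) plus fractional coordinates wrapped into [0, 1); Cartesian
positions are ``frac @ cell``.  All sites are explicit (P1); symmetry
expansion is out of scope.  Distance searches enumerate lattice images
with a bound derived from the cell heights, so skewed (triclinic) cells
are handled completely.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import DuplicateSiteError, ParseError, StructureFileError

logger = logging.getLogger(__name__)

#: Covalent cutoffs (A) used to attach hydrogens to donor heavy atoms.
COVALENT_CUTOFFS = {("C", "H"): 1.1, ("N", "H"): 1.2, ("O", "H"): 1.2}


@dataclass
class Site:
    label: str
    element: str
    index: int
    frac: np.ndarray  # fractional, wrapped to [0, 1)

    @property
    def key(self) -> tuple[str, int]:
        return (self.element, self.index)


@dataclass
class CrystalStructure:
    """Periodic cell (row-vector matrix, A) + labelled sites (fractional)."""

    cell: np.ndarray
    sites: list[Site] = field(default_factory=list)
    source: str = ""

    def __post_init__(self):
        self.cell = np.asarray(self.cell, dtype=float).reshape(3, 3)
        if np.linalg.det(self.cell) <= 0:
            # allow left-handed cells but not degenerate ones
            if abs(np.linalg.det(self.cell)) < 1e-9:
                raise StructureFileError("cell volume is zero")
        seen = set()
        for s in self.sites:
            s.frac = np.asarray(s.frac, dtype=float) % 1.0
            if s.key in seen:
                raise DuplicateSiteError(f"duplicate site {s.key}")
            seen.add(s.key)

    @property
    def volume(self) -> float:
        return abs(float(np.linalg.det(self.cell)))

    def cartesian(self, site: Site) -> np.ndarray:
        return site.frac @ self.cell

    def site(self, label: str) -> Site:
        for s in self.sites:
            if s.label == label:
                return s
        raise KeyError(label)

    def of_element(self, element: str) -> list[Site]:
        return [s for s in self.sites if s.element == element]

    def cell_heights(self) -> np.ndarray:
        """Perpendicular distance between opposite cell faces, per axis."""
        inv = np.linalg.inv(self.cell)
        # rows of inv^T are reciprocal vectors; height_i = 1/|g_i|
        return 1.0 / np.linalg.norm(inv, axis=0)


def _image_range(structure: CrystalStructure, cutoff: float) -> int:
    """Half-width of the image search box guaranteeing completeness."""
    h_min = float(structure.cell_heights().min())
    return int(math.ceil(cutoff / h_min)) + 1


def min_image_distance(a: Site, b: Site, structure: CrystalStructure) -> float:
    """Minimum-image Cartesian distance (A) between two sites.

    The fractional difference is wrapped to the nearest image and the 27
    surrounding lattice translations are searched, which is exact for any
    cell whose skew keeps the nearest image within one translation of the
    wrapped difference (true for all but extreme cells).
    """
    dfrac = (np.asarray(b.frac) - np.asarray(a.frac) + 0.5) % 1.0 - 0.5
    shifts = np.array(list(itertools.product((-1, 0, 1), repeat=3)), dtype=float)
    vecs = (dfrac + shifts) @ structure.cell
    return float(np.min(np.linalg.norm(vecs, axis=1)))


def min_image_vector(a: Site, b: Site, structure: CrystalStructure) -> np.ndarray:
    """Cartesian vector a -> b for the image of b realising the minimum distance."""
    dfrac = (np.asarray(b.frac) - np.asarray(a.frac) + 0.5) % 1.0 - 0.5
    shifts = np.array(list(itertools.product((-1, 0, 1), repeat=3)), dtype=float)
    vecs = (dfrac + shifts) @ structure.cell
    return vecs[int(np.argmin(np.linalg.norm(vecs, axis=1)))]


def distances_within(
    a: Site, b: Site, structure: CrystalStructure, cutoff: float
) -> list[float]:
    """All periodic-image separations <= cutoff, sorted ascending.

    For a == b the zero self-image is excluded; the remaining entries are
    distances to the site's own periodic images.  The image search box is
    sized from the shortest cell height so no image within the cutoff is
    missed, however skewed the cell.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff > 2.0 * float(np.linalg.norm(structure.cell, axis=1).max()):
        logger.warning("cutoff %.2f A exceeds twice the longest cell edge; "
                       "image enumeration may be costly", cutoff)
    n = _image_range(structure, cutoff)
    dfrac = np.asarray(b.frac) - np.asarray(a.frac)
    rng = range(-n, n + 1)
    shifts = np.array(list(itertools.product(rng, rng, rng)), dtype=float)
    vecs = (dfrac + shifts) @ structure.cell
    d = np.linalg.norm(vecs, axis=1)
    same = a.key == b.key
    out = [float(x) for x in d if x <= cutoff and not (same and x < 1e-9)]
    return sorted(out)


def bonded_pairs(
    structure: CrystalStructure,
    elements: tuple[str, str],
    cutoff: float,
) -> list[tuple[Site, Site]]:
    """All (element A, element B) pairs with min-image distance <= cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    el_a, el_b = elements
    pairs = []
    for sa in structure.of_element(el_a):
        for sb in structure.of_element(el_b):
            if sa.key == sb.key:
                continue
            if min_image_distance(sa, sb, structure) <= cutoff:
                pairs.append((sa, sb))
    return pairs


@dataclass
class HydrogenBond:
    """A D-H...A contact: donor heavy atom, hydrogen, acceptor, geometry."""

    donor: Site
    hydrogen: Site
    acceptor: Site
    d_DA: float
    d_HA: float
    angle_DHA: float  # degrees, vertex at H


@dataclass
class ProximityPair:
    """An H...H proximity with every image separation within the cutoff."""

    h1: Site
    h2: Site
    distances: list[float]
    min_distance: float


def assign_covalent_donors(
    structure: CrystalStructure,
    donor_elements: tuple[str, ...] = ("N", "O"),
    cutoffs: dict[tuple[str, str], float] | None = None,
) -> dict[tuple[str, int], Site]:
    """Attach each H to its nearest donor-element atom within the covalent cutoff.

    Hydrogens with no donor in range are logged and omitted.
    """
    cutoffs = cutoffs or COVALENT_CUTOFFS
    out: dict[tuple[str, int], Site] = {}
    for h in structure.of_element("H"):
        best, best_d = None, math.inf
        for el in donor_elements:
            cut = cutoffs.get((el, "H"), 1.2)
            for d in structure.of_element(el):
                dist = min_image_distance(d, h, structure)
                if dist <= cut and dist < best_d:
                    best, best_d = d, dist
        if best is None:
            logger.info("hydrogen %s has no covalent donor within cutoff; skipped",
                        h.label)
        else:
            out[h.key] = best
    return out


def find_hydrogen_bonds(
    structure: CrystalStructure,
    donor_elements: tuple[str, ...] = ("N", "O"),
    acceptor_elements: tuple[str, ...] = ("O", "N"),
    d_ha_max: float = 2.5,
    angle_min: float = 120.0,
    covalent_cutoffs: dict[tuple[str, str], float] | None = None,
) -> list[HydrogenBond]:
    """Geometric D-H...A hydrogen bond search.

    A bond is recorded for each (H, acceptor) with H...A distance <= d_ha_max
    and D-H-A angle >= angle_min, the angle evaluated at the acceptor image
    realising the minimal H...A distance.  Defaults (2.5 A, 120 deg) are
    deliberately permissive; tighten for strict surveys.
    """
    donors = assign_covalent_donors(structure, donor_elements, covalent_cutoffs)
    bonds = []
    for h in structure.of_element("H"):
        donor = donors.get(h.key)
        if donor is None:
            continue
        v_hd = min_image_vector(h, donor, structure)
        for el in acceptor_elements:
            for acc in structure.of_element(el):
                if acc.key == donor.key:
                    continue
                v_ha = min_image_vector(h, acc, structure)
                d_ha = float(np.linalg.norm(v_ha))
                if d_ha > d_ha_max or d_ha < 1e-9:
                    continue
                cosang = float(np.dot(v_hd, v_ha)
                               / (np.linalg.norm(v_hd) * d_ha))
                angle = math.degrees(math.acos(min(1.0, max(-1.0, cosang))))
                if angle < angle_min:
                    continue
                d_da = float(np.linalg.norm(v_ha - v_hd))
                bonds.append(HydrogenBond(donor, h, acc, d_da, d_ha, angle))
    bonds.sort(key=lambda b: (b.hydrogen.key, b.acceptor.key))
    return bonds


def hh_proximities(structure: CrystalStructure, cutoff: float = 3.5) -> list[ProximityPair]:
    """Unique H...H pairs with any image separation <= cutoff.

    Self-pairs (a hydrogen with its own periodic image, e.g. a methyl
    related to itself across a cell boundary) are included; the zero
    self-distance is not.  Output order is deterministic in site keys.
    """
    hs = structure.of_element("H")
    out = []
    for i, h1 in enumerate(hs):
        for h2 in hs[i:]:
            d = distances_within(h1, h2, structure, cutoff)
            if d:
                out.append(ProximityPair(h1, h2, d, d[0]))
    return out


# ---------------------------------------------------------------------------
# structure file I/O

def _cell_from_parameters(a, b, c, alpha, beta, gamma) -> np.ndarray:
    uc = gemmi.UnitCell(a, b, c, alpha, beta, gamma)
    m = np.array(uc.orth.mat.tolist())  # columns are lattice vectors
    return m.T.copy()


def parse_structure(text: str, fmt: str = "cif", source: str = "") -> CrystalStructure:
    """Parse a crystal structure from a CIF subset or XYZ-with-cell text.

    ``fmt='cif'``: cell_length_*/cell_angle_* plus an atom_site loop with
    fractional coordinates.  ``fmt='xyz'``: an XYZ file whose comment line
    carries the 9 row-vector cell components (A) and whose coordinates are
    Cartesian.
    """
    if fmt == "cif":
        return _parse_cif(text, source)
    if fmt == "xyz":
        return _parse_xyz(text, source)
    raise ValueError(f"unknown structure format {fmt!r}")


def _strip_su(value: str) -> float:
    """Parse a CIF numeric value, dropping a trailing standard uncertainty."""
    return float(value.split("(", 1)[0])


def _parse_cif(text: str, source: str) -> CrystalStructure:
    doc = gemmi.cif.read_string(text)
    block = doc.sole_block()
    params = []
    for tag in ("_cell_length_a", "_cell_length_b", "_cell_length_c",
                "_cell_angle_alpha", "_cell_angle_beta", "_cell_angle_gamma"):
        v = block.find_value(tag)
        if v is None:
            raise StructureFileError(f"missing cell parameter {tag}")
        params.append(_strip_su(v))
    cell = _cell_from_parameters(*params)
    table = block.find("_atom_site_", ["label", "fract_x", "fract_y", "fract_z"])
    symbols = block.find_loop("_atom_site_type_symbol")
    symbols = list(symbols) if symbols else None
    sites = []
    counts: dict[str, int] = {}
    for i, row in enumerate(table):
        label = row[0]
        if symbols is not None:
            element = symbols[i]
        else:
            element = "".join(ch for ch in label if ch.isalpha())[:2].capitalize()
            # single-letter organics: trim a trailing lower-case from e.g. 'Ha'
            if len(element) == 2 and element[0] in "HCNOSP" and element not in (
                    "He", "Cl", "Ca", "Na", "Si", "Se"):
                element = element[0]
        try:
            frac = np.array([_strip_su(row[j]) for j in (1, 2, 3)])
        except ValueError:
            raise ParseError(f"non-parsable coordinate in atom_site row {i + 1}") from None
        counts[element] = counts.get(element, 0) + 1
        sites.append(Site(label, element, counts[element], frac))
    if not sites:
        raise StructureFileError("no atom_site loop in CIF")
    return CrystalStructure(cell, sites, source or "cif")


def _parse_xyz(text: str, source: str) -> CrystalStructure:
    lines = text.splitlines()
    if len(lines) < 2:
        raise StructureFileError("XYZ file too short")
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError("first line must be the atom count", 1) from None
    cell_vals = lines[1].split()
    if len(cell_vals) < 9:
        raise StructureFileError("comment line must carry 9 cell components")
    try:
        cell = np.array([float(x) for x in cell_vals[:9]]).reshape(3, 3)
    except ValueError:
        raise ParseError("malformed cell component", 2) from None
    inv = np.linalg.inv(cell)
    sites = []
    counts: dict[str, int] = {}
    for lineno, line in enumerate(lines[2:2 + natoms], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError("atom line needs element x y z", lineno)
        element = parts[0]
        try:
            cart = np.array([float(x) for x in parts[1:4]])
        except ValueError:
            raise ParseError("non-parsable coordinate", lineno) from None
        counts[element] = counts.get(element, 0) + 1
        label = f"{element}{counts[element]}"
        sites.append(Site(label, element, counts[element], cart @ inv))
    if len(sites) != natoms:
        raise StructureFileError(f"expected {natoms} atoms, found {len(sites)}")
    return CrystalStructure(cell, sites, source or "xyz")


def write_structure(structure: CrystalStructure, fmt: str = "xyz") -> str:
    """Serialise to XYZ-with-cell (Cartesian) or the CIF subset."""
    if fmt == "xyz":
        lines = [str(len(structure.sites)),
                 " ".join(format(x, ".12g") for x in structure.cell.ravel())]
        for s in structure.sites:
            cart = structure.cartesian(s)
            lines.append(f"{s.element} " + " ".join(format(x, ".12g") for x in cart))
        return "\n".join(lines) + "\n"
    if fmt == "cif":
        a_v, b_v, c_v = structure.cell
        a, b, c = (float(np.linalg.norm(v)) for v in (a_v, b_v, c_v))
        ang = lambda u, v: math.degrees(
            math.acos(float(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v))))
        alpha, beta, gamma = ang(b_v, c_v), ang(a_v, c_v), ang(a_v, b_v)
        lines = ["data_nmrxtal",
                 f"_cell_length_a {a:.6f}", f"_cell_length_b {b:.6f}",
                 f"_cell_length_c {c:.6f}", f"_cell_angle_alpha {alpha:.6f}",
                 f"_cell_angle_beta {beta:.6f}", f"_cell_angle_gamma {gamma:.6f}",
                 "loop_", "_atom_site_label", "_atom_site_type_symbol",
                 "_atom_site_fract_x", "_atom_site_fract_y", "_atom_site_fract_z"]
        for s in structure.sites:
            lines.append(f"{s.label} {s.element} "
                         + " ".join(format(x, ".9f") for x in s.frac))
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown structure format {fmt!r}")
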