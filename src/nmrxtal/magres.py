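"""Reading and writing .magres tensor files and scalar NMR observables.

The .magres text format (v1.0 block layout) carries, per atom, the magnetic
shielding tensor ("ms", ppm) and the electric field gradient tensor ("efg",
atomic units) produced by a periodic DFT calculation, together with the
lattice and atomic positions.  This module parses those blocks into a
:class:`MagresDataset` and reduces the 3x3 tensors to the scalars the rest
of the pipeline consumes: the isotropic shielding sigma_iso = tr(sigma)/3
and the quadrupolar parameters (C_Q, eta, P_Q) of quadrupolar nuclei.

Sites are identified by (label, index) pairs throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .constants import EFG_AU_TO_MHZ_PER_BARN, Q_14N_BARN
from .errors import (
    ConsistencyError,
    DuplicateSiteError,
    NotAnEFGError,
    ParseError,
    StructureFileError,
)

SiteKey = tuple[str, int]

_ALLOWED_UNITS = {
    "lattice": {"angstrom"},
    "atom": {"angstrom"},
    "ms": {"ppm"},
    "efg": {"au", "atomic"},
}


@dataclass
class MagresAtom:
    """One atom: element species, site label, 1-based index, Cartesian position (A)."""

    species: str
    label: str
    index: int
    position: np.ndarray

    @property
    def key(self) -> SiteKey:
        return (self.label, self.index)


@dataclass
class MagresDataset:
    """Parsed contents of a .magres file.

    ``ms_tensors`` and ``efg_tensors`` hold the raw 3x3 tensors exactly as
    read; symmetrisation for eigen-analysis happens at the point of use.
    """

    atoms: list[MagresAtom] = field(default_factory=list)
    lattice: np.ndarray | None = None  # 3x3 row vectors, Angstrom
    ms_tensors: dict[SiteKey, np.ndarray] = field(default_factory=dict)
    efg_tensors: dict[SiteKey, np.ndarray] = field(default_factory=dict)
    units_declared: dict[str, str] = field(default_factory=dict)

    def site_keys(self) -> list[SiteKey]:
        return [a.key for a in self.atoms]

    def atom(self, key: SiteKey) -> MagresAtom:
        for a in self.atoms:
            if a.key == key:
                return a
        raise KeyError(key)

    def validate(self, efg_trace_tol: float = 1e-6) -> None:
        """Enforce dataset invariants; raise on violation."""
        keys = set()
        for a in self.atoms:
            if a.key in keys:
                raise DuplicateSiteError(f"duplicate site {a.key}")
            keys.add(a.key)
        for name, tensors in (("ms", self.ms_tensors), ("efg", self.efg_tensors)):
            for k in tensors:
                if k not in keys:
                    raise ConsistencyError(f"{name} tensor for unknown site {k}")
        if self.lattice is not None and abs(np.linalg.det(self.lattice)) < 1e-12:
            raise StructureFileError("lattice matrix is singular")
        for k, t in self.efg_tensors.items():
            sym = 0.5 * (t + t.T)
            if abs(np.trace(sym)) > efg_trace_tol:
                raise NotAnEFGError(
                    f"EFG tensor for site {k} has trace {np.trace(sym):.3g} a.u."
                )

    def equals(self, other: "MagresDataset", tol: float = 1e-12) -> bool:
        """Field-level equality, tensors compared to ``tol``.

        Atom order is not significant (the writer canonicalises it)."""
        mine = sorted(self.atoms, key=lambda a: a.key)
        theirs = sorted(other.atoms, key=lambda a: a.key)
        if [a.key for a in mine] != [a.key for a in theirs]:
            return False
        for a, b in zip(mine, theirs):
            if a.species != b.species or not np.allclose(a.position, b.position, atol=tol):
                return False
        if (self.lattice is None) != (other.lattice is None):
            return False
        if self.lattice is not None and not np.allclose(self.lattice, other.lattice, atol=tol):
            return False
        for mine, theirs in ((self.ms_tensors, other.ms_tensors),
                             (self.efg_tensors, other.efg_tensors)):
            if set(mine) != set(theirs):
                return False
            if any(not np.allclose(mine[k], theirs[k], atol=tol) for k in mine):
                return False
        return True


@dataclass
class QuadrupolarParams:
    """Quadrupolar parameters of one site.

    C_Q = e Q V_zz / h (signed, MHz); eta = (V_xx - V_yy)/V_zz in [0, 1];
    P_Q = |C_Q| sqrt(1 + eta^2/3) >= |C_Q| (the sign experiment cannot see
    lives in C_Q / V_zz, not in P_Q).  Principal values obey the EFG
    ordering convention |V_zz| >= |V_yy| >= |V_xx|.
    """

    site: SiteKey
    C_Q: float
    eta: float
    P_Q: float
    V_eigen: tuple[float, float, float]  # (V_xx, V_yy, V_zz), a.u.


def _parse_floats(parts: list[str], lineno: int) -> list[float]:
    out = []
    for p in parts:
        try:
            out.append(float(p))
        except ValueError:
            raise ParseError(f"malformed numeric field {p!r}", lineno) from None
    return out


def parse_magres(source) -> MagresDataset:
    """Parse a .magres v1.0 text stream or string into a :class:`MagresDataset`.

    Unknown blocks are ignored; ``units`` declarations are recorded and
    checked against the supported set (Angstrom / ppm / atomic units).
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    ds = MagresDataset()
    block = None
    seen_keys: set[SiteKey] = set()
    for lineno, raw in enumerate(source, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line or line.startswith("#$"):
            continue
        if line.startswith("[/"):
            block = None
            continue
        if line.startswith("["):
            block = line.strip("[]").strip().lower()
            continue
        parts = line.split()
        tag = parts[0].lower()
        if tag == "units":
            if len(parts) != 3:
                raise ParseError("units line needs 'units <block> <unit>'", lineno)
            what, unit = parts[1].lower(), parts[2]
            allowed = _ALLOWED_UNITS.get(what)
            if allowed is not None and unit.lower() not in allowed:
                raise ParseError(f"unsupported units {unit!r} for {what!r}", lineno)
            ds.units_declared[what] = unit
        elif block == "atoms" and tag == "lattice":
            vals = _parse_floats(parts[1:], lineno)
            if len(vals) != 9:
                raise ParseError("lattice line needs 9 components", lineno)
            ds.lattice = np.array(vals, dtype=float).reshape(3, 3)
        elif block == "atoms" and tag == "atom":
            if len(parts) != 7:
                raise ParseError("atom line needs species label index x y z", lineno)
            species, label = parts[1], parts[2]
            try:
                index = int(parts[3])
            except ValueError:
                raise ParseError(f"malformed atom index {parts[3]!r}", lineno) from None
            pos = np.array(_parse_floats(parts[4:7], lineno))
            key = (label, index)
            if key in seen_keys:
                raise DuplicateSiteError(f"duplicate site {key} at line {lineno}")
            seen_keys.add(key)
            ds.atoms.append(MagresAtom(species, label, index, pos))
        elif block == "magres" and tag in ("ms", "efg"):
            if len(parts) != 12:
                raise ParseError(f"{tag} line needs label index + 9 components", lineno)
            label = parts[1]
            try:
                index = int(parts[2])
            except ValueError:
                raise ParseError(f"malformed site index {parts[2]!r}", lineno) from None
            vals = _parse_floats(parts[3:], lineno)
            tensor = np.array(vals, dtype=float).reshape(3, 3)
            target = ds.ms_tensors if tag == "ms" else ds.efg_tensors
            target[(label, index)] = tensor
        # anything else: unknown block content, preserved-by-ignoring
    if ds.atoms and ds.lattice is None:
        raise StructureFileError("no lattice line in [atoms] block")
    ds.validate()
    return ds


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_magres(ds: MagresDataset) -> str:
    """Serialise a dataset to .magres v1.0 text.

    Deterministic: atoms ordered by (species, index); tensor lines follow
    the same order; numbers at full double precision, so two writes of the
    same dataset are byte-identical.
    """
    for name, tensors in (("ms", ds.ms_tensors), ("efg", ds.efg_tensors)):
        known = {a.key for a in ds.atoms}
        for k in tensors:
            if k not in known:
                raise ConsistencyError(f"{name} tensor for site {k} with no coordinates")
    lines = ["#$magres-abinitio-v1.0"]
    order = sorted(ds.atoms, key=lambda a: (a.species, a.index))
    if ds.atoms or ds.lattice is not None:
        lines.append("[atoms]")
        if ds.lattice is not None:
            lines.append("units lattice Angstrom")
            lines.append("lattice " + " ".join(_fmt(x) for x in ds.lattice.ravel()))
        if ds.atoms:
            lines.append("units atom Angstrom")
            for a in order:
                lines.append(
                    f"atom {a.species} {a.label} {a.index} "
                    + " ".join(_fmt(x) for x in a.position)
                )
        lines.append("[/atoms]")
    if ds.ms_tensors or ds.efg_tensors:
        lines.append("[magres]")
        if ds.ms_tensors:
            lines.append("units ms ppm")
            for a in order:
                if a.key in ds.ms_tensors:
                    t = ds.ms_tensors[a.key]
                    lines.append(
                        f"ms {a.label} {a.index} " + " ".join(_fmt(x) for x in t.ravel())
                    )
        if ds.efg_tensors:
            lines.append("units efg au")
            for a in order:
                if a.key in ds.efg_tensors:
                    t = ds.efg_tensors[a.key]
                    lines.append(
                        f"efg {a.label} {a.index} " + " ".join(_fmt(x) for x in t.ravel())
                    )
        lines.append("[/magres]")
    return "\n".join(lines) + "\n"


def isotropic_shielding(tensor: np.ndarray) -> float:
    """Isotropic shielding sigma_iso = tr(sigma)/3 in ppm.

    Rotation-invariant; the antisymmetric part of a raw GIPAW tensor does
    not contribute to the trace.
    """
    t = np.asarray(tensor, dtype=float)
    if t.shape != (3, 3) or not np.all(np.isfinite(t)):
        raise ValueError("shielding tensor must be a finite 3x3 matrix")
    return float(np.trace(t)) / 3.0


def quadrupolar_params(
    efg: np.ndarray,
    quadrupole_moment_barn: float = Q_14N_BARN,
    site: SiteKey = ("", 0),
    trace_tol: float = 1e-6,
) -> QuadrupolarParams:
    """Reduce an EFG tensor (a.u.) to (C_Q, eta, P_Q).

    The tensor is symmetrised as (V + V^T)/2; its eigenvalues are ordered
    by the convention |V_zz| >= |V_yy| >= |V_xx|.  An exact magnitude tie
    between V_yy and V_zz is broken in favour of the algebraically larger
    (positive-sign-preferred) eigenvalue, so output is deterministic.
    C_Q[MHz] = 234.9647 * Q[barn] * V_zz[a.u.].  For C_Q = 0 eta is 0 by
    convention.
    """
    t = np.asarray(efg, dtype=float)
    if t.shape != (3, 3) or not np.all(np.isfinite(t)):
        raise NotAnEFGError("EFG tensor must be a finite 3x3 matrix")
    sym = 0.5 * (t + t.T)
    scale = max(1.0, float(np.abs(sym).max()))
    if abs(np.trace(sym)) > trace_tol * scale:
        raise NotAnEFGError(f"tensor trace {np.trace(sym):.3g} a.u. exceeds tolerance")
    eig = np.linalg.eigvalsh(sym)
    # ascending (|v|, v): last entry is V_zz with positive preferred on ties
    vxx, vyy, vzz = sorted(eig, key=lambda v: (abs(v), v))
    if abs(vzz) < 1e-300:
        return QuadrupolarParams(site, 0.0, 0.0, 0.0, (0.0, 0.0, 0.0))
    c_q = EFG_AU_TO_MHZ_PER_BARN * quadrupole_moment_barn * vzz
    eta = (vxx - vyy) / vzz
    eta = min(max(eta, 0.0), 1.0) + 0.0  # clip jitter; +0.0 kills -0.0
    p_q = abs(c_q) * np.sqrt(1.0 + eta * eta / 3.0)
    return QuadrupolarParams(site, float(c_q), float(eta), float(p_q),
                             (float(vxx), float(vyy), float(vzz)))
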