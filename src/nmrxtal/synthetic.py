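"""Seeded generators of toy crystals, magres files and noisy shift tables.

The generator stands in for the DFT and experimental stages so every
pipeline step is testable offline with known ground truth.  It emulates
the statistical structure those stages provide — calc = exp + small
residual — not the physics: shifts are drawn from per-nucleus uniform
ranges, shielding tensors realise sigma_iso = sigma_ref_true - shift_true
plus a random anisotropy, EFG tensors realise drawn (C_Q, eta) in a
random orientation, and the "experimental" table is truth plus seeded
Gaussian noise at the stated accuracy of routine solid-state shift
measurements (0.2 / 0.1 / 5 ppm for 1H / 13C / 15N).

One numpy Generator per case, consumed in a documented order (placement,
shifts, tensor orientations, noise), so regeneration is stable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .constants import EFG_AU_TO_MHZ_PER_BARN, Q_14N_BARN
from .errors import PackingError
from .geometry import CrystalStructure, Site, min_image_distance, write_structure
from .magres import MagresAtom, MagresDataset, write_magres
from .referencing import ShiftTable

#: Element -> observed nucleus for the toy cases.
NUCLEUS_OF = {"H": "1H", "C": "13C", "N": "15N"}

#: True-shift draw ranges per nucleus, ppm.
SHIFT_RANGES = {"1H": (0.0, 15.0), "13C": (10.0, 180.0), "15N": (-300.0, 0.0)}

#: Default noise sigma per nucleus, ppm (stated experimental accuracy).
DEFAULT_NOISE = {"1H": 0.2, "13C": 0.1, "15N": 5.0}

#: Default true reference shieldings, ppm.
DEFAULT_SIGMA_REF = {"1H": 31.0, "13C": 172.0, "15N": -160.0}

#: Shielding anisotropy scale per nucleus, ppm.
ANISO_SCALE = {"1H": 5.0, "13C": 30.0, "15N": 50.0}


@dataclass
class GroundTruth:
    """Everything the generator knows, for use as a test oracle."""

    structure: CrystalStructure
    true_shifts: dict[str, dict[str, float]]  # nucleus -> site label -> ppm
    sigma_ref: dict[str, float]
    quad: dict[str, tuple[float, float]]  # N site label -> (C_Q MHz, eta)
    noise: dict[str, float]
    seed: int
    magres_text: str = ""
    structure_xyz: str = ""
    exp_table: ShiftTable | None = None

    def manifest(self) -> str:
        """JSON record of the ground truth for test harnesses."""
        return json.dumps({
            "seed": self.seed,
            "sigma_ref": self.sigma_ref,
            "noise": self.noise,
            "true_shifts": self.true_shifts,
            "quad": {k: list(v) for k, v in self.quad.items()},
        }, indent=2, sort_keys=True)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    return Rotation.random(rng=rng).as_matrix()


def _place_sites(
    counts: dict[str, int], cell: np.ndarray, rng: np.random.Generator,
    min_separation: float, max_tries: int = 2000,
) -> list[Site]:
    sites: list[Site] = []
    struct = CrystalStructure(cell, [])
    for el in sorted(counts):
        for i in range(1, counts[el] + 1):
            for _ in range(max_tries):
                frac = rng.random(3)
                cand = Site(f"{el}{i}", el, i, frac)
                ok = True
                for s in sites:
                    if min_image_distance(s, cand, struct) < min_separation:
                        ok = False
                        break
                if ok:
                    sites.append(cand)
                    break
            else:
                raise PackingError(
                    f"could not place {el}{i} with {min_separation} A separation; "
                    "cell too small for requested sites")
    return sites


def efg_tensor_from_cq_eta(
    c_q: float, eta: float, rotation: np.ndarray,
    quadrupole_moment_barn: float = Q_14N_BARN,
) -> np.ndarray:
    """Traceless symmetric EFG tensor (a.u.) realising (C_Q, eta).

    Principal frame diag(V_xx, V_yy, V_zz) with V_zz = C_Q / (K Q),
    V_xx = -V_zz (1 - eta)/2, V_yy = -V_zz (1 + eta)/2, rotated into a
    laboratory orientation; traceless by construction.
    """
    v_zz = c_q / (EFG_AU_TO_MHZ_PER_BARN * quadrupole_moment_barn)
    diag = np.diag([-v_zz * (1 - eta) / 2.0, -v_zz * (1 + eta) / 2.0, v_zz])
    return rotation @ diag @ rotation.T


def _ms_tensor(sigma_iso: float, scale: float, rng: np.random.Generator) -> np.ndarray:
    a1, a2 = rng.normal(0.0, scale, size=2)
    diag = np.diag([a1, a2, -a1 - a2])
    r = _random_rotation(rng)
    return sigma_iso * np.eye(3) + r @ diag @ r.T


def generate_case(
    n_h: int = 8,
    n_c: int = 8,
    n_n: int = 2,
    n_o: int = 0,
    cell: float | np.ndarray = 12.0,
    noise: dict[str, float] | None = None,
    sigma_ref: dict[str, float] | None = None,
    seed: int = 0,
    min_separation: float = 0.8,
    cq_range: tuple[float, float] = (2.0, 4.5),
) -> GroundTruth:
    """Generate a toy case: structure + magres text + noisy shift table.

    The rng stream is consumed in a fixed order (site placement, true
    shifts, shielding tensors, EFG tensors, noise), so a seed pins every
    output byte-for-byte.
    """
    rng = np.random.default_rng(seed)
    noise = dict(DEFAULT_NOISE if noise is None else noise)
    sigma_ref = dict(DEFAULT_SIGMA_REF if sigma_ref is None else sigma_ref)
    cell_m = np.eye(3) * float(cell) if np.isscalar(cell) else np.asarray(cell, float)
    counts = {"H": n_h, "C": n_c, "N": n_n, "O": n_o}
    counts = {k: v for k, v in counts.items() if v > 0}
    sites = _place_sites(counts, cell_m, rng, min_separation)
    structure = CrystalStructure(cell_m, sites, source=f"synthetic seed={seed}")

    true_shifts: dict[str, dict[str, float]] = {}
    for s in sites:
        nuc = NUCLEUS_OF.get(s.element)
        if nuc is None:
            continue
        lo, hi = SHIFT_RANGES[nuc]
        true_shifts.setdefault(nuc, {})[s.label] = float(rng.uniform(lo, hi))

    atoms = [MagresAtom(s.element, s.label, s.index, structure.cartesian(s))
             for s in sites]
    ds = MagresDataset(atoms=atoms, lattice=cell_m.copy())
    for s in sites:
        nuc = NUCLEUS_OF.get(s.element)
        if nuc is None:
            continue
        sigma_iso = sigma_ref[nuc] - true_shifts[nuc][s.label]
        ds.ms_tensors[(s.label, s.index)] = _ms_tensor(
            sigma_iso, ANISO_SCALE[nuc], rng)

    quad: dict[str, tuple[float, float]] = {}
    for s in sites:
        if s.element != "N":
            continue
        c_q = float(rng.uniform(*cq_range)) * float(rng.choice([-1.0, 1.0]))
        eta = float(rng.uniform(0.0, 1.0))
        quad[s.label] = (c_q, eta)
        ds.efg_tensors[(s.label, s.index)] = efg_tensor_from_cq_eta(
            c_q, eta, _random_rotation(rng))

    rows = []
    for nuc in sorted(true_shifts):
        for label in sorted(true_shifts[nuc]):
            exp = true_shifts[nuc][label] + rng.normal(0.0, noise.get(nuc, 0.0))
            rows.append({"site": label, "nucleus": nuc, "exp": exp})
    exp_table = ShiftTable(pd.DataFrame(rows))

    return GroundTruth(
        structure=structure, true_shifts=true_shifts, sigma_ref=sigma_ref,
        quad=quad, noise=noise, seed=seed,
        magres_text=write_magres(ds),
        structure_xyz=write_structure(structure, "xyz"),
        exp_table=exp_table,
    )


def generate_hbond_motif(
    d_ha: float = 1.8,
    angle_dha: float = 170.0,
    d_dh: float = 1.03,
    donor: str = "N",
    acceptor: str = "O",
    cell_edge: float = 15.0,
    seed: int | None = None,
) -> CrystalStructure:
    """Embed a D-H...A triplet with exact requested geometry in a padded cell.

    The donor sits near the cell centre; H lies d_dh away; the acceptor is
    placed at distance d_ha from H with the requested D-H-A angle (vertex
    at H).  With a seed the whole motif is rigidly rotated, which must not
    change any recovered geometry.
    """
    if not (0.5 <= d_dh <= 1.3) or not (1.0 <= d_ha <= 3.0):
        raise ValueError("requested bond geometry outside physical range")
    if not (0.0 < angle_dha <= 180.0):
        raise ValueError("D-H-A angle must be in (0, 180]")
    a = math.radians(angle_dha)
    d_pos = np.zeros(3)
    h_pos = d_pos + np.array([d_dh, 0.0, 0.0])
    # H->D is -x; H->A makes the requested angle with it
    h_to_a = np.array([-math.cos(a), math.sin(a), 0.0])
    a_pos = h_pos + d_ha * h_to_a
    coords = np.vstack([d_pos, h_pos, a_pos])
    if seed is not None:
        r = _random_rotation(np.random.default_rng(seed))
        coords = coords @ r.T
    coords += cell_edge / 2.0  # centre in the cell, away from images
    cell = np.eye(3) * cell_edge
    inv = np.linalg.inv(cell)
    sites = [
        Site(f"{donor}1", donor, 1, coords[0] @ inv),
        Site("H1", "H", 1, coords[1] @ inv),
        Site(f"{acceptor}1", acceptor, 1, coords[2] @ inv),
    ]
    return CrystalStructure(cell, sites, source="synthetic hbond motif")
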