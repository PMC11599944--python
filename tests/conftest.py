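"""Shared fixtures and independent brute-force oracles."""

import itertools

import numpy as np
import pytest

from nmrxtal.geometry import CrystalStructure, Site


def brute_force_distances(a, b, structure, cutoff, n=5):
    """Image-enumeration oracle: all separations <= cutoff over |n_i| <= n."""
    dfrac = np.asarray(b.frac) - np.asarray(a.frac)
    out = []
    for shift in itertools.product(range(-n, n + 1), repeat=3):
        d = float(np.linalg.norm((dfrac + np.array(shift)) @ structure.cell))
        if d <= cutoff and not (a.key == b.key and d < 1e-9):
            out.append(d)
    return sorted(out)


def brute_force_min_image(a, b, structure, n=5):
    dfrac = np.asarray(b.frac) - np.asarray(a.frac)
    best = np.inf
    for shift in itertools.product(range(-n, n + 1), repeat=3):
        best = min(best, float(np.linalg.norm((dfrac + np.array(shift)) @ structure.cell)))
    return best


def random_triclinic_cell(rng, lo=6.0, hi=12.0):
    """Moderately skewed triclinic cell (angles 70-110 deg)."""
    import gemmi

    a, b, c = rng.uniform(lo, hi, 3)
    al, be, ga = rng.uniform(70.0, 110.0, 3)
    m = np.array(gemmi.UnitCell(a, b, c, al, be, ga).orth.mat.tolist())
    return m.T.copy()


def random_rotation_matrix(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()


@pytest.fixture
def cubic10():
    """10 A cubic cell with two H sites across the cell boundary."""
    cell = np.eye(3) * 10.0
    sites = [Site("H1", "H", 1, np.array([0.0, 0.0, 0.0])),
             Site("H2", "H", 2, np.array([0.0, 0.0, 0.9]))]
    return CrystalStructure(cell, sites)


@pytest.fixture
def methane_box():
    """A CH4 molecule centred in a 12 A cube: exactly 4 C-H bonds."""
    d = 1.09 / np.sqrt(3.0)
    carts = np.array([[0, 0, 0], [d, d, d], [d, -d, -d], [-d, d, -d], [-d, -d, d]])
    carts += 6.0
    cell = np.eye(3) * 12.0
    inv = np.linalg.inv(cell)
    sites = [Site("C1", "C", 1, carts[0] @ inv)]
    sites += [Site(f"H{i}", "H", i, carts[i] @ inv) for i in range(1, 5)]
    return CrystalStructure(cell, sites)
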