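"""Periodic geometry: distances, bonds, hydrogen bonds, proximities."""

import numpy as np
import pytest

from nmrxtal import (
    CrystalStructure,
    Site,
    bonded_pairs,
    distances_within,
    find_hydrogen_bonds,
    generate_hbond_motif,
    hh_proximities,
    min_image_distance,
    parse_structure,
    write_structure,
)
from nmrxtal.errors import ParseError, StructureFileError

from conftest import (
    brute_force_distances,
    brute_force_min_image,
    random_triclinic_cell,
)

TOY_CIF = """\
data_toy
_cell_length_a 10.0
_cell_length_b 11.0
_cell_length_c 12.0
_cell_angle_alpha 90.0
_cell_angle_beta 90.0
_cell_angle_gamma 90.0
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
C1 C 0.10 0.20 0.30
H1 H 1.25 0.20 0.30
O1 O -0.10 0.50 0.60
"""


class TestStructureIO:
    def test_cif_parse_and_wrap(self):
        s = parse_structure(TOY_CIF, "cif")
        assert len(s.sites) == 3
        assert s.site("H1").frac[0] == pytest.approx(0.25)  # 1.25 wraps
        assert s.site("O1").frac[0] == pytest.approx(0.90)  # -0.10 wraps
        assert s.volume == pytest.approx(10 * 11 * 12)

    def test_missing_cell_parameter(self):
        with pytest.raises(StructureFileError):
            parse_structure(TOY_CIF.replace("_cell_length_b 11.0\n", ""), "cif")

    def test_bad_coordinate_reported(self):
        with pytest.raises(ParseError):
            parse_structure(TOY_CIF.replace("0.10 0.20 0.30", "0.10 x 0.30"), "cif")

    def test_xyz_round_trip(self):
        s = parse_structure(TOY_CIF, "cif")
        s2 = parse_structure(write_structure(s, "xyz"), "xyz")
        assert np.allclose(s2.cell, s.cell)
        for a, b in zip(s.sites, s2.sites):
            assert a.element == b.element
            assert np.allclose(a.frac, b.frac, atol=1e-9)

    def test_cif_round_trip(self):
        s = parse_structure(TOY_CIF, "cif")
        s2 = parse_structure(write_structure(s, "cif"), "cif")
        assert np.allclose(s2.cell, s.cell, atol=1e-5)
        for a, b in zip(s.sites, s2.sites):
            assert np.allclose(a.frac, b.frac, atol=1e-8)


class TestMinImage:
    def test_self_distance_zero(self, cubic10):
        h1 = cubic10.site("H1")
        assert min_image_distance(h1, h1, cubic10) == 0.0

    def test_wrap_around(self, cubic10):
        """(0,0,0) to (0,0,0.9) in a 10 A cube is 1 A through the boundary."""
        d = min_image_distance(cubic10.site("H1"), cubic10.site("H2"), cubic10)
        assert d == pytest.approx(1.0)

    def test_symmetry(self, cubic10):
        a, b = cubic10.sites
        assert min_image_distance(a, b, cubic10) == pytest.approx(
            min_image_distance(b, a, cubic10), abs=1e-9)

    def test_triclinic_against_brute_force(self):
        """Minimum image equals a 5x5x5-image enumeration on random cells."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            cell = random_triclinic_cell(rng)
            sites = [Site(f"X{i}", "X", i, rng.random(3)) for i in range(1, 5)]
            s = CrystalStructure(cell, sites)
            for i in range(len(sites)):
                for j in range(i, len(sites)):
                    got = min_image_distance(sites[i], sites[j], s)
                    want = brute_force_min_image(sites[i], sites[j], s)
                    assert got == pytest.approx(want, abs=1e-9)


class TestDistancesWithin:
    def test_beyond_cutoff_empty(self):
        s = CrystalStructure(np.eye(3) * 20, [
            Site("H1", "H", 1, np.array([0.0, 0.0, 0.0])),
            Site("H2", "H", 2, np.array([0.5, 0.5, 0.5]))])
        assert distances_within(*s.sites, s, cutoff=3.5) == []

    def test_small_cell_images(self):
        """1 A pair in a 3 A cube: the 2 A wrap-around image is within 3.5 A."""
        s = CrystalStructure(np.eye(3) * 3.0, [
            Site("H1", "H", 1, np.array([0.0, 0.0, 0.0])),
            Site("H2", "H", 2, np.array([1 / 3, 0.0, 0.0]))])
        d = distances_within(*s.sites, s, cutoff=3.5)
        assert d[0] == pytest.approx(1.0)
        assert any(abs(x - 2.0) < 1e-9 for x in d)

    def test_against_brute_force(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            cell = random_triclinic_cell(rng)
            sites = [Site(f"X{i}", "X", i, rng.random(3)) for i in range(1, 4)]
            s = CrystalStructure(cell, sites)
            cutoff = rng.uniform(3.0, 8.0)
            for i in range(len(sites)):
                for j in range(i, len(sites)):
                    got = distances_within(sites[i], sites[j], s, cutoff)
                    want = brute_force_distances(sites[i], sites[j], s, cutoff)
                    assert np.allclose(got, want, atol=1e-9)
                    if got:
                        assert min_image_distance(sites[i], sites[j], s) <= got[0] + 1e-12

    def test_invariance_to_translation_and_rewrap(self):
        """Integer lattice translation of a site changes no distance."""
        rng = np.random.default_rng(5)
        cell = random_triclinic_cell(rng)
        f1, f2 = rng.random(3), rng.random(3)
        s1 = CrystalStructure(cell, [Site("H1", "H", 1, f1), Site("H2", "H", 2, f2)])
        s2 = CrystalStructure(cell, [Site("H1", "H", 1, f1 + np.array([2, -1, 3])),
                                     Site("H2", "H", 2, f2 - np.array([0, 4, 1]))])
        a = distances_within(*s1.sites, s1, 6.0)
        b = distances_within(*s2.sites, s2, 6.0)
        assert np.allclose(a, b, atol=1e-9)


class TestBondsAndProximities:
    def test_ch_bond_cutoff(self):
        cell = np.eye(3) * 10
        for d, expect in ((1.09, 1), (1.2, 0)):
            s = CrystalStructure(cell, [
                Site("C1", "C", 1, np.array([0.0, 0.0, 0.0])),
                Site("H1", "H", 1, np.array([d / 10, 0.0, 0.0]))])
            assert len(bonded_pairs(s, ("C", "H"), 1.1)) == expect

    def test_methane_has_four_bonds(self, methane_box):
        assert len(bonded_pairs(methane_box, ("C", "H"), 1.1)) == 4

    def test_two_protons_one_pair(self):
        s = CrystalStructure(np.eye(3) * 20, [
            Site("H1", "H", 1, np.array([0.0, 0.0, 0.0])),
            Site("H2", "H", 2, np.array([0.1, 0.0, 0.0]))])
        pairs = hh_proximities(s, cutoff=3.5)
        assert len(pairs) == 1
        assert pairs[0].min_distance == pytest.approx(2.0)

    def test_lone_proton_no_self_pair(self):
        s = CrystalStructure(np.eye(3) * 20,
                             [Site("H1", "H", 1, np.array([0.3, 0.3, 0.3]))])
        assert hh_proximities(s, cutoff=3.5) == []

    def test_self_image_pair_in_small_cell(self):
        """A proton 3 A from its own image forms a self-pair."""
        s = CrystalStructure(np.eye(3) * 3.0,
                             [Site("H1", "H", 1, np.array([0.0, 0.0, 0.0]))])
        pairs = hh_proximities(s, cutoff=3.5)
        assert len(pairs) == 1
        assert pairs[0].h1.key == pairs[0].h2.key
        assert pairs[0].min_distance == pytest.approx(3.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        cell = np.eye(3) * 8
        sites = [Site(f"H{i}", "H", i, rng.random(3)) for i in range(1, 6)]
        s1 = CrystalStructure(cell, sites)
        s2 = CrystalStructure(cell, list(reversed(sites)))
        key = lambda p: tuple(sorted((p.h1.label, p.h2.label)))
        got1 = {key(p): p.min_distance for p in hh_proximities(s1, 3.5)}
        got2 = {key(p): p.min_distance for p in hh_proximities(s2, 3.5)}
        assert got1.keys() == got2.keys()
        for k in got1:
            assert got1[k] == pytest.approx(got2[k], abs=1e-9)


class TestHydrogenBonds:
    def test_collinear_bond_detected(self):
        m = generate_hbond_motif(d_ha=1.8, angle_dha=180.0)
        bonds = find_hydrogen_bonds(m)
        assert len(bonds) == 1
        b = bonds[0]
        assert b.d_HA == pytest.approx(1.8, abs=1e-9)
        assert b.angle_DHA == pytest.approx(180.0, abs=1e-6)
        assert b.d_DA == pytest.approx(1.03 + 1.8, abs=1e-9)

    def test_bent_geometry_excluded_by_angle(self):
        m = generate_hbond_motif(d_ha=1.8, angle_dha=100.0)
        assert find_hydrogen_bonds(m, angle_min=120.0) == []
        assert len(find_hydrogen_bonds(m, angle_min=90.0)) == 1

    def test_distance_cutoff(self):
        m = generate_hbond_motif(d_ha=2.8, angle_dha=170.0)
        assert find_hydrogen_bonds(m, d_ha_max=2.5) == []

    def test_dha_less_than_dda(self):
        for seed in range(5):
            m = generate_hbond_motif(d_ha=1.9, angle_dha=150.0, seed=seed)
            (b,) = find_hydrogen_bonds(m)
            assert b.d_HA < b.d_DA

    def test_orphan_hydrogen_skipped(self):
        """An H with no donor heavy atom nearby yields no bonds."""
        s = CrystalStructure(np.eye(3) * 15, [
            Site("H1", "H", 1, np.array([0.1, 0.1, 0.1])),
            Site("O1", "O", 1, np.array([0.25, 0.1, 0.1]))])  # 2.25 A away
        assert find_hydrogen_bonds(s) == []
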