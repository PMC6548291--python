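"""SASA closed forms, Miller normalization, interface area oracles."""

import numpy as np
import pytest

import prenylpocket as pp
from prenylpocket.sasa_interface import (MILLER_TRIPEPTIDE_SASA, interface_area,
                                         normalized_residue_sasa, sasa)
from prenylpocket.synthetic_data import make_extended_peptide

from conftest import full_selection, make_structure

ISOLATED_C = 4 * np.pi * (1.70 + 1.4) ** 2  # ≈ 120.76 Å²


class TestShrakeRupley:
    def test_isolated_carbon_closed_form(self):
        s = make_structure([[0, 0, 0]])
        result = sasa(None, full_selection(s))
        assert result.total == pytest.approx(ISOLATED_C, rel=0.02)

    def test_enclosed_atom_has_zero_area(self):
        # shell tight enough that wall spheres occlude the whole surface
        shell, _ = pp.make_cavity_shell(pp.CavitySpec(inner_radius=2.0))
        s = make_structure(
            np.concatenate([shell.coordinates, [[0.0, 0, 0]]]),
            residue_numbers=np.arange(1, shell.n_atoms + 2))
        result = sasa(None, full_selection(s))
        assert result.atom_areas[-1] == 0.0

    def test_two_distant_atoms_are_independent(self):
        s = make_structure([[0, 0, 0], [10.0, 0, 0]])  # > 2(r+probe)
        result = sasa(None, full_selection(s))
        np.testing.assert_allclose(result.atom_areas, ISOLATED_C, rtol=0.02)

    def test_too_few_points_rejected(self):
        s = make_structure([[0, 0, 0]])
        with pytest.raises(ValueError):
            sasa(None, full_selection(s), n_points=10)

    def test_rigid_motion_invariance(self, random_rotation):
        rng = np.random.default_rng(8)
        s = make_structure(rng.uniform(0, 8, (10, 3)),
                           residue_numbers=np.arange(1, 11))
        a0 = sasa(None, full_selection(s)).atom_areas
        moved = s.coordinates @ random_rotation.T + 50.0
        a1 = sasa(moved, full_selection(s)).atom_areas
        np.testing.assert_allclose(a0, a1, rtol=0.02, atol=0.5)

    def test_point_density_convergence_below_1_percent(self):
        rng = np.random.default_rng(9)
        s = make_structure(rng.uniform(0, 6, (8, 3)),
                           residue_numbers=np.arange(1, 9))
        t960 = sasa(None, full_selection(s), n_points=960).total
        t3840 = sasa(None, full_selection(s), n_points=3840).total
        assert abs(t960 - t3840) / t3840 < 0.01

    def test_cross_check_against_mdtraj(self, tmp_path):
        """Independent Shrake–Rupley implementation agrees on a toy cluster."""
        mdtraj = pytest.importorskip("mdtraj")
        rng = np.random.default_rng(10)
        coords = rng.uniform(0, 8, (12, 3))
        s = make_structure(coords, residue_numbers=np.arange(1, 13),
                           atom_names=["CA"] * 12, res_names=["ALA"] * 12)
        path = pp.save_structure(s, tmp_path / "toy.pdb")
        ours = sasa(None, full_selection(s), n_points=960).total
        t = mdtraj.load(str(path))
        theirs = float(mdtraj.shrake_rupley(t, probe_radius=0.14,
                                            n_sphere_points=960).sum()) * 100.0
        assert ours == pytest.approx(theirs, rel=0.03)


class TestMillerNormalization:
    def test_table_covers_all_20_residues_positively(self):
        assert len(MILLER_TRIPEPTIDE_SASA) == 20
        assert all(v > 0 for v in MILLER_TRIPEPTIDE_SASA.values())

    def test_gly_ala_gly_central_fraction_near_one(self):
        pep = make_extended_peptide("GAG")
        result = sasa(None, full_selection(pep))
        frac = normalized_residue_sasa(result)
        assert frac[1] == pytest.approx(1.0, abs=0.10)

    def test_fully_buried_residue_fraction_zero(self):
        shell, _ = pp.make_cavity_shell(pp.CavitySpec(inner_radius=2.0))
        s = make_structure(
            np.concatenate([shell.coordinates, [[0.0, 0, 0]]]),
            residue_numbers=np.concatenate([np.ones(shell.n_atoms, dtype=int),
                                            [2]]),
            res_names=["GLY"] * shell.n_atoms + ["ALA"])
        result = sasa(None, full_selection(s))
        frac = normalized_residue_sasa(result)
        assert frac[result.residue_keys.index(("A", 2))] == 0.0

    def test_separating_atoms_never_decreases_fractions(self):
        base = make_extended_peptide("GAG")
        result0 = normalized_residue_sasa(sasa(None, full_selection(base)))
        # pull residue 3 away from the rest
        coords = base.coordinates.copy()
        coords[base.residue_numbers == 3] += np.array([20.0, 0, 0])
        stretched = normalized_residue_sasa(
            sasa(coords, full_selection(base)))
        assert np.all(stretched >= result0 - 1e-9)

    def test_unknown_residue_type_rejected(self):
        s = make_structure([[0, 0, 0]], res_names=["XYZ"])
        with pytest.raises(ValueError, match="XYZ"):
            normalized_residue_sasa(sasa(None, full_selection(s)))


class TestInterfaceArea:
    def test_separated_bodies_interface_is_zero(self):
        s = make_structure([[0, 0, 0], [100.0, 0, 0]])
        a = pp.AtomSelection(s, np.array([0]), "a")
        b = pp.AtomSelection(s, np.array([1]), "b")
        assert interface_area(None, a, b) == pytest.approx(0.0, abs=1.0)

    def test_two_sphere_overlap_matches_cap_integral(self):
        # two identical extended spheres R = r + probe at distance d < 2R:
        # buried area (unhalved) = 2 * 2πR(R − d/2), the two spherical caps
        d = 4.0
        R = 1.70 + 1.4
        s = make_structure([[0, 0, 0], [d, 0, 0]])
        a = pp.AtomSelection(s, np.array([0]), "a")
        b = pp.AtomSelection(s, np.array([1]), "b")
        buried = interface_area(None, a, b, n_points=3840)
        analytic = 2 * 2 * np.pi * R * (R - d / 2)
        assert buried == pytest.approx(analytic, rel=0.03)

    def test_symmetry_and_halved_convention(self):
        s = make_structure([[0, 0, 0], [4.0, 0, 0]])
        a = pp.AtomSelection(s, np.array([0]), "a")
        b = pp.AtomSelection(s, np.array([1]), "b")
        assert interface_area(None, a, b) == pytest.approx(
            interface_area(None, b, a), abs=1e-9)
        assert interface_area(None, a, b, halved=True) == pytest.approx(
            interface_area(None, a, b) / 2.0)

    def test_overlapping_selections_rejected(self):
        s = make_structure([[0, 0, 0], [4.0, 0, 0]])
        a = pp.AtomSelection(s, np.array([0, 1]), "a")
        b = pp.AtomSelection(s, np.array([1]), "b")
        with pytest.raises(ValueError, match="overlap"):
            interface_area(None, a, b)

    def test_tight_interface_exceeds_loose(self):
        rng = np.random.default_rng(11)
        blob = rng.uniform(0, 6, (8, 3))
        for d, expect_larger in ((8.0, True),):
            coords_tight = np.concatenate([blob, blob + [d, 0, 0]])
            coords_loose = np.concatenate([blob, blob + [d + 10, 0, 0]])
            s = make_structure(coords_tight,
                               residue_numbers=np.arange(1, 17))
            a = pp.AtomSelection(s, np.arange(8), "a")
            b = pp.AtomSelection(s, np.arange(8, 16), "b")
            tight = interface_area(coords_tight, a, b)
            loose = interface_area(coords_loose, a, b)
            assert tight > loose


class TestRegionSasa:
    def test_frozen_trajectory_sd_zero_and_burial(self):
        # switch-like residues on body A, partner body B nearby vs far
        rng = np.random.default_rng(12)
        blob_a = rng.uniform(0, 8, (20, 3))
        blob_b = rng.uniform(0, 8, (20, 3)) + np.array([8.0, 0, 0])
        coords = np.concatenate([blob_a, blob_b])
        s = make_structure(
            coords,
            residue_numbers=np.concatenate([np.arange(44, 64),
                                            np.arange(300, 320)]),
            chain_ids=["A"] * 20 + ["B"] * 20)
        regions = pp.RegionMap({"switch1": {"chain": "A", "range": [44, 63]}})
        contact = np.repeat(coords[None], 2, axis=0)
        apart = contact.copy()
        apart[:, 20:] += np.array([50.0, 0, 0])
        traj_contact = pp.Trajectory(s, contact, np.arange(2.0))
        traj_apart = pp.Trajectory(s, apart, np.arange(2.0))
        near = pp.region_sasa(traj_contact, regions, ["switch1"], n_points=240)
        far = pp.region_sasa(traj_apart, regions, ["switch1"], n_points=240)
        assert near["switch1"].sd() == 0.0
        assert far["switch1"].values[0] > near["switch1"].values[0]

    def test_empty_region_is_error(self):
        s = make_structure([[0, 0, 0]], residue_numbers=[1])
        traj = pp.Trajectory(s, s.coordinates[None], np.array([0.0]))
        regions = pp.RegionMap({"ghost": {"range": [500, 510]}})
        with pytest.raises(Exception, match="matched no atoms"):
            pp.region_sasa(traj, regions, ["ghost"])
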