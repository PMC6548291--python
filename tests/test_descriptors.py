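"""Geometric descriptor correctness: closed forms, invariances, oracles."""

import numpy as np
import pytest

import prenylpocket as pp
from prenylpocket.descriptors import apply_superposition, superpose
from prenylpocket.synthetic_data import HelixSpec, make_ideal_helix

from conftest import full_selection, make_structure


def _one_frame_traj(struct):
    return pp.Trajectory(struct, struct.coordinates[None], np.array([0.0]))


class TestComDistance:
    def test_overlapping_selections_rejected_then_zero_when_disabled(self):
        s = make_structure([[0, 0, 0], [2, 0, 0]])
        traj = _one_frame_traj(s)
        sel = full_selection(s)
        with pytest.raises(ValueError, match="overlap"):
            pp.com_distance(traj, sel, sel)
        d = pp.com_distance(traj, sel, sel, check_disjoint=False)
        assert d.values[0] == 0.0

    def test_symmetric_and_rigid_motion_invariant(self, random_rotation):
        rng = np.random.default_rng(2)
        s = make_structure(rng.uniform(0, 10, (8, 3)))
        traj = _one_frame_traj(s)
        a = pp.AtomSelection(s, np.arange(4), "a")
        b = pp.AtomSelection(s, np.arange(4, 8), "b")
        d_ab = pp.com_distance(traj, a, b).values[0]
        d_ba = pp.com_distance(traj, b, a).values[0]
        assert d_ab == pytest.approx(d_ba, abs=1e-12)
        moved = s.coordinates @ random_rotation.T + np.array([5.0, -3.0, 2.0])
        traj2 = pp.Trajectory(s, moved[None], np.array([0.0]))
        assert pp.com_distance(traj2, a, b).values[0] == pytest.approx(d_ab, abs=1e-9)

    def test_mass_weighting_shifts_centroid(self):
        s = make_structure([[0, 0, 0], [1, 0, 0], [10, 0, 0]],
                           elements=["C", "O", "C"])
        traj = _one_frame_traj(s)
        a = pp.AtomSelection(s, np.array([0, 1]), "a")
        b = pp.AtomSelection(s, np.array([2]), "b")
        uniform = pp.com_distance(traj, a, b, mass_weighted=False).values[0]
        weighted = pp.com_distance(traj, a, b, mass_weighted=True).values[0]
        assert weighted < uniform  # O is heavier, pulls COM toward x=1


class TestHelixAxis:
    def test_reversing_residue_order_flips_sign(self):
        helix = make_ideal_helix(HelixSpec(n_residues=12))
        sel = full_selection(helix)
        rev = pp.AtomSelection(helix, np.arange(11, -1, -1)[::-1], "fwd")
        axis_fwd = pp.helix_axis(sel)
        reversed_struct = helix.subset(np.arange(11, -1, -1))
        axis_rev = pp.helix_axis(full_selection(reversed_struct))
        assert np.dot(axis_fwd, axis_rev) == pytest.approx(-1.0, abs=1e-6)

    def test_collinear_points_give_exact_direction(self):
        s = make_structure(np.outer(np.arange(6), [1.0, 0, 0]))
        axis = pp.helix_axis(full_selection(s))
        np.testing.assert_allclose(axis, [1, 0, 0], atol=1e-12)

    def test_fewer_than_four_atoms_rejected(self):
        s = make_structure(np.random.default_rng(0).uniform(0, 5, (3, 3)))
        with pytest.raises(ValueError):
            pp.helix_axis(full_selection(s))

    def test_interhelix_angle_symmetric_and_rigid_invariant(self, random_rotation):
        h1 = make_ideal_helix(HelixSpec(n_residues=12, axis_direction=(0, 0, 1)))
        ang = np.deg2rad(40.0)
        h2 = make_ideal_helix(HelixSpec(
            n_residues=12, axis_direction=(np.sin(ang), 0, np.cos(ang)),
            origin=(15, 0, 0), chain_id="B"))
        s1, s2 = full_selection(h1), full_selection(h2)
        t12 = pp.interhelix_angle(h1, s1, pp.AtomSelection(h2, np.arange(12), "h2"))
        t21 = pp.interhelix_angle(h2, pp.AtomSelection(h2, np.arange(12), "h2"), s1)
        # note: both selections carry their own parent structures; the frame
        # argument applies per structure, so evaluate on static structures
        assert t12.values[0] == pytest.approx(40.0, abs=1.0)
        assert t21.values[0] == pytest.approx(t12.values[0], abs=1e-9)


class TestInsertionDepthAndInsideCount:
    def test_planted_depth_two_nm(self):
        s = make_structure([[0, 0, 0], [20, 0, 0]], residue_numbers=[132, 212])
        traj = _one_frame_traj(s)
        met = pp.AtomSelection(s, np.array([0]), "met")
        cys = {212: pp.AtomSelection(s, np.array([1]), "cys")}
        series = pp.insertion_depth(traj, met, cys)
        assert series["d_GGpocket_Cys212"].values[0] == pytest.approx(2.0)
        assert series["d_GGpocket_mean"].values[0] == pytest.approx(2.0)

    @pytest.mark.parametrize("d1,d2,expected", [
        (10.0, 10.0, 2), (14.9, 15.1, 1), (15.0, 15.0, 0)])
    def test_strict_inequality_boundary(self, d1, d2, expected):
        s = make_structure([[0, 0, 0], [d1, 0, 0], [0, d2, 0]],
                           residue_numbers=[132, 212, 213],
                           atom_names=["CA", "C20", "C20"],
                           hetero=[False, True, True])
        traj = _one_frame_traj(s)
        met = pp.AtomSelection(s, np.array([0]), "met")
        heads = pp.AtomSelection(s, np.array([1, 2]), "heads")
        counts = pp.gg_inside_count(traj, met, heads, cutoff=1.5)
        assert counts.values[0] == expected


class TestMembraneDistance:
    def test_slab_to_protein_distance(self):
        slab = [[x, y, 0.0] for x in range(3) for y in range(3)]
        coords = slab + [[1.0, 1.0, 44.0]]
        s = make_structure(coords, residue_numbers=list(range(1, 11)))
        traj = _one_frame_traj(s)
        mem = pp.AtomSelection(s, np.arange(9), "mem")
        prot = pp.AtomSelection(s, np.array([9]), "prot")
        assert pp.membrane_distance(traj, mem, prot).values[0] == pytest.approx(4.4)

    def test_absolute_value_below_slab(self):
        s = make_structure([[0, 0, 0], [0, 0, -30.0]], residue_numbers=[1, 2])
        traj = _one_frame_traj(s)
        mem = pp.AtomSelection(s, np.array([0]), "mem")
        prot = pp.AtomSelection(s, np.array([1]), "prot")
        assert pp.membrane_distance(traj, mem, prot).values[0] == pytest.approx(3.0)

    def test_two_frame_mean(self):
        s = make_structure([[0, 0, 0], [0, 0, 40.0]], residue_numbers=[1, 2])
        frames = np.array([s.coordinates,
                           [[0, 0, 0], [0, 0, 48.0]]])
        traj = pp.Trajectory(s, frames, np.array([0.0, 1.0]))
        mem = pp.AtomSelection(s, np.array([0]), "mem")
        prot = pp.AtomSelection(s, np.array([1]), "prot")
        assert pp.membrane_distance(traj, mem, prot).mean() == pytest.approx(4.4)


def _brute_force_min_rmsd(mobile, reference, n_coarse=40_000, n_refine=6,
                          seed=0):
    """Independent superposition oracle: random rotation search with local
    refinement, no Kabsch involved."""
    rng = np.random.default_rng(seed)

    def rmsd_for(quats):
        # normalize quaternions -> rotation matrices (vectorized)
        q = quats / np.linalg.norm(quats, axis=1, keepdims=True)
        w, x, y, z = q.T
        mats = np.stack([
            1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y),
            2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x),
            2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y),
        ], axis=-1).reshape(-1, 3, 3)
        mob_c = mobile - mobile.mean(axis=0)
        ref_c = reference - reference.mean(axis=0)
        rotated = np.einsum("rij,nj->rni", mats, mob_c)
        return np.sqrt(((rotated - ref_c) ** 2).sum(axis=2).mean(axis=1)), q

    best_q = None
    best = np.inf
    quats = rng.standard_normal((n_coarse, 4))
    vals, q = rmsd_for(quats)
    i = int(np.argmin(vals))
    best, best_q = vals[i], q[i]
    scale = 0.2
    for _ in range(n_refine):
        quats = best_q + scale * rng.standard_normal((n_coarse // 4, 4))
        vals, q = rmsd_for(quats)
        i = int(np.argmin(vals))
        if vals[i] < best:
            best, best_q = vals[i], q[i]
        scale *= 0.3
    return best


class TestSuperposition:
    def test_rotated_copy_gives_zero_rmsd(self, random_rotation):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 10, (20, 3))
        moved = pts @ random_rotation.T + np.array([1.0, 2.0, 3.0])
        fit = superpose(moved, pts)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_four_point_fit_matches_brute_force_oracle(self):
        reference = np.array([[0.0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]])
        mobile = reference.copy()
        mobile[3] += np.array([1.0, 0, 0])  # one point displaced 1 Å
        fit = superpose(mobile, reference)
        oracle = _brute_force_min_rmsd(mobile, reference)
        assert fit.rmsd * 10.0 == pytest.approx(oracle, abs=1e-3)  # Å

    def test_collinear_sets_rejected(self):
        line = np.outer(np.arange(4), [1.0, 0, 0])
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line)

    def test_rmsd_invariant_under_mobile_prerotation(self, random_rotation):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 10, (15, 3))
        b = a + rng.normal(0, 0.5, a.shape)
        r1 = superpose(a, b).rmsd
        r2 = superpose(a @ random_rotation.T, b).rmsd
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_moving_point_onto_reference_never_raises_rmsd(self):
        reference = np.array([[0.0, 0, 0], [4, 0, 0], [0, 4, 0], [2, 2, 3]])
        mobile = reference + np.array([[0.5, 0, 0], [0, 0, 0],
                                       [0, 0, 0], [0, 0, 0]])
        before = superpose(mobile, reference).rmsd
        mobile2 = mobile.copy()
        mobile2[0] = reference[0]
        # after aligning the frames, snap the deviating point onto its pair
        fit = superpose(mobile, reference)
        snapped = apply_superposition(mobile, fit)
        snapped[0] = reference[0]
        after = superpose(snapped, reference).rmsd
        assert after <= before + 1e-12


class TestRmsf:
    def _traj_with_oscillation(self, amplitude):
        rng = np.random.default_rng(5)
        base = rng.uniform(0, 20, (6, 3))
        s = make_structure(base, residue_numbers=np.arange(1, 7))
        frames = np.repeat(base[None], 4, axis=0)
        frames[:, 2, 0] += amplitude * np.array([1, -1, 1, -1])
        return pp.Trajectory(s, frames, np.arange(4.0)), s

    def test_frozen_trajectory_gives_zero(self):
        s = make_structure(np.random.default_rng(6).uniform(0, 9, (5, 3)),
                           residue_numbers=np.arange(1, 6))
        traj = pp.Trajectory(s, np.repeat(s.coordinates[None], 3, axis=0),
                             np.arange(3.0))
        residues, values = pp.rmsf(traj, full_selection(s))
        np.testing.assert_allclose(values, 0.0, atol=1e-12)

    def test_oscillating_residue_closed_form(self):
        traj, s = self._traj_with_oscillation(1.0)
        fixed = pp.AtomSelection(s, np.array([0, 1, 3, 4, 5]), "fit")
        residues, values = pp.rmsf(traj, full_selection(s), fit_sel=fixed)
        assert values[2] == pytest.approx(0.1, abs=1e-6)  # 1 Å -> 0.1 nm
        np.testing.assert_allclose(np.delete(values, 2), 0.0, atol=1e-9)

    def test_rmsf_linear_in_amplitude(self):
        t1, s1 = self._traj_with_oscillation(1.0)
        t2, s2 = self._traj_with_oscillation(2.0)
        fixed1 = pp.AtomSelection(s1, np.array([0, 1, 3, 4, 5]), "fit")
        fixed2 = pp.AtomSelection(s2, np.array([0, 1, 3, 4, 5]), "fit")
        _, v1 = pp.rmsf(t1, full_selection(s1), fit_sel=fixed1)
        _, v2 = pp.rmsf(t2, full_selection(s2), fit_sel=fixed2)
        assert v2[2] == pytest.approx(2 * v1[2], rel=1e-6)

    def test_window_shorter_than_two_frames_rejected(self):
        traj, s = self._traj_with_oscillation(1.0)
        with pytest.raises(ValueError):
            pp.rmsf(traj, full_selection(s), window=(0, 1))
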