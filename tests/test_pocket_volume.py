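"""Grid pocket volume: analytic sphere oracle, invariances, persistence."""

import warnings

import numpy as np
import pytest

import prenylpocket as pp
from prenylpocket.pocket_volume import GridSpec, compute_pocket_volume

from conftest import full_selection, make_structure


@pytest.fixture(scope="module")
def sphere_grid():
    return GridSpec(spacing=0.5, inclusion_spheres=[((0, 0, 0), 9.0)])


class TestSphereOracle:
    def test_closed_cavity_within_5_percent_of_ball_volume(self, cavity_fixture,
                                                           sphere_grid):
        shell, truth = cavity_fixture
        v, _ = compute_pocket_volume(shell.coordinates, full_selection(shell),
                                     sphere_grid)
        assert v == pytest.approx(truth, rel=0.05)

    def test_solid_block_has_zero_volume(self):
        xs = np.arange(-6, 7, 1.5)
        coords = np.array([[x, y, z] for x in xs for y in xs for z in xs])
        block = make_structure(coords, residue_numbers=np.arange(1, len(coords) + 1))
        grid = GridSpec(spacing=1.0, inclusion_spheres=[((0, 0, 0), 4.0)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v, _ = compute_pocket_volume(block.coordinates,
                                         full_selection(block), grid)
        assert v == 0.0

    def test_halving_spacing_changes_volume_below_8_percent(self, cavity_fixture):
        shell, _ = cavity_fixture
        sel = full_selection(shell)
        vols = {}
        for spacing in (1.0, 0.5):
            grid = GridSpec(spacing=spacing,
                            inclusion_spheres=[((0, 0, 0), 9.0)])
            vols[spacing], _ = compute_pocket_volume(shell.coordinates, sel, grid)
        assert abs(vols[0.5] - vols[1.0]) / vols[0.5] < 0.08

    def test_rigid_motion_invariance_with_frame_local_centers(
            self, cavity_fixture, random_rotation):
        shell, _ = cavity_fixture
        sel = full_selection(shell)
        grid = GridSpec(spacing=0.5, inclusion_spheres=[((0, 0, 0), 9.0)])
        v0, _ = compute_pocket_volume(shell.coordinates, sel, grid,
                                      center_sel=sel)
        moved = shell.coordinates @ random_rotation.T + np.array([11.0, -4.0, 7.0])
        v1, _ = compute_pocket_volume(moved, sel, grid, center_sel=sel)
        assert v1 == pytest.approx(v0, rel=0.02)

    def test_nested_cavities_are_monotone(self):
        vols = []
        for r in (4.0, 6.0):
            shell, _ = pp.make_cavity_shell(pp.CavitySpec(inner_radius=r))
            grid = GridSpec(spacing=0.5, inclusion_spheres=[((0, 0, 0), 10.0)])
            v, _ = compute_pocket_volume(shell.coordinates,
                                         full_selection(shell), grid)
            vols.append(v)
        assert vols[0] <= vols[1]

    def test_inclusion_radius_beyond_wall_cannot_increase_volume(self,
                                                                 cavity_fixture):
        shell, _ = cavity_fixture
        sel = full_selection(shell)
        v_small, _ = compute_pocket_volume(
            shell.coordinates, sel,
            GridSpec(spacing=0.5, inclusion_spheres=[((0, 0, 0), 8.0)]))
        v_large, _ = compute_pocket_volume(
            shell.coordinates, sel,
            GridSpec(spacing=0.5, inclusion_spheres=[((0, 0, 0), 14.0)]))
        assert v_large <= v_small * 1.02  # walls bound the cavity


class TestVolumeSeries:
    def _frozen_traj(self, shell, n_frames=3):
        frames = np.repeat(shell.coordinates[None], n_frames, axis=0)
        return pp.Trajectory(shell, frames, np.arange(float(n_frames)))

    def test_frozen_trajectory_sd_zero(self, cavity_fixture):
        shell, _ = cavity_fixture
        traj = self._frozen_traj(shell)
        grid = GridSpec(spacing=1.0, inclusion_spheres=[((0, 0, 0), 9.0)])
        series, mean, sd = pp.volume_series(traj, full_selection(shell), grid)
        assert sd == 0.0
        assert mean == pytest.approx(series.values[0])

    def test_alternating_blocked_cavity_mean_is_half(self, cavity_fixture):
        shell, _ = cavity_fixture
        # frame 2: fill the cavity with a plug of pseudo-atoms
        plug = np.array([[x, y, z] for x in np.arange(-6, 7, 2.0)
                         for y in np.arange(-6, 7, 2.0)
                         for z in np.arange(-6, 7, 2.0)])
        plugged = make_structure(
            np.concatenate([shell.coordinates, plug]),
            residue_numbers=np.arange(1, shell.n_atoms + len(plug) + 1))
        frames = np.stack([
            np.concatenate([shell.coordinates, plug + 100.0]),  # plug far away
            np.concatenate([shell.coordinates, plug]),          # plug inside
        ])
        traj = pp.Trajectory(plugged, frames, np.array([0.0, 1.0]))
        grid = GridSpec(spacing=1.0, inclusion_spheres=[((0, 0, 0), 9.0)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            series, mean, _ = pp.volume_series(traj, full_selection(plugged), grid)
        assert series.values[1] == pytest.approx(0.0, abs=30.0)
        assert mean == pytest.approx(series.values[0] / 2.0, abs=20.0)


class TestPersistentPocket:
    def test_frozen_trajectory_equals_single_frame(self, cavity_fixture):
        shell, _ = cavity_fixture
        frames = np.repeat(shell.coordinates[None], 4, axis=0)
        traj = pp.Trajectory(shell, frames, np.arange(4.0))
        sel = full_selection(shell)
        grid = GridSpec(spacing=1.0, inclusion_spheres=[((0, 0, 0), 9.0)])
        _, single = compute_pocket_volume(shell.coordinates, sel, grid)
        persistent = pp.persistent_pocket(traj, sel, grid, fraction=0.75)
        np.testing.assert_array_equal(persistent.free_mask, single.free_mask)

    def test_threshold_is_greater_equal_rule(self):
        # voxel free in exactly 3 of 4 frames, fraction 0.75 -> included
        shell, _ = pp.make_cavity_shell(pp.CavitySpec(inner_radius=4.0))
        plug = np.zeros((1, 3))  # one atom at the center
        s = make_structure(np.concatenate([shell.coordinates, plug]),
                           residue_numbers=np.arange(1, shell.n_atoms + 2))
        open_frame = np.concatenate([shell.coordinates, plug + 200.0])
        blocked = np.concatenate([shell.coordinates, plug])
        frames = np.stack([open_frame, open_frame, open_frame, blocked])
        traj = pp.Trajectory(s, frames, np.arange(4.0))
        grid = GridSpec(spacing=1.0, inclusion_spheres=[((0, 0, 0), 6.0)])
        p75 = pp.persistent_pocket(traj, full_selection(s), grid, fraction=0.75)
        p100 = pp.persistent_pocket(traj, full_selection(s), grid, fraction=1.0)
        center_voxel = tuple(np.round(
            (np.zeros(3) - p75.origin) / p75.spacing).astype(int))
        assert p75.free_mask[center_voxel]
        assert not p100.free_mask[center_voxel]

    def test_invalid_fraction_rejected(self, cavity_fixture):
        shell, _ = cavity_fixture
        frames = np.repeat(shell.coordinates[None], 2, axis=0)
        traj = pp.Trajectory(shell, frames, np.arange(2.0))
        grid = GridSpec(spacing=1.0, inclusion_spheres=[((0, 0, 0), 9.0)])
        with pytest.raises(ValueError):
            pp.persistent_pocket(traj, full_selection(shell), grid, fraction=0.0)

    def test_exports_write_text_files(self, cavity_fixture, tmp_path):
        shell, _ = cavity_fixture
        grid = GridSpec(spacing=1.0, inclusion_spheres=[((0, 0, 0), 9.0)])
        _, pg = compute_pocket_volume(shell.coordinates, full_selection(shell),
                                      grid)
        from prenylpocket.pocket_volume import (pocket_grid_to_opendx,
                                                pocket_grid_to_pdb)
        pocket_grid_to_pdb(pg, tmp_path / "p.pdb")
        pocket_grid_to_opendx(pg, tmp_path / "p.dx")
        assert (tmp_path / "p.pdb").read_text().startswith("HETATM")
        assert "gridpositions" in (tmp_path / "p.dx").read_text()
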