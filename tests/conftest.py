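"""Shared fixtures: all test inputs are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

import prenylpocket as pp
from prenylpocket.structure_io import Structure


def make_structure(coords, elements=None, residue_numbers=None, chain_ids=None,
                   atom_names=None, res_names=None, hetero=None) -> Structure:
    """Minimal Structure factory for hand-placed atom sets."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    return Structure(
        atom_ids=np.arange(1, n + 1),
        atom_names=np.array(atom_names or ["CA"] * n, dtype=object),
        elements=np.array(elements or ["C"] * n, dtype=object),
        residue_numbers=np.asarray(residue_numbers if residue_numbers is not None
                                   else np.arange(1, n + 1)),
        residue_names=np.array(res_names or ["ALA"] * n, dtype=object),
        chain_ids=np.array(chain_ids or ["A"] * n, dtype=object),
        coordinates=coords,
        hetero=np.asarray(hetero if hetero is not None else [False] * n),
    )


def full_selection(struct: Structure, label: str = "all") -> pp.AtomSelection:
    return pp.AtomSelection(struct, np.arange(struct.n_atoms), label)


@pytest.fixture(scope="session")
def cavity_fixture():
    """Closed spherical cavity, inner radius 6 Å, with analytic volume."""
    shell, truth = pp.make_cavity_shell(pp.CavitySpec(inner_radius=6.0))
    return shell, truth


@pytest.fixture(scope="session")
def tight_open_bundle():
    return pp.make_complex_bundle("tight", "open", n_frames=6, seed=11)


@pytest.fixture(scope="session")
def random_rotation():
    rng = np.random.default_rng(7)
    m = rng.standard_normal((3, 3))
    q, _ = np.linalg.qr(m)
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
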