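"""Shrake–Rupley solvent accessible surface area and buried interface area.

Per-atom SASA is computed by point sampling: a deterministic golden-section
spiral point set is placed on each atom's solvent-extended sphere
(radius = vdW + probe) and the accessible fraction — points not buried inside
any neighbour's extended sphere — scales the sphere area.  No RNG is
involved, so results are bit-reproducible.

Per-residue SASA can be normalized by the Miller et al. Gly-X-Gly tripeptide
reference areas to give relative solvent accessibility; buried interface
area is SASA(A alone) + SASA(B alone) − SASA(A∪B).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .descriptors import DescriptorSeries
from .structure_io import AtomSelection, RegionMap, Trajectory, resolve_region

__all__ = [
    "SasaResult",
    "MILLER_TRIPEPTIDE_SASA",
    "sasa",
    "normalized_residue_sasa",
    "region_sasa",
    "interface_area",
]

#: Reference SASA (Å²) of residue X in a Gly-X-Gly tripeptide
#: (Miller et al., J Mol Biol 1987), used for relative-accessibility
#: normalization.
MILLER_TRIPEPTIDE_SASA: dict[str, float] = {
    "ALA": 113.0, "ARG": 241.0, "ASN": 158.0, "ASP": 151.0, "CYS": 140.0,
    "GLN": 189.0, "GLU": 183.0, "GLY": 85.0, "HIS": 194.0, "ILE": 182.0,
    "LEU": 180.0, "LYS": 211.0, "MET": 204.0, "PHE": 218.0, "PRO": 143.0,
    "SER": 122.0, "THR": 146.0, "TRP": 259.0, "TYR": 229.0, "VAL": 160.0,
}

#: Non-standard residue names mapped onto table entries.  The
#: geranylgeranylated cysteine is normalized against plain Cys: the Miller
#: table has no prenylated entry, and the comparison of interest is the
#: solvent exposure of the amino-acid moiety.
RESIDUE_ALIASES: dict[str, str] = {"CYG": "CYS", "GCY": "CYS", "MSE": "MET"}


def _spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class SasaResult:
    """Per-atom and per-residue solvent accessible surface areas (Å²)."""

    atom_indices: np.ndarray          # indices into the parent structure
    atom_areas: np.ndarray            # (n,) Å²
    residue_keys: list[tuple[str, int]]   # (chain, residue number)
    residue_names: list[str]
    residue_areas: np.ndarray         # (n_res,) Å²
    probe_radius: float
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(self.atom_areas.sum())

    def residue_area(self, chain: str, residue: int) -> float:
        key = (chain, residue)
        return float(self.residue_areas[self.residue_keys.index(key)])


def sasa(frame_coords: np.ndarray | None, sel: AtomSelection,
         probe: float = 1.4, n_points: int = 960,
         include_hydrogens: bool = False) -> SasaResult:
    """Shrake–Rupley SASA of a selection, occluded only by the selection.

    ``frame_coords`` is a full-structure coordinate array (or None for the
    structure's own coordinates).  Hydrogens are dropped by default; vdW radii
    come from the structure's element-based Bondi table.
    """
    if n_points < 50:
        raise ValueError("n_points < 50 is below the accuracy floor")
    struct = sel.structure
    idx = sel.indices
    if not include_hydrogens:
        idx = idx[struct.elements[idx] != "H"]
    if idx.size == 0:
        raise ValueError("sasa: selection contains no (heavy) atoms")
    coords = (struct.coordinates if frame_coords is None else frame_coords)[idx]
    radii = struct.vdw_radii[idx] + probe
    unit = _spiral_points(n_points)

    from scipy.spatial.distance import cdist

    tree = cKDTree(coords)
    r_max = radii.max()
    all_neighbors = tree.query_ball_point(coords, radii + r_max, workers=-1)
    areas = np.empty(len(idx))
    for a in range(len(idx)):
        nb = np.asarray([j for j in all_neighbors[a] if j != a], dtype=int)
        if nb.size:
            pts = coords[a] + radii[a] * unit
            buried = (cdist(pts, coords[nb]) < radii[nb]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[a] = frac * 4.0 * np.pi * radii[a] ** 2

    keys: list[tuple[str, int]] = []
    names: list[str] = []
    sums: list[float] = []
    order: dict[tuple[str, int], int] = {}
    for a, g in enumerate(idx):
        key = (str(struct.chain_ids[g]), int(struct.residue_numbers[g]))
        if key not in order:
            order[key] = len(keys)
            keys.append(key)
            names.append(str(struct.residue_names[g]))
            sums.append(0.0)
        sums[order[key]] += areas[a]
    return SasaResult(atom_indices=idx, atom_areas=areas,
                      residue_keys=keys, residue_names=names,
                      residue_areas=np.asarray(sums),
                      probe_radius=probe, n_sphere_points=n_points)


def normalized_residue_sasa(result: SasaResult,
                            table: dict[str, float] | None = None,
                            aliases: dict[str, str] | None = None) -> np.ndarray:
    """Per-residue SASA divided by the Gly-X-Gly reference value.

    Fractions are ~0–1 for interior residues and may exceed 1 at chain
    termini.  Residue types absent from the table (after alias mapping) are
    a hard error.
    """
    table = table if table is not None else MILLER_TRIPEPTIDE_SASA
    aliases = aliases if aliases is not None else RESIDUE_ALIASES
    fractions = np.empty(len(result.residue_keys))
    for i, name in enumerate(result.residue_names):
        ref = table.get(name) or table.get(aliases.get(name, ""))
        if ref is None:
            chain, res = result.residue_keys[i]
            raise ValueError(
                f"no tripeptide reference SASA for residue {name} "
                f"{chain}:{res}; extend the table or alias map")
        fractions[i] = result.residue_areas[i] / ref
    return fractions


def region_sasa(traj: Trajectory, regions: RegionMap, names: list[str],
                window: tuple[int, int] | None = None, probe: float = 1.4,
                n_points: int = 960,
                context_sel: AtomSelection | None = None,
                ) -> dict[str, DescriptorSeries]:
    """Per-frame summed residue SASA (Å²) for each named region.

    SASA is evaluated in the full complex context (all heavy atoms of the
    structure by default, or ``context_sel``), then summed over the region's
    residues — so burial by the partner protein is reflected.
    """
    struct = traj.structure
    if context_sel is None:
        context_sel = AtomSelection(struct, np.arange(struct.n_atoms), "all")
    region_sels = {name: resolve_region(struct, regions, name, atom_filter="heavy")
                   for name in names}
    idx = traj.window(frame_range=window) if window else np.arange(traj.n_frames)
    out = {name: np.empty(len(idx)) for name in names}
    for k, f in enumerate(idx):
        result = sasa(traj.frames[f], context_sel, probe=probe, n_points=n_points)
        area_of = dict(zip(result.residue_keys, result.residue_areas))
        for name, rsel in region_sels.items():
            keys = {(str(struct.chain_ids[g]), int(struct.residue_numbers[g]))
                    for g in rsel.indices}
            out[name][k] = sum(area_of.get(key, 0.0) for key in keys)
    times = traj.frame_times[idx]
    return {name: DescriptorSeries(f"sasa_{name}", vals, "Å²", times)
            for name, vals in out.items()}


def interface_area(frame_coords: np.ndarray | None, sel_a: AtomSelection,
                   sel_b: AtomSelection, probe: float = 1.4,
                   n_points: int = 960, halved: bool = False) -> float:
    """Buried interface area (Å²): SASA(A) + SASA(B) − SASA(A∪B).

    Reported un-halved by default; ``halved=True`` gives the
    per-protein-surface convention.
    """
    if np.intersect1d(sel_a.indices, sel_b.indices).size:
        raise ValueError("interface_area: selections overlap")
    union = AtomSelection(sel_a.structure,
                          np.sort(np.concatenate([sel_a.indices, sel_b.indices])),
                          label="complex")
    area_a = sasa(frame_coords, sel_a, probe=probe, n_points=n_points).total
    area_b = sasa(frame_coords, sel_b, probe=probe, n_points=n_points).total
    area_ab = sasa(frame_coords, union, probe=probe, n_points=n_points).total
    buried = area_a + area_b - area_ab
    return buried / 2.0 if halved else buried
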