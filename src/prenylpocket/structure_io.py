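"""Structures, trajectories, residue regions and sequence comparison.

The in-memory model is deliberately small: a :class:`Structure` is a set of
atoms with coordinates and PDB-style metadata (author residue numbering is
authoritative throughout), a :class:`Trajectory` is an ordered stack of
coordinate frames over a fixed atom set, and an :class:`AtomSelection` is an
index list into a parent structure.  All lengths are Ångström internally;
descriptor layers convert to nm on output where the field convention uses nm.

PDB reading/writing is delegated to biotite, DCD/XTC to MDAnalysis, and
pairwise global sequence alignment to Biopython.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Structure",
    "Trajectory",
    "AtomSelection",
    "RegionMap",
    "DEFAULT_REGIONS",
    "load_structure",
    "save_structure",
    "load_trajectory",
    "save_trajectory",
    "resolve_region",
    "read_fasta",
    "count_sequence_differences",
    "VDW_RADII",
    "ATOMIC_MASSES",
]

# Bondi-type van der Waals radii (Å) by element symbol.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "CA": 2.31, "ZN": 1.39,
    "MN": 2.05, "FE": 2.05, "CU": 1.40, "NI": 1.63, "CO": 2.00,
}

# Standard atomic weights (u) for mass-weighted centroids.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "SE": 78.971, "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078,
    "ZN": 65.38, "MN": 54.938, "FE": 55.845, "CU": 63.546, "NI": 58.693,
    "CO": 58.933,
}


class StructureError(ValueError):
    """Raised for unreadable or inconsistent structural input."""


def _normalize_element(element: str, atom_name: str, index: int) -> str:
    """Return a canonical element symbol, inferring from the atom name if the
    PDB element column is blank.  Raises for atoms that cannot be resolved."""
    sym = element.strip().upper()
    if not sym:
        name = atom_name.strip().lstrip("0123456789")
        if len(name) >= 2 and name[:2].upper() in VDW_RADII and name[:2].upper() not in {
            "CA", "CO", "NI", "SE",  # ambiguous with Cα / carbonyl / amide names
        }:
            sym = name[:2].upper()
        elif name and name[0].upper() in VDW_RADII:
            sym = name[0].upper()
    if sym not in VDW_RADII:
        raise StructureError(
            f"atom {index} ({atom_name!r}): element {element!r} has no "
            f"van der Waals radius; known elements: {sorted(VDW_RADII)}"
        )
    return sym


@dataclass
class Structure:
    """Static atom set with coordinates and PDB metadata.

    ``residue_numbers`` carry author numbering; ``hetero`` flags HETATM
    records (prenyl chains, ligands) so they can be excluded from protein
    selections or explicitly picked up.
    """

    atom_ids: np.ndarray          # (n,) int
    atom_names: np.ndarray        # (n,) str
    elements: np.ndarray          # (n,) str, canonical symbols
    residue_numbers: np.ndarray   # (n,) int, author numbering
    residue_names: np.ndarray     # (n,) str, 3-letter
    chain_ids: np.ndarray         # (n,) str
    coordinates: np.ndarray       # (n, 3) float, Å
    hetero: np.ndarray            # (n,) bool
    insertion_codes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        n = self.coordinates.shape[0]
        for name in ("atom_ids", "atom_names", "elements", "residue_numbers",
                     "residue_names", "chain_ids", "hetero"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise StructureError(f"{name} has length {arr.shape[0]}, expected {n}")
            setattr(self, name, arr)
        if self.insertion_codes is None:
            self.insertion_codes = np.array([""] * n, dtype=object)
        if not np.isfinite(self.coordinates).all():
            bad = np.where(~np.isfinite(self.coordinates).all(axis=1))[0]
            raise StructureError(f"non-finite coordinates at atom indices {bad[:5].tolist()}")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    def __len__(self) -> int:
        return self.n_atoms

    def _lookup(self, table: dict[str, float], what: str) -> np.ndarray:
        out = np.empty(self.n_atoms)
        for i, e in enumerate(self.elements):
            try:
                out[i] = table[str(e).upper()]
            except KeyError:
                raise StructureError(
                    f"atom {self.atom_ids[i]} ({self.atom_names[i]!r}): "
                    f"element {e!r} has no {what}") from None
        return out

    @property
    def vdw_radii(self) -> np.ndarray:
        """Per-atom Bondi radii (Å)."""
        return self._lookup(VDW_RADII, "van der Waals radius")

    @property
    def masses(self) -> np.ndarray:
        """Per-atom standard atomic weights (u)."""
        return self._lookup(ATOMIC_MASSES, "atomic mass")

    def subset(self, indices: Sequence[int]) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(
            atom_ids=self.atom_ids[idx],
            atom_names=self.atom_names[idx],
            elements=self.elements[idx],
            residue_numbers=self.residue_numbers[idx],
            residue_names=self.residue_names[idx],
            chain_ids=self.chain_ids[idx],
            coordinates=self.coordinates[idx],
            hetero=self.hetero[idx],
            insertion_codes=np.asarray(self.insertion_codes, dtype=object)[idx],
        )

    def with_coordinates(self, coords: np.ndarray) -> "Structure":
        return replace(self, coordinates=np.asarray(coords, dtype=float))


@dataclass
class AtomSelection:
    """Ordered, unique atom-index list into a parent :class:`Structure`."""

    structure: Structure
    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= self.structure.n_atoms):
            raise StructureError(f"selection {self.label!r}: atom index out of range")
        if len(np.unique(idx)) != len(idx):
            raise StructureError(f"selection {self.label!r}: duplicate atom indices")
        self.indices = idx

    def __len__(self) -> int:
        return len(self.indices)

    def coordinates(self, frame: np.ndarray | None = None) -> np.ndarray:
        coords = self.structure.coordinates if frame is None else frame
        return coords[self.indices]

    @property
    def masses(self) -> np.ndarray:
        return self.structure.masses[self.indices]


@dataclass
class Trajectory:
    """Time-ordered coordinate frames (Å) over a fixed topology; times in ns."""

    structure: Structure
    frames: np.ndarray       # (n_frames, n_atoms, 3)
    frame_times: np.ndarray  # (n_frames,) ns, strictly increasing

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise StructureError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.structure.n_atoms:
            raise StructureError(
                f"frame atom count {self.frames.shape[1]} != topology atom count "
                f"{self.structure.n_atoms}"
            )
        if self.frames.shape[0] != self.frame_times.shape[0]:
            raise StructureError("frame_times length must match frame count")
        if len(self.frame_times) > 1 and not (np.diff(self.frame_times) > 0).all():
            raise StructureError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def window(self, discard_fraction: float = 0.0,
               frame_range: tuple[int, int] | None = None) -> np.ndarray:
        """Frame indices of the analysis window.

        ``discard_fraction`` drops the leading equilibration portion of the
        trajectory (default pipeline choice: 0.2, mirroring a 50 ns discard on
        a 250 ns run); ``frame_range`` overrides with an explicit [start, stop).
        """
        if frame_range is not None:
            start, stop = frame_range
            if not (0 <= start < stop <= self.n_frames):
                raise StructureError(f"frame range {frame_range} outside [0, {self.n_frames})")
            return np.arange(start, stop)
        start = int(np.floor(discard_fraction * self.n_frames))
        return np.arange(start, self.n_frames)


# ---------------------------------------------------------------------------
# Region definitions
# ---------------------------------------------------------------------------

#: Default residue regions for the Rab5:GDI system (author numbering).
#: Rab regions live on the Rab chain, gdi_* on the GDI chain; which chain is
#: which is bound at resolve time via RegionMap.chain_of.
DEFAULT_REGIONS: dict[str, list[int]] = {
    "rab_gdomain": list(range(16, 185)),
    "switch1": list(range(44, 67)),
    "switch2": list(range(75, 92)),
    "hvr": list(range(190, 216)),
    "gg_cys": [212, 213],
    "gdi_h1": list(range(122, 130)),
    "gdi_rbp": list(range(226, 256)),
    "gdi_helix_rbp": list(range(230, 247)),
    "gdi_mel": list(range(215, 222)),
    "gdi_met132": [132],
    "gdi_ccr": [88, 92, 97, 98, 102, 103, 104, 218, 219, 225, 439, 447],
}


class RegionMap:
    """Named residue regions: name -> (chain or None, residue number list).

    Construct from a mapping whose values are either ``[start, stop]``
    inclusive ranges, explicit residue lists, or ``{"chain": X, "residues":
    [...]}`` / ``{"chain": X, "range": [a, b]}`` dicts.  Names not supplied
    fall back to :data:`DEFAULT_REGIONS` (chain unbound).  ``gdi_h2`` and
    ``gdi_h3`` have no default and must come from configuration.
    """

    def __init__(self, entries: Mapping[str, object] | None = None,
                 use_defaults: bool = True) -> None:
        self._regions: dict[str, tuple[str | None, list[int]]] = {}
        if use_defaults:
            for name, residues in DEFAULT_REGIONS.items():
                self._regions[name] = (None, list(residues))
        for name, value in (entries or {}).items():
            self._regions[name] = self._parse_entry(name, value)

    @staticmethod
    def _parse_entry(name: str, value: object) -> tuple[str | None, list[int]]:
        chain: str | None = None
        if isinstance(value, Mapping):
            chain = value.get("chain")
            if "range" in value:
                a, b = value["range"]
                residues = list(range(int(a), int(b) + 1))
            else:
                residues = [int(r) for r in value["residues"]]
        elif isinstance(value, (list, tuple)):
            residues = [int(r) for r in value]
        else:
            raise StructureError(f"region {name!r}: cannot parse definition {value!r}")
        if not residues:
            raise StructureError(f"region {name!r}: empty residue list")
        return chain, residues

    def __contains__(self, name: str) -> bool:
        return name in self._regions

    def names(self) -> list[str]:
        return sorted(self._regions)

    def residues(self, name: str) -> list[int]:
        if name not in self._regions:
            raise KeyError(
                f"region {name!r} is not defined; known regions: {self.names()}"
            )
        return list(self._regions[name][1])

    def chain_of(self, name: str) -> str | None:
        if name not in self._regions:
            raise KeyError(f"region {name!r} is not defined")
        return self._regions[name][0]

    def with_chain(self, chain_assignments: Mapping[str, str]) -> "RegionMap":
        """Return a copy with region-name-prefix -> chain bindings applied
        (e.g. ``{"rab": "A", "gdi": "B"}`` binds rab_*/switch*/hvr/gg_cys to A)."""
        out = RegionMap(use_defaults=False)
        rab_names = {"rab_gdomain", "switch1", "switch2", "hvr", "gg_cys"}
        for name, (chain, residues) in self._regions.items():
            if chain is None:
                if name.startswith("gdi") and "gdi" in chain_assignments:
                    chain = chain_assignments["gdi"]
                elif name in rab_names and "rab" in chain_assignments:
                    chain = chain_assignments["rab"]
            out._regions[name] = (chain, list(residues))
        return out


def resolve_region(structure: Structure, regions: RegionMap, name: str,
                   atom_filter: str = "all", include_hetero: bool = False) -> AtomSelection:
    """Resolve a named region to an :class:`AtomSelection`.

    ``atom_filter``: ``all`` | ``heavy`` (no hydrogens) | ``CA`` (Cα only).
    HETATM atoms are excluded unless ``include_hetero`` — prenyl/ligand atoms
    are tracked as a separate moiety and must be requested explicitly.
    Matching zero atoms is a hard error; silent empty selections are forbidden.
    """
    residues = regions.residues(name)
    chain = regions.chain_of(name)
    mask = np.isin(structure.residue_numbers, residues)
    if chain is not None:
        mask &= structure.chain_ids == chain
    if not include_hetero:
        mask &= ~structure.hetero
    if atom_filter == "CA":
        mask &= structure.atom_names == "CA"
    elif atom_filter == "heavy":
        mask &= structure.elements != "H"
    elif atom_filter != "all":
        raise StructureError(f"unknown atom filter {atom_filter!r}")
    indices = np.flatnonzero(mask)
    if indices.size == 0:
        raise StructureError(
            f"region {name!r} (chain {chain!r}, residues "
            f"{residues[0]}..{residues[-1]}, filter {atom_filter}) matched no atoms"
        )
    return AtomSelection(structure, indices, label=name)


# ---------------------------------------------------------------------------
# PDB I/O (biotite)
# ---------------------------------------------------------------------------

def _atomarray_to_structure(atoms) -> Structure:
    import biotite.structure as struc

    n = atoms.array_length()
    atom_ids = (atoms.get_annotation("atom_id")
                if "atom_id" in atoms.get_annotation_categories()
                else np.arange(1, n + 1))
    elements = np.array([
        _normalize_element(e, a, i)
        for i, (e, a) in enumerate(zip(atoms.element, atoms.atom_name))
    ], dtype=object)
    ins = (atoms.get_annotation("ins_code")
           if "ins_code" in atoms.get_annotation_categories()
           else np.array([""] * n, dtype=object))
    return Structure(
        atom_ids=np.asarray(atom_ids, dtype=int),
        atom_names=np.asarray(atoms.atom_name, dtype=object),
        elements=elements,
        residue_numbers=np.asarray(atoms.res_id, dtype=int),
        residue_names=np.asarray(atoms.res_name, dtype=object),
        chain_ids=np.asarray(atoms.chain_id, dtype=object),
        coordinates=np.asarray(atoms.coord, dtype=float),
        hetero=np.asarray(atoms.hetero, dtype=bool),
        insertion_codes=np.asarray(ins, dtype=object),
    )


def load_structure(path: str | Path, format: str = "pdb", model: int = 1) -> Structure:
    """Read a structure from a PDB file.

    Author residue numbering and HETATM flags are preserved; alternate
    locations are resolved to the highest-occupancy conformer (ties -> "A").
    """
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    if format != "pdb":
        raise StructureError(f"unsupported structure format {format!r}")
    if not path.exists():
        raise StructureError(f"structure file not found: {path}")
    try:
        pdb_file = pdb.PDBFile.read(str(path))
        atoms = pdb_file.get_structure(
            model=model, altloc="occupancy", extra_fields=["atom_id"]
        )
    except Exception as exc:  # biotite raises several parse-error types
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc
    return _atomarray_to_structure(atoms)


def _structure_to_atomarray(structure: Structure):
    import biotite.structure as struc

    atoms = struc.AtomArray(structure.n_atoms)
    atoms.coord = np.asarray(structure.coordinates, dtype=np.float32)
    atoms.chain_id = np.asarray(structure.chain_ids, dtype="U4")
    atoms.res_id = np.asarray(structure.residue_numbers, dtype=int)
    atoms.res_name = np.asarray(structure.residue_names, dtype="U5")
    atoms.atom_name = np.asarray(structure.atom_names, dtype="U6")
    atoms.element = np.asarray(structure.elements, dtype="U2")
    atoms.hetero = np.asarray(structure.hetero, dtype=bool)
    atoms.set_annotation("atom_id", np.asarray(structure.atom_ids, dtype=int))
    return atoms


def save_structure(structure: Structure, path: str | Path) -> Path:
    """Write a Structure to PDB (ATOM/HETATM with author numbering)."""
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(_structure_to_atomarray(structure))
    pdb_file.write(str(path))
    return path


# ---------------------------------------------------------------------------
# Trajectory I/O (MDAnalysis for DCD/XTC, biotite for multi-model PDB)
# ---------------------------------------------------------------------------

def load_trajectory(topology: str | Path, coords: str | Path | None = None,
                    format: str | None = None, frame_dt: float = 1.0) -> Trajectory:
    """Read a trajectory: topology PDB plus DCD/XTC coordinates, or a
    multi-model PDB doing double duty.  ``frame_dt`` is the frame spacing in
    ns; frame times are ``index * frame_dt``.
    """
    topology = Path(topology)
    structure = load_structure(topology)
    if coords is None or str(coords) == str(topology):
        frames = _read_multimodel_frames(topology)
    else:
        coords = Path(coords)
        fmt = (format or coords.suffix.lstrip(".")).lower()
        if fmt in ("pdb", "multimodel-pdb"):
            frames = _read_multimodel_frames(coords)
        elif fmt in ("dcd", "xtc"):
            frames = _read_mdanalysis_frames(topology, coords)
        else:
            raise StructureError(f"unsupported trajectory format {fmt!r}")
    if frames.shape[1] != structure.n_atoms:
        raise StructureError(
            f"atom count mismatch: topology has {structure.n_atoms} atoms, "
            f"coordinate frames have {frames.shape[1]}"
        )
    times = np.arange(frames.shape[0]) * float(frame_dt)
    return Trajectory(structure=structure, frames=frames, frame_times=times)


def _read_multimodel_frames(path: Path) -> np.ndarray:
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure(altloc="occupancy")
    coord = np.asarray(stack.coord, dtype=float)
    if coord.ndim == 2:
        coord = coord[None]
    return coord


def _read_mdanalysis_frames(topology: Path, coords: Path) -> np.ndarray:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology), str(coords))
        return np.array([ts.positions.copy() for ts in u.trajectory], dtype=float)


def save_trajectory(traj: Trajectory, topology_path: str | Path,
                    coords_path: str | Path, format: str | None = None) -> tuple[Path, Path]:
    """Write topology PDB plus coordinates (DCD, XTC or multi-model PDB)."""
    topology_path = Path(topology_path)
    coords_path = Path(coords_path)
    save_structure(traj.structure, topology_path)
    fmt = (format or coords_path.suffix.lstrip(".")).lower()
    if fmt in ("pdb", "multimodel-pdb"):
        _write_multimodel(traj, coords_path)
    elif fmt in ("dcd", "xtc"):
        _write_mdanalysis(traj, topology_path, coords_path)
    else:
        raise StructureError(f"unsupported trajectory format {fmt!r}")
    return topology_path, coords_path


def _write_multimodel(traj: Trajectory, path: Path) -> None:
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    template = _structure_to_atomarray(traj.structure)
    stack = struc.stack([template] * traj.n_frames)
    stack.coord = np.asarray(traj.frames, dtype=np.float32)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def _write_mdanalysis(traj: Trajectory, topology_path: Path, path: Path) -> None:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology_path))
        with mda.Writer(str(path), n_atoms=traj.structure.n_atoms) as writer:
            for frame in traj.frames:
                u.atoms.positions = frame
                writer.write(u.atoms)


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences from FASTA as an {id: sequence} dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def count_sequence_differences(seq_a: str, seq_b: str) -> tuple[float, int, int]:
    """Globally align two amino-acid sequences and count differences.

    Scoring: match +1, mismatch 0, linear gap −1.  Returns
    ``(identity_percent, n_substitutions, n_indels)`` with identity defined as
    matches / alignment length × 100.  The motivating comparison is the
    human-vs-bovine GDIα pair, which differs by a handful of substitutions at
    >98 % identity.
    """
    from Bio import Align

    for label, seq in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not seq:
            raise ValueError(f"{label} is empty")
        for pos, ch in enumerate(seq):
            if ch.upper() not in _AA_ALPHABET:
                raise ValueError(
                    f"{label}: illegal amino-acid character {ch!r} at position {pos}"
                )
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    alignment = aligner.align(seq_a, seq_b)[0]
    a, b = alignment[0], alignment[1]
    matches = substitutions = indels = 0
    for ca, cb in zip(a, b):
        if ca == "-" or cb == "-":
            indels += 1
        elif ca == cb:
            matches += 1
        else:
            substitutions += 1
    identity = 100.0 * matches / len(a)
    return identity, substitutions, indels
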