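"""Synthetic structures and trajectories with analytically known ground truth.

Every analysis stage in this package (descriptors, pocket volume, SASA,
contacts, classification) can be exercised on the fixtures built here without
any MD engine or structure download:

* ideal poly-alanine Cα helices at prescribed mutual angles,
* spherical pseudo-atom shells enclosing cavities of known volume,
* rigid two-body trajectories following a center-of-mass distance schedule,
* scripted per-residue contact schedules,
* near-identical sequence pairs with a planted number of substitutions,
* a toy Rab:GDI-like complex with planted binding-mode and pocket-state
  ground truth for end-to-end pipeline runs.

All generators are seed-deterministic and emit regular :class:`Structure` /
:class:`Trajectory` objects that round-trip through the standard formats.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .structure_io import (
    VDW_RADII,
    RegionMap,
    Structure,
    StructureError,
    Trajectory,
)

__all__ = [
    "HelixSpec",
    "CavitySpec",
    "ContactSchedule",
    "make_ideal_helix",
    "make_cavity_shell",
    "make_two_body_trajectory",
    "make_contact_trajectory",
    "make_mutated_pair",
    "make_complex_bundle",
    "ComplexBundle",
]

# Canonical α-helix Cα geometry.
HELIX_RADIUS = 2.3          # Å, Cα distance from the helix axis
DEFAULT_RISE = 1.5          # Å per residue
DEFAULT_TWIST = 100.0       # degrees per residue

#: Occupancy padding the cavity-shell ground-truth formula assumes (matches
#: the pocket-volume grid default).
SHELL_REFERENCE_PADDING = 1.09
SHELL_ATOM_ELEMENT = "C"    # carbon pseudo-atoms, vdW 1.70 Å


def _rotation_from_z(direction: np.ndarray) -> np.ndarray:
    """Proper rotation taking +z onto ``direction`` (unit vector)."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, d)
    c = float(np.dot(z, d))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _ca_structure(coords: np.ndarray, residue_numbers, chain_id: str = "A",
                  res_name: str = "ALA", atom_name: str = "CA",
                  element: str = "C", hetero: bool = False,
                  first_atom_id: int = 1) -> Structure:
    n = len(coords)
    return Structure(
        atom_ids=np.arange(first_atom_id, first_atom_id + n),
        atom_names=np.array([atom_name] * n, dtype=object),
        elements=np.array([element] * n, dtype=object),
        residue_numbers=np.asarray(residue_numbers, dtype=int),
        residue_names=np.array([res_name] * n, dtype=object),
        chain_ids=np.array([chain_id] * n, dtype=object),
        coordinates=np.asarray(coords, dtype=float),
        hetero=np.array([hetero] * n, dtype=bool),
    )


def concat_structures(*parts: Structure) -> Structure:
    """Concatenate structures, renumbering atom ids serially."""
    return Structure(
        atom_ids=np.arange(1, sum(p.n_atoms for p in parts) + 1),
        atom_names=np.concatenate([p.atom_names for p in parts]),
        elements=np.concatenate([p.elements for p in parts]),
        residue_numbers=np.concatenate([p.residue_numbers for p in parts]),
        residue_names=np.concatenate([p.residue_names for p in parts]),
        chain_ids=np.concatenate([p.chain_ids for p in parts]),
        coordinates=np.concatenate([p.coordinates for p in parts]),
        hetero=np.concatenate([p.hetero for p in parts]),
    )


@dataclass
class HelixSpec:
    """Ideal α-helix parameters (Cα-only poly-alanine)."""

    n_residues: int
    rise_per_residue: float = DEFAULT_RISE
    twist_per_residue: float = DEFAULT_TWIST
    axis_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    chain_id: str = "A"
    first_residue: int = 1

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise ValueError("a helix needs at least 4 residues")
        norm = float(np.linalg.norm(self.axis_direction))
        if abs(norm - 1.0) > 1e-6:
            self.axis_direction = tuple(np.asarray(self.axis_direction) / norm)


def make_ideal_helix(spec: HelixSpec) -> Structure:
    """Cα-only ideal helix whose least-squares axis matches the spec axis.

    Residues are laid on the canonical helix (radius 2.3 Å, rise 1.5 Å/res,
    twist 100°/res) along +z, then rotated onto ``axis_direction`` and
    translated to ``origin``.  Helix start (residue 1) is at the origin end,
    so the N→C direction equals the axis direction.
    """
    i = np.arange(spec.n_residues)
    phi = np.deg2rad(spec.twist_per_residue) * i
    local = np.column_stack([
        HELIX_RADIUS * np.cos(phi),
        HELIX_RADIUS * np.sin(phi),
        spec.rise_per_residue * i,
    ])
    local -= local.mean(axis=0)  # center before rotation for clean placement
    # A fractional final turn tilts the least-squares (PCA) axis away from z
    # by a couple of degrees; counter-rotate so the fitted axis is exactly z
    # before orienting, keeping the generator's axis contract exact.
    _, _, vt = np.linalg.svd(local, full_matrices=False)
    pca_axis = vt[0] if np.dot(vt[0], local[-1] - local[0]) > 0 else -vt[0]
    local = local @ _rotation_from_z(pca_axis)  # maps pca_axis -> z
    rot = _rotation_from_z(np.asarray(spec.axis_direction))
    coords = local @ rot.T + np.asarray(spec.origin, dtype=float)
    residues = np.arange(spec.first_residue, spec.first_residue + spec.n_residues)
    return _ca_structure(coords, residues, chain_id=spec.chain_id)


@dataclass
class CavitySpec:
    """Spherical pseudo-atom shell enclosing an empty ball.

    ``mouth_solid_angle`` (steradians) opens a cone-shaped mouth around +z;
    0 keeps the shell fully closed.
    """

    inner_radius: float
    shell_thickness: float = 1.7
    shell_atom_spacing: float = 1.0
    mouth_solid_angle: float = 0.0

    def __post_init__(self) -> None:
        if self.inner_radius < 2.0:
            raise ValueError("inner_radius must be at least probe scale (2 Å)")
        max_spacing = VDW_RADII[SHELL_ATOM_ELEMENT]
        if self.shell_atom_spacing > max_spacing:
            raise ValueError(
                f"shell_atom_spacing {self.shell_atom_spacing} Å would leak: "
                f"must be <= vdW radius {max_spacing} Å of the wall atoms"
            )


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_cavity_shell(spec: CavitySpec, center=(0.0, 0.0, 0.0),
                      chain_id: str = "A", residue_numbers=None,
                      res_name: str = "SHL") -> tuple[Structure, float]:
    """Build a shell of carbon pseudo-atoms around an empty ball.

    Wall-atom centers sit at ``inner_radius + r_vdW(C) + 1.09 Å`` so that,
    under the default grid occupancy padding (1.09 Å), the free interior is
    exactly the ball of radius ``inner_radius``; the returned ground truth is
    therefore ``4/3 π inner_radius³`` with no residual wall correction.
    """
    r_wall = spec.inner_radius + VDW_RADII[SHELL_ATOM_ELEMENT] + SHELL_REFERENCE_PADDING
    layers = max(1, int(np.ceil(spec.shell_thickness / spec.shell_atom_spacing)))
    points = []
    for layer in range(layers):
        radius = r_wall + layer * spec.shell_atom_spacing
        n = max(32, int(np.ceil(4.0 * np.pi * radius**2 / spec.shell_atom_spacing**2)))
        points.append(radius * _fibonacci_sphere(n))
    coords = np.concatenate(points) + np.asarray(center, dtype=float)
    if spec.mouth_solid_angle > 0.0:
        # remove wall atoms inside the mouth cone around +z
        cos_half = 1.0 - spec.mouth_solid_angle / (2.0 * np.pi)
        rel = coords - np.asarray(center, dtype=float)
        keep = rel[:, 2] / np.linalg.norm(rel, axis=1) < cos_half
        coords = coords[keep]
        if len(coords) == 0:
            raise ValueError("mouth_solid_angle removed the entire shell")
    if residue_numbers is None:
        residues = np.arange(1, len(coords) + 1)
    else:
        residues = np.resize(np.asarray(residue_numbers, dtype=int), len(coords))
    shell = _ca_structure(coords, residues, chain_id=chain_id,
                          res_name=res_name, atom_name="PS", element="C")
    true_volume = 4.0 / 3.0 * np.pi * spec.inner_radius**3
    return shell, float(true_volume)


def make_two_body_trajectory(distance_schedule, body_a: Structure,
                             body_b: Structure, direction=(1.0, 0.0, 0.0),
                             frame_dt: float = 1.0,
                             mass_weighted: bool = True) -> Trajectory:
    """Rigid two-body trajectory with a prescribed COM-distance schedule.

    Per frame, body B is translated along ``direction`` so that the
    (mass-weighted) center-of-mass separation equals the scheduled value (Å)
    exactly; both bodies stay internally rigid.
    """
    schedule = np.asarray(distance_schedule, dtype=float)
    if (schedule < 0).any():
        raise ValueError("distance schedule contains negative distances")
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)

    def com(s: Structure) -> np.ndarray:
        w = s.masses if mass_weighted else np.ones(s.n_atoms)
        return np.average(s.coordinates, axis=0, weights=w)

    combined = concat_structures(body_a, body_b)
    offset0 = com(body_b) - com(body_a)
    frames = np.empty((len(schedule), combined.n_atoms, 3))
    na = body_a.n_atoms
    for k, d in enumerate(schedule):
        shift = d * u - offset0
        frames[k, :na] = body_a.coordinates
        frames[k, na:] = body_b.coordinates + shift
    first = frames[0] if len(frames) else combined.coordinates
    combined = combined.with_coordinates(first.copy())
    times = np.arange(len(schedule)) * float(frame_dt)
    return Trajectory(structure=combined, frames=frames, frame_times=times)


@dataclass
class ContactSchedule:
    """Scripted per-residue contact intervals.

    ``intervals`` maps residue number -> list of [start, stop) frame windows
    during which that residue sits within contact range of the partner.
    """

    n_frames: int
    intervals: dict[int, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for res, spans in self.intervals.items():
            spans = sorted(tuple(s) for s in spans)
            prev_stop = -1
            for start, stop in spans:
                if not (0 <= start < stop <= self.n_frames):
                    raise ValueError(
                        f"residue {res}: interval [{start}, {stop}) outside "
                        f"[0, {self.n_frames})"
                    )
                if start < prev_stop:
                    raise ValueError(f"residue {res}: overlapping intervals")
                prev_stop = stop
            self.intervals[res] = spans

    def occupancy_row(self, residue: int) -> np.ndarray:
        row = np.zeros(self.n_frames, dtype=bool)
        for start, stop in self.intervals.get(residue, []):
            row[start:stop] = True
        return row


def make_contact_trajectory(schedule: ContactSchedule, cutoff: float = 3.0,
                            frame_dt: float = 1.0) -> Trajectory:
    """Trajectory realizing a scripted contact schedule.

    The partner group is one carbon at the origin (chain B, residue 1); each
    scheduled residue contributes one Cα probe on chain A that sits at
    0.8×cutoff from the partner while "in contact" and at 3×cutoff otherwise.
    Each residue uses its own direction so probes never crowd each other.
    """
    residues = sorted(schedule.intervals)
    if not residues:
        raise ValueError("contact schedule is empty")
    directions = _fibonacci_sphere(max(len(residues), 4))[: len(residues)]
    partner = _ca_structure(np.zeros((1, 3)), [1], chain_id="B", res_name="PRT")
    probes0 = np.array([3.0 * cutoff * d for d in directions])
    probe_struct = _ca_structure(probes0, residues, chain_id="A")
    combined = concat_structures(probe_struct, partner)
    frames = np.empty((schedule.n_frames, combined.n_atoms, 3))
    for f in range(schedule.n_frames):
        for j, res in enumerate(residues):
            dist = 0.8 * cutoff if schedule.occupancy_row(res)[f] else 3.0 * cutoff
            frames[f, j] = dist * directions[j]
        frames[f, -1] = 0.0
    times = np.arange(schedule.n_frames) * float(frame_dt)
    return Trajectory(structure=combined, frames=frames, frame_times=times)


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NERF placement: position D bonded to c with given internal coordinates
    (b-c-D angle, a-b-c-D dihedral)."""
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(chi),
        bond * np.sin(theta) * np.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def make_extended_peptide(sequence: str, chain_id: str = "A") -> Structure:
    """Fully extended (all-trans) peptide backbone with Cβ side-chain stubs.

    Standard bond geometry, φ = ψ = ω = 180°; heavy backbone atoms N, CA, C,
    O plus CB for non-glycine residues (larger side chains are represented by
    their Cβ only).  Intended as the reference-state approximation for
    Gly-X-Gly tripeptide SASA normalization tests.
    """
    coords: list[np.ndarray] = []
    names: list[str] = []
    elements: list[str] = []
    res_ids: list[int] = []
    res_names: list[str] = []

    def add(name, element, pos, res_i, res3):
        coords.append(pos)
        names.append(name)
        elements.append(element)
        res_ids.append(res_i)
        res_names.append(res3)

    prev_c = prev_ca = prev_n = None
    for i, aa in enumerate(sequence.upper(), start=1):
        res3 = _ONE_TO_THREE[aa]
        if prev_c is None:
            n = np.array([0.0, 0.0, 0.0])
            ca = np.array([1.458, 0.0, 0.0])
            c = _place_atom(np.array([0.0, 1.0, 0.0]), n, ca, 1.525, 111.0, 180.0)
        else:
            n = _place_atom(prev_n, prev_ca, prev_c, 1.329, 116.2, 180.0)   # psi
            ca = _place_atom(prev_ca, prev_c, n, 1.458, 121.7, 180.0)       # omega
            c = _place_atom(prev_c, n, ca, 1.525, 111.0, 180.0)             # phi
        o = _place_atom(n, ca, c, 1.231, 120.8, 0.0)
        add("N", "N", n, i, res3)
        add("CA", "C", ca, i, res3)
        add("C", "C", c, i, res3)
        add("O", "O", o, i, res3)
        if aa != "G":
            cb = _place_atom(c, n, ca, 1.53, 110.5, -122.0)
            add("CB", "C", cb, i, res3)
        prev_n, prev_ca, prev_c = n, ca, c
    n_atoms = len(coords)
    return Structure(
        atom_ids=np.arange(1, n_atoms + 1),
        atom_names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        residue_numbers=np.array(res_ids),
        residue_names=np.array(res_names, dtype=object),
        chain_ids=np.array([chain_id] * n_atoms, dtype=object),
        coordinates=np.array(coords),
        hetero=np.zeros(n_atoms, dtype=bool),
    )


_AA = "ACDEFGHIKLMNPQRSTVWY"


def make_mutated_pair(length: int, k: int, seed: int = 0) -> tuple[str, str]:
    """Random amino-acid sequence plus a copy with exactly ``k`` substitutions
    (no indels) at seed-deterministic positions."""
    if k > length:
        raise ValueError(f"cannot plant {k} substitutions in a {length}-mer")
    rng = np.random.default_rng(seed)
    seq_a = "".join(rng.choice(list(_AA), size=length))
    positions = rng.choice(length, size=k, replace=False)
    chars = list(seq_a)
    for pos in positions:
        options = [c for c in _AA if c != chars[pos]]
        chars[pos] = options[rng.integers(len(options))]
    return seq_a, "".join(chars)


# ---------------------------------------------------------------------------
# Planted-state toy complex
# ---------------------------------------------------------------------------

#: Planted parameters per state: (d_inter nm, theta deg, depth nm,
#: pocket inner radius Å, gg head distance nm).  Pocket radii are chosen so
#: the analytic cavity volume lands in the open / semi-open / close bands.
_STATE_PARAMS = {
    ("tight", "open"): (3.3, 45.0, 2.0, 5.50, 1.0),
    ("loose", "semi-open"): (3.7, 35.0, 2.6, 4.55, 1.7),
    ("loose", "close"): (3.7, 25.0, 3.0, 3.40, 1.9),
}


@dataclass
class ComplexBundle:
    """A toy Rab:GDI-like complex with planted ground truth."""

    trajectory: Trajectory
    regions: RegionMap
    truth: dict


def make_complex_bundle(binding: str = "tight", pocket: str = "open",
                        n_frames: int = 20, frame_dt: float = 1.0,
                        seed: int = 0) -> ComplexBundle:
    """Build a two-chain toy complex with planted binding mode and pocket state.

    Chain A mimics Rab5: a Cα ball for the G domain (residues 16–184), an HVR
    strand (190–215) with prenylated cysteines 212/213 and two HETATM prenyl
    head atoms.  Chain B mimics GDI: helices H1 (122–129) and H2 (135–148) at
    the planted opening angle, buried Met132, a pocket-lining cavity shell
    (residues 160–175, standing in for the H3 side of the pocket) of planted
    volume, and RBP/CCR marker residues.  Frame-to-frame jitter is applied to
    the scheduled inter-protein distance only, so the planted pocket geometry
    holds in every frame.
    """
    key = (binding, pocket)
    if key not in _STATE_PARAMS:
        raise ValueError(f"no planted parameterization for state {key}")
    d_inter_nm, theta, depth_nm, r_pocket, head_nm = _STATE_PARAMS[key]
    rng = np.random.default_rng(seed)

    pocket_center = np.zeros(3)
    shell, pocket_volume = make_cavity_shell(
        CavitySpec(inner_radius=r_pocket), center=pocket_center,
        chain_id="B", residue_numbers=np.arange(160, 176), res_name="SHL",
    )
    shell_outer = r_pocket + VDW_RADII["C"] + SHELL_REFERENCE_PADDING + 2.0
    h1 = make_ideal_helix(HelixSpec(
        n_residues=8, axis_direction=(0, 0, 1),
        origin=(shell_outer + 6.0, 0.0, 0.0), chain_id="B", first_residue=122))
    ax2 = (np.sin(np.deg2rad(theta)), 0.0, np.cos(np.deg2rad(theta)))
    h2 = make_ideal_helix(HelixSpec(
        n_residues=14, axis_direction=ax2,
        origin=(-(shell_outer + 6.0), 0.0, 0.0), chain_id="B", first_residue=135))
    met132 = _ca_structure(
        np.array([[0.0, 0.0, -(shell_outer + 4.0)]]), [132],
        chain_id="B", res_name="MET")
    rbp = _ca_structure(
        np.column_stack([
            np.full(30, shell_outer + 14.0),
            np.linspace(-10, 10, 30),
            np.full(30, 10.0),
        ]), np.arange(226, 256), chain_id="B", res_name="GLY")

    met_pos = met132.coordinates[0]
    # Rab side: the G domain carries the inter-protein distance; the HVR and
    # prenyl moiety stay pinned to the pocket so planted depth/head distances
    # and HVR-CCR contacts hold exactly in every frame.
    n_gdom = 169
    cloud = rng.standard_normal((n_gdom, 3))
    cloud = 12.0 * cloud / np.abs(cloud).max()
    gdom_center = met_pos + np.array([0.0, 0.0, -40.0])
    gdom = _ca_structure(cloud + gdom_center, np.arange(16, 185),
                         chain_id="A", res_name="ALA")
    hvr_res = np.arange(190, 212)  # 212/213 are the cysteine segment below
    hvr_end = met_pos + np.array([14.0, 0.0, -6.0])   # clear of the pocket grid
    hvr_path = gdom_center + np.outer(np.linspace(0, 1, len(hvr_res)),
                                      hvr_end - gdom_center)
    hvr = _ca_structure(hvr_path, hvr_res, chain_id="A", res_name="GLY")
    depth = 10.0 * depth_nm
    cys_coords = np.array([
        met_pos + depth * np.array([np.sin(0.3), 0, np.cos(0.3)]),
        met_pos + depth * np.array([np.sin(-0.3), 0, np.cos(-0.3)]),
    ])
    cys = _ca_structure(cys_coords, [212, 213], chain_id="A", res_name="CYS")
    head = 10.0 * head_nm
    gg_heads = Structure(
        atom_ids=np.array([1, 2]),
        atom_names=np.array(["C20", "C20"], dtype=object),
        elements=np.array(["C", "C"], dtype=object),
        residue_numbers=np.array([212, 213]),
        residue_names=np.array(["GER", "GER"], dtype=object),
        chain_ids=np.array(["A", "A"], dtype=object),
        coordinates=np.array([
            met_pos + head * np.array([0.2, 0.1, 0.97]) / np.linalg.norm([0.2, 0.1, 0.97]),
            met_pos + head * np.array([-0.2, 0.1, 0.97]) / np.linalg.norm([-0.2, 0.1, 0.97]),
        ]),
        hetero=np.array([True, True]),
    )
    rab = concat_structures(gdom, hvr, cys, gg_heads)

    # CCR markers: three residues planted within contact range (2.5 Å) of the
    # HVR tail, the rest on a remote shelf (never in contact).
    ccr_residues = [88, 92, 97, 98, 102, 103, 104, 218, 219, 225, 439, 447]
    in_contact = {97, 219, 225}
    ccr_coords = []
    tail = hvr_path[-6:]
    for i, res in enumerate(ccr_residues):
        if res in in_contact:
            anchor = tail[i % len(tail)]
            ccr_coords.append(anchor + np.array([0.0, 2.5, 0.0]))
        else:
            ccr_coords.append(met_pos + np.array([30.0 + 5.0 * i, 20.0, 0.0]))
    ccr = _ca_structure(np.array(ccr_coords), ccr_residues,
                        chain_id="B", res_name="GLY")
    gdi = concat_structures(shell, h1, h2, met132, rbp, ccr)

    # Shift the G domain so COM(G domain) - COM(GDI) matches the planted
    # distance, then jitter that distance along the separation axis.
    def com(s: Structure) -> np.ndarray:
        return np.average(s.coordinates, axis=0, weights=s.masses)

    com_gdom = com(gdom)
    sep = com_gdom - com(gdi)
    u = sep / np.linalg.norm(sep)
    base_shift = (10.0 * d_inter_nm - np.linalg.norm(sep)) * u

    combined = concat_structures(rab, gdi)
    gdom_idx = np.arange(n_gdom)  # first atoms of the combined structure
    jitter = rng.normal(0.0, 0.3, size=n_frames)  # Å, on d_inter only
    base = combined.coordinates.copy()
    base[gdom_idx] += base_shift
    frames = np.repeat(base[None], n_frames, axis=0)
    for f in range(n_frames):
        frames[f, gdom_idx] += jitter[f] * u
    combined = combined.with_coordinates(frames[0].copy())
    traj = Trajectory(structure=combined,
                      frames=frames,
                      frame_times=np.arange(n_frames) * float(frame_dt))

    regions = RegionMap({
        "gdi_h2": {"chain": "B", "range": [135, 148]},
        "gdi_h3": {"chain": "B", "range": [160, 175]},
        "pocket_lining": {"chain": "B", "range": [160, 175]},
    }).with_chain({"rab": "A", "gdi": "B"})
    truth = {
        "binding": binding,
        "pocket": pocket,
        "d_inter_nm": d_inter_nm,
        "theta_deg": theta,
        "depth_nm": depth_nm,
        "pocket_volume_A3": pocket_volume,
        "gg_head_distance_nm": head_nm,
        "n_gg_inside": int(2 * (head_nm < 1.5)),
    }
    return ComplexBundle(trajectory=traj, regions=regions, truth=truth)
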