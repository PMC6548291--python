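"""Per-frame geometric descriptors of Rab:GDI recognition.

Implements the descriptor set used to characterize prenylated-Rab binding to
GDI: the inter-protein center-of-mass distance ``d_inter`` (nm), the
H1–H2 pocket opening angle ``theta`` (degrees), the prenyl-cysteine insertion
depth ``d_GGpocket`` (Cα of each GG-cysteine to the buried Met132 Cα, nm),
the count of prenyl chains "inside" the pocket (head-carbon to Met132
distance < 1.5 nm, strict), the membrane–protein distance along the bilayer
normal, plus Kabsch superposition, RMSD and RMSF utilities.

Distances are computed in Å internally and reported in nm, following the
field's plotting convention for these quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import AtomSelection, Structure, Trajectory

__all__ = [
    "DescriptorSeries",
    "SuperpositionResult",
    "com_distance",
    "helix_axis",
    "interhelix_angle",
    "insertion_depth",
    "gg_inside_count",
    "membrane_distance",
    "superpose",
    "apply_superposition",
    "rmsf",
]

ANGSTROM_PER_NM = 10.0


@dataclass
class DescriptorSeries:
    """Per-frame scalar series with unit and provenance label."""

    name: str
    values: np.ndarray
    unit: str
    frame_times: np.ndarray

    _ALLOWED_UNITS = {"Å", "nm", "degrees", "Å²", "Å³", "count"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.values.shape[0] != self.frame_times.shape[0]:
            raise ValueError(
                f"series {self.name!r}: {self.values.shape[0]} values vs "
                f"{self.frame_times.shape[0]} frame times"
            )
        if self.unit not in self._ALLOWED_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")

    def __len__(self) -> int:
        return len(self.values)

    def mean(self) -> float:
        return float(np.mean(self.values))

    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0

    def summary(self) -> dict:
        return {
            "name": self.name,
            "unit": self.unit,
            "n_frames": len(self.values),
            "mean": self.mean(),
            "sd": self.sd(),
            "min": float(np.min(self.values)),
            "max": float(np.max(self.values)),
        }


def _frames_of(traj_or_struct) -> tuple[np.ndarray, np.ndarray]:
    """Normalize input to (frames, times); a bare Structure is one frame."""
    if isinstance(traj_or_struct, Trajectory):
        return traj_or_struct.frames, traj_or_struct.frame_times
    if isinstance(traj_or_struct, Structure):
        return traj_or_struct.coordinates[None], np.array([0.0])
    raise TypeError(f"expected Trajectory or Structure, got {type(traj_or_struct)!r}")


def _weighted_com(coords: np.ndarray, weights: np.ndarray) -> np.ndarray:
    return np.average(coords, axis=0, weights=weights)


def com_distance(traj, sel_a: AtomSelection, sel_b: AtomSelection,
                 mass_weighted: bool = True,
                 check_disjoint: bool = True) -> DescriptorSeries:
    """Inter-group center-of-mass distance per frame (``d_inter``, nm)."""
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValueError("com_distance: empty selection")
    if check_disjoint and np.intersect1d(sel_a.indices, sel_b.indices).size:
        raise ValueError(
            f"selections {sel_a.label!r} and {sel_b.label!r} overlap; "
            "pass check_disjoint=False to allow"
        )
    frames, times = _frames_of(traj)
    wa = sel_a.masses if mass_weighted else np.ones(len(sel_a))
    wb = sel_b.masses if mass_weighted else np.ones(len(sel_b))
    com_a = np.einsum("fij,i->fj", frames[:, sel_a.indices], wa) / wa.sum()
    com_b = np.einsum("fij,i->fj", frames[:, sel_b.indices], wb) / wb.sum()
    dist = np.linalg.norm(com_b - com_a, axis=1) / ANGSTROM_PER_NM
    label = f"d_inter({sel_a.label or 'A'},{sel_b.label or 'B'})"
    return DescriptorSeries(label, dist, "nm", times)


def helix_axis(sel: AtomSelection, frame: np.ndarray | None = None) -> np.ndarray:
    """Helix axis by principal component of the Cα coordinate covariance.

    The sign is fixed N→C: the axis has positive projection on the vector
    from the first to the last selected atom.  PCA is used rather than
    windowed-centroid methods because the H1 helix has only ~2 turns.
    """
    coords = sel.coordinates(frame)
    if len(coords) < 4:
        raise ValueError(f"helix_axis needs >= 4 atoms, got {len(coords)}")
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    n_to_c = coords[-1] - coords[0]
    if np.dot(axis, n_to_c) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def interhelix_angle(traj_or_struct, h1: AtomSelection,
                     h2: AtomSelection) -> DescriptorSeries:
    """Angle between the N→C-oriented axes of two helices (degrees, [0, 180]).

    This is the pocket opening angle ``theta`` when applied to GDI helices
    H1 and H2; parallel vs antiparallel orientation is preserved (no folding
    to [0, 90]).
    """
    if isinstance(traj_or_struct, Structure):
        # static structures: each selection reads its own parent coordinates,
        # so helices from two separate structures can be compared
        a1 = helix_axis(h1)
        a2 = helix_axis(h2)
        cosang = float(np.clip(np.dot(a1, a2), -1.0, 1.0))
        return DescriptorSeries("theta", [np.degrees(np.arccos(cosang))],
                                "degrees", [0.0])
    frames, times = _frames_of(traj_or_struct)
    values = np.empty(len(frames))
    for i, frame in enumerate(frames):
        a1 = helix_axis(h1, frame)
        a2 = helix_axis(h2, frame)
        cosang = float(np.clip(np.dot(a1, a2), -1.0, 1.0))
        values[i] = np.degrees(np.arccos(cosang))
    return DescriptorSeries("theta", values, "degrees", times)


def _single_ca(sel: AtomSelection, what: str) -> int:
    if len(sel) != 1:
        raise ValueError(f"{what}: expected exactly one Cα atom, got {len(sel)}")
    return int(sel.indices[0])


def insertion_depth(traj, met132_ca: AtomSelection,
                    gg_cys_ca: dict[int, AtomSelection]) -> dict[str, DescriptorSeries]:
    """Prenyl insertion depth ``d_GGpocket`` per GG-cysteine (nm).

    Distance from each GG-cysteine Cα (typically Cys212 and Cys213) to the
    Cα of the buried Met132 at the pocket bottom, plus their per-frame mean.
    """
    if not gg_cys_ca:
        raise ValueError("insertion_depth: no GG cysteines given")
    frames, times = _frames_of(traj)
    met_idx = _single_ca(met132_ca, "Met132")
    out: dict[str, DescriptorSeries] = {}
    stack = []
    for res, sel in sorted(gg_cys_ca.items()):
        cys_idx = _single_ca(sel, f"Cys{res}")
        d = np.linalg.norm(frames[:, cys_idx] - frames[:, met_idx], axis=1)
        d = d / ANGSTROM_PER_NM
        out[f"d_GGpocket_Cys{res}"] = DescriptorSeries(
            f"d_GGpocket_Cys{res}", d, "nm", times)
        stack.append(d)
    out["d_GGpocket_mean"] = DescriptorSeries(
        "d_GGpocket_mean", np.mean(stack, axis=0), "nm", times)
    return out


def gg_inside_count(traj, met132_sel: AtomSelection,
                    gg_head_atoms: AtomSelection,
                    cutoff: float = 1.5) -> DescriptorSeries:
    """Per-frame number of prenyl chains inside the pocket (0, 1 or 2).

    A chain counts as inside when its head-carbon to Met132 Cα distance is
    strictly below ``cutoff`` (nm, default 1.5).
    """
    if len(gg_head_atoms) == 0:
        raise ValueError("gg_inside_count: no prenyl head atoms selected")
    frames, times = _frames_of(traj)
    met_idx = _single_ca(met132_sel, "Met132")
    head = frames[:, gg_head_atoms.indices]          # (f, n_chains, 3)
    met = frames[:, met_idx][:, None, :]
    dist_nm = np.linalg.norm(head - met, axis=2) / ANGSTROM_PER_NM
    counts = (dist_nm < cutoff).sum(axis=1).astype(float)
    return DescriptorSeries("n_gg_inside", counts, "count", times)


def membrane_distance(traj, membrane_sel: AtomSelection,
                      protein_sel: AtomSelection,
                      normal_axis: str = "z",
                      mass_weighted: bool = True) -> DescriptorSeries:
    """|COM(protein) − COM(membrane)| projected on the bilayer normal (nm).

    The membrane selection is typically the phosphate atoms; the normal axis
    is one of x/y/z.
    """
    if len(membrane_sel) == 0 or len(protein_sel) == 0:
        raise ValueError("membrane_distance: empty selection")
    axis = {"x": 0, "y": 1, "z": 2}.get(normal_axis)
    if axis is None:
        raise ValueError(f"normal_axis must be x, y or z, got {normal_axis!r}")
    frames, times = _frames_of(traj)
    wm = membrane_sel.masses if mass_weighted else np.ones(len(membrane_sel))
    wp = protein_sel.masses if mass_weighted else np.ones(len(protein_sel))
    com_m = np.einsum("fij,i->fj", frames[:, membrane_sel.indices], wm) / wm.sum()
    com_p = np.einsum("fij,i->fj", frames[:, protein_sel.indices], wp) / wp.sum()
    d = np.abs(com_p[:, axis] - com_m[:, axis]) / ANGSTROM_PER_NM
    return DescriptorSeries("d_membrane", d, "nm", times)


@dataclass
class SuperpositionResult:
    """Optimal rigid-body fit: x_fit = rotation @ x + translation."""

    rotation: np.ndarray     # (3, 3), proper
    translation: np.ndarray  # (3,), Å
    rmsd: float              # nm


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares proper rotation + translation mapping mobile onto
    reference (Kabsch algorithm via SVD)."""
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    h = (mobile - mob_c).T @ (reference - ref_c)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    rot = vt.T @ correction @ u.T
    trans = ref_c - rot @ mob_c
    return rot, trans


def superpose(mobile: AtomSelection | np.ndarray,
              reference: AtomSelection | np.ndarray,
              mobile_frame: np.ndarray | None = None,
              reference_frame: np.ndarray | None = None) -> SuperpositionResult:
    """Optimal least-squares superposition of paired atoms (proper rotation).

    Inputs are paired 1:1 in order; RMSD over the paired atoms is reported in
    nm.  Degenerate (collinear or < 3 atoms) inputs raise.
    """
    mob = (mobile.coordinates(mobile_frame)
           if isinstance(mobile, AtomSelection) else np.asarray(mobile, float))
    ref = (reference.coordinates(reference_frame)
           if isinstance(reference, AtomSelection) else np.asarray(reference, float))
    if mob.shape != ref.shape:
        raise ValueError(
            f"superpose: paired atom counts differ ({mob.shape[0]} vs {ref.shape[0]})"
        )
    if mob.shape[0] < 3:
        raise ValueError("superpose needs at least 3 paired atoms")
    for name, pts in (("mobile", mob), ("reference", ref)):
        centered = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
            raise ValueError(f"superpose: {name} point set is collinear/degenerate")
    rot, trans = _kabsch(mob, ref)
    fitted = mob @ rot.T + trans
    rmsd_A = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans,
                               rmsd=rmsd_A / ANGSTROM_PER_NM)


def apply_superposition(coords: np.ndarray, fit: SuperpositionResult) -> np.ndarray:
    return coords @ fit.rotation.T + fit.translation


def rmsf(traj: Trajectory, sel: AtomSelection, fit_sel: AtomSelection | None = None,
         window: tuple[int, int] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue root mean square fluctuation (nm) over a frame window.

    Frames are first superposed on ``fit_sel`` (default: the analysed
    selection itself) onto the window-average reference, then per-residue
    Cα fluctuations about the mean position are computed.  Returns
    ``(residue_numbers, rmsf_nm)``.
    """
    fit_sel = fit_sel or sel
    idx = traj.window(frame_range=window) if window else traj.window()
    if len(idx) < 2:
        raise ValueError("rmsf window must contain at least 2 frames")
    # two-pass reference: fit everything onto the first frame, average,
    # then fit onto that average
    ref_fit = traj.frames[idx[0]][fit_sel.indices]
    aligned = np.empty((len(idx), len(sel.indices), 3))
    fits = []
    for k, f in enumerate(idx):
        fit = superpose(traj.frames[f][fit_sel.indices], ref_fit)
        aligned[k] = apply_superposition(traj.frames[f][sel.indices], fit)
        fits.append(fit)
    mean_ref_fit = np.mean(
        [apply_superposition(traj.frames[f][fit_sel.indices], fits[k])
         for k, f in enumerate(idx)], axis=0)
    for k, f in enumerate(idx):
        fit = superpose(traj.frames[f][fit_sel.indices], mean_ref_fit)
        aligned[k] = apply_superposition(traj.frames[f][sel.indices], fit)
    mean_pos = aligned.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((aligned - mean_pos) ** 2, axis=2), axis=0))
    residues = sel.structure.residue_numbers[sel.indices]
    uniq = np.unique(residues)
    out = np.array([
        np.sqrt(np.mean(per_atom[residues == r] ** 2)) for r in uniq
    ]) / ANGSTROM_PER_NM
    return uniq, out
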