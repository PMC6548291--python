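# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `prenylpocket`. Units are Å internally everywhere; descriptor
series that the field conventionally plots in nm (distances) are converted
on output and carry explicit unit strings.

## Descriptors

**Inter-protein distance d_inter.** Mass-weighted centroids (standard atomic
weights) of two disjoint selections, Euclidean distance per frame, reported
in nm. The Rab-side selection defaults to the folded G domain (residues
16–184, heavy atoms, HETATM excluded) rather than the whole chain, so the
disordered HVR and the prenyl chains do not drag the centroid. Overlapping
selections are an error unless explicitly allowed.

**Helix axes and opening angle θ.** A helix axis is the first principal
component of the Cα coordinate covariance, sign-fixed so it points N→C
(positive projection on first→last Cα). PCA was chosen over
windowed-centroid axis methods because H1 has only 8 residues (~2 turns),
where sliding-window estimators are unstable. θ is the angle between the two
N→C axes, kept in [0°, 180°] to preserve the parallel/antiparallel
distinction; the 40–57° range of interest is unaffected by the convention.
A fractional final helix turn biases the PCA axis of an ideal helix by up to
~2.5°; the synthetic generator counter-rotates for this so its fitted axis
matches the requested direction exactly, and the descriptor-side tolerance
for angle recovery is 1°.

**Insertion depth d_GGpocket.** Cα(GG-Cys) to Cα(Met132) distance per
cysteine (212 and 213) plus their per-frame mean, in nm. Exactly one Cα per
named residue is required; anything else is an error.

**GG-inside count.** A prenyl chain counts as inside the pocket when its
head carbon (default atom name `C20`, the terminal carbon of the fourth
isoprene unit; configurable since crystal/topology naming varies) is at a
Met132 distance strictly below 1.5 nm. The strict inequality is asserted by
tests at the boundary.

**Membrane distance.** |COM(protein) − COM(membrane selection)| projected on
a named box axis. The membrane selection is intended to be the phosphate
atoms; whether the reference is a COM or a phosphate plane is a convention
choice — COM of the selection is used here and stated in output metadata.

**Superposition, RMSD, RMSF.** Kabsch (SVD with determinant correction, so
the rotation is always proper). RMSD is reported in nm. Collinear or
fewer-than-3-point inputs are rejected. RMSF superposes each window frame
onto the window-average reference on a fit selection (two-pass: align to the
first frame, average, re-align to the average), then reports per-residue
Cα fluctuations about the mean position.

## Pocket volume

The grid method mirrors the POVME 2.0 procedure, whose published defaults
are adopted because the analysis they support did not print them: spacing
1.0 Å, occupancy padding 1.09 Å, contiguous-points criterion 3, convex-hull
constraint on. All are config-exposed. The algorithm per frame:

1. lattice points inside any inclusion sphere (default: one 12 Å sphere at
   the centroid of the pocket-lining region — H1+H2+H3 Cα by default; H2/H3
   residue ranges are mandatory config since no default range is defensible);
2. a point is occupied if within (vdW + padding) of any occupancy-set atom;
   the occupancy set must exclude the prenyl/ligand atoms, because the
   cavity being measured is the one they occupy;
3. convex-hull clip against pocket-lining atoms (those within sphere radius
   + 5 Å), suppressing open-mouth bleed; skipped with a warning for
   degenerate linings;
4. contiguity: free voxels with fewer than 3 free 26-neighbors are dropped,
   iterated to fixpoint;
5. the connected component containing the seed (default: first inclusion
   center) is kept; if the seed is occupied, the largest component; if no
   free voxels remain, volume 0 with a warning, not an error;
6. volume = free-voxel count × spacing³.

With `center_sel` the inclusion centers are offsets from a per-frame
centroid, making volumes invariant under rigid motion of the frame (verified
to 2 %, the grid-realignment noise). Lattice-count fluctuation at 1 Å
spacing is a few percent for ~700 Å³ cavities and under 1 % at 0.5 Å; the
analytic-sphere acceptance bound (5 % at 0.5 Å) reflects that.

The persistent pocket superposes window frames onto the first on the
pocket-lining selection, accumulates free masks on the template lattice
(nearest-voxel regridding) and keeps voxels free in ≥ fraction (default
0.75) of frames. Output: dummy-atom PDB and OpenDX density.

## SASA and interface

Shrake–Rupley with a deterministic golden-section-spiral point set (default
960 points/atom) — no RNG, so results are bit-reproducible. Probe 1.4 Å,
heavy atoms only by default, Bondi-type vdW radii; the original analysis
used a visualization tool's unprinted defaults, so all three are exposed.
A point on the solvent-extended sphere is buried if inside any neighbor's
extended sphere; only atoms of the evaluated selection occlude, which is
what makes SASA(A alone) vs SASA(complex) well-defined for interface area.
Increasing the point count 960→3840 changes fixture totals by <1 %.

Per-residue SASA is normalized by the Miller et al. (1987) Gly-X-Gly
tripeptide reference areas (bundled 20-residue table). Geranylgeranylated
cysteine is normalized against plain Cys — the table has no prenylated
entry, and the quantity of interest is the exposure of the amino-acid
moiety; this mapping is an alias-table entry and overridable. Termini can
exceed 1. Unknown residue types are an error naming the residue.

Interface area = SASA(A) + SASA(B) − SASA(A∪B), reported un-halved with the
halved value alongside in JSON summaries, since figure conventions differ.
A two-sphere fixture verifies the implementation against the closed-form
spherical-cap overlap to 3 %.

Note a physical subtlety the tests encode: an atom inside a cavity wider
than one probe diameter retains nonzero SASA — Shrake–Rupley has no notion
of solvent connectivity. Burial tests therefore use shells tight enough for
genuine occlusion.

## Contacts and residence times

Residue r of group A is in contact in a frame iff its minimum heavy-atom
distance to group B is strictly below the cutoff (default 3 Å). Heavy atoms
only by default — robust to hydrogen placement, with a flag to include
hydrogens since the original criterion's atom set is unstated. "Average
residence time" is read as occupancy fraction × window span (bar heights
bounded by the window length are consistent with this reading); the mean
maximal continuous dwell and event count are reported alongside because the
wording admits a kinetic reading too. Dwell lengths are conserved: they sum
to the total contact frames per residue.

## State classification

Binding mode: tight iff d_inter ≤ 3.55 nm, the midpoint between the tight
band edge (3.5 nm) and the loose mean (3.7 nm); the source gives bands, not
a boundary, so this is config-exposed. Window label by majority; exact ties
go to loose (the conservative call). Pocket state is volume-primary with
left-closed bands at 250 and 550 Å³ (midpoints between the three reported
state means); θ > 40° and depth ≤ 2.3 nm define a geometric open-state
criterion reported as a per-frame concordance flag rather than a competing
classifier, because only the open state has a stated angle criterion.
Per-frame labels are an extension — the majority label is the
literature-comparable output.

## Synthetic data: what it emulates and what it does not

Generators are seed-deterministic and write standard formats (PDB, DCD/XTC,
multi-model PDB) so integration tests go through real I/O. The cavity shell
places carbon pseudo-atoms (single vdW radius, hence a single documented
wall formula) at inner_radius + r_vdW + 1.09 Å, so under the default grid
padding the free interior is exactly the ball of radius inner_radius and the
ground truth is 4/3 π r³ with no residual wall correction; shells deny
spacings coarse enough to leak. The planted-state toy complex carries a Rab
Cα cloud G domain, an HVR strand with prenyl-cysteines and HETATM head
atoms, GDI helices at the planted angle, a pocket shell of planted volume
and CCR/RBP marker residues; only the G domain carries the inter-protein
distance jitter (Normal, σ = 0.3 Å — small thermal COM motion) so the
planted pocket geometry holds in every frame.

These fixtures validate the measurement layer exactly, which is the point —
they do not emulate force-field physics, solvent, side-chain packing or
realistic conformational coupling. Trajectory-scale MD observables (mean
pocket volumes with their ±80 Å³ fluctuations, RMSF profiles, membrane
distances) are therefore covered by planted-truth recovery properties, not
by value reproduction; crystal-structure-derived numbers are reproduced when
the PDB entries are available (cache-first fetch, skip offline).

## Numerical choices and degenerate inputs

Problem sizes in the default test and acceptance runs: toy complexes of
~2200 atoms and 5–10 frames, 10⁴-frame schedules for sampling recoveries,
960-point SASA spheres, 0.5–1.0 Å grids — sizes at which every run completes
in seconds while keeping discretization terms well inside the asserted
tolerances. Alternate locations resolve to the highest-occupancy conformer
(ties → "A"). Elements missing from the PDB element column are inferred from
atom names, with ambiguous two-letter cases (CA, CO, NI, SE) resolved to the
single-letter element; atoms whose element cannot be resolved are a hard
error naming the atom. Sequence comparison scores match +1 / mismatch 0 /
linear gap −1; the aligner's deterministic first optimal alignment is used —
for the substitution-only comparisons this operation targets the optimum is
unique, but heavily gapped ties may resolve differently than a
fewest-gaps-leftmost rule. Region defaults follow author numbering
(switch I 44–66, switch II 75–91, HVR 190–215 with the 186-start variant
available via config, RBP 226–255, H1 122–129, MEL 215–221); the switch-I
epitope residue list is fully user-configurable because one conserved
residue number is not recoverable from the source text.

## Known limitations

No PBC unwrapping beyond what upstream readers provide; no secondary-
structure assignment (helix selections are trusted); no analytic
(Lee–Richards) SASA; no kinetic (correlation-function) contact lifetimes;
no automatic pocket detection — the inclusion region must be told where the
pocket is. mmCIF is not read. The CLI is a thin layer; programmatic use via
the library API is the primary interface.
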