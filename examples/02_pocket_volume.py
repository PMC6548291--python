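"""Grid-based pocket volume against an analytically known cavity.

A spherical pseudo-atom shell encloses an empty ball of radius 6 Å
(true volume 4/3 π 6³ = 904.8 Å³); the voxel-grid method should land within
a few percent at 0.5 Å spacing.
"""

import numpy as np

import prenylpocket as pp
from prenylpocket.pocket_volume import GridSpec, compute_pocket_volume

shell, true_volume = pp.make_cavity_shell(pp.CavitySpec(inner_radius=6.0))
sel = pp.AtomSelection(shell, np.arange(shell.n_atoms), "shell")
grid = GridSpec(spacing=0.5, inclusion_spheres=[((0.0, 0.0, 0.0), 9.0)])

volume, pocket = compute_pocket_volume(shell.coordinates, sel, grid)
print(f"grid volume     = {volume:.1f} Å³")
print(f"analytic volume = {true_volume:.1f} Å³ "
      f"(error {100 * abs(volume - true_volume) / true_volume:.2f} %)")
print("The same machinery measures the GDI prenyl-binding pocket: volumes",
      "near 692/396/170 Å³ correspond to open/semi-open/close pocket states.")
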