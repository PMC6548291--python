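"""Inter-protein COM distance and tight/loose binding-mode classification.

Builds a rigid two-body trajectory whose center-of-mass distance follows a
noisy schedule around 3.3 nm (the tight-complex band), measures d_inter per
frame and classifies the binding mode.
"""

import numpy as np

import prenylpocket as pp

rng = np.random.default_rng(0)
schedule_A = rng.normal(33.0, 1.0, size=500)  # Å

body_a = pp.make_ideal_helix(pp.HelixSpec(n_residues=10))
body_b = pp.make_ideal_helix(pp.HelixSpec(n_residues=10, chain_id="B"))
traj = pp.make_two_body_trajectory(schedule_A, body_a, body_b)

sel_a = pp.AtomSelection(traj.structure, np.arange(10), "rab")
sel_b = pp.AtomSelection(traj.structure, np.arange(10, 20), "gdi")
d_inter = pp.com_distance(traj, sel_a, sel_b)

assignment = pp.classify_binding_mode(d_inter)
print(f"d_inter mean = {d_inter.mean():.3f} nm (sd {d_inter.sd():.3f})")
print(f"binding mode = {assignment.majority}, fractions {assignment.fractions}")
print("A mean near 3.3 nm with most frames <= 3.55 nm is a tightly bound",
      "Rab:GDI complex; above that boundary the complex is loosely bound.")
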