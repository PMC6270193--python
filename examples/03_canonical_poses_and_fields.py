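"""One canonical 3-D pose per fragment, then grid fields around it.

The pose rules (attachment atom at the origin, open valence along +X,
anti torsions, rank-based azimuth and mirror conventions) guarantee that
a given substituent always produces the same steric/electrostatic field
values, no matter which parent molecule it was cut from — the property
that makes fragment-based CoMFA alignment-free.
"""

import numpy as np
from rdkit import Chem

from fragqsar import make_grid, steric_field, electrostatic_field, topomer_pose
from fragqsar.fields import ProbeParams

acetoxy = topomer_pose(Chem.MolFromSmiles("CC(=O)O[*:2]"))
print("acetoxy fragment, canonical pose (Å):")
for sym, (x, y, z) in zip(acetoxy.elements, acetoxy.coords):
    print(f"  {sym:2s} {x:7.3f} {y:7.3f} {z:7.3f}")
print(f"attachment atom at origin; cap direction {acetoxy.open_valence_direction}")

grid = make_grid([acetoxy], spacing=2.0, padding=4.0)
probe = ProbeParams()
ster = steric_field(acetoxy, grid, probe)
elec = electrostatic_field(acetoxy, grid, probe)
print(f"\ngrid: dims {grid.dims} ({grid.n_points} points), spacing {grid.spacing} Å")
print(f"steric field      : min {ster.min():7.3f}  max {ster.max():7.3f} kcal/mol")
print(f"electrostatic     : min {elec.min():7.3f}  max {elec.max():7.3f} kcal/mol")
print(f"clamped points    : {(ster >= probe.clamp).sum()} (inside the fragment envelope)")
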