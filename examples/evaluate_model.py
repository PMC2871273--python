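"""Score a model against its native with every packaged metric.

Creates a noisy decoy of a mixed helix+hairpin toy (2 Angstrom CA RMSD by
construction) and reports GDT_TS, the simplified clashscore, the 11-residue
local window profile, the secondary-structure assignment and the
previous-contact statistic (ALR).
"""

import numpy as np

from cotransfold.metrics import alr, clashscore, gdt_ts, window_quality_profile
from cotransfold.ss import assign_ss
from cotransfold.synthetic import ToySpec, make_decoy_set, make_toy_native

native, _ = make_toy_native(ToySpec(26, "mixed", 0.0, 104))
decoy = make_decoy_set(native, n=1, sigma=2.0, seed=42)[0]

g = gdt_ts(decoy, native)
print(f"GDT_TS = {g.gdt_ts:.2f}  (residues within 1/2/4/8 A: "
      f"{g.N1}/{g.N2}/{g.N4}/{g.N8} of {g.N})")

c = clashscore(decoy)
print(f"clashscore = {c.clashscore:.1f} overlaps per 1000 atoms "
      f"({c.n_overlaps} overlaps > 0.4 A among {c.n_atoms} atoms)")

prof = window_quality_profile(decoy, native)
worst = max(prof.values, key=prof.values.get)
print(f"local 11-mer quality: mean deviation {np.mean(list(prof.values.values())):.2f} A, "
      f"worst window centred at residue {worst} ({prof.values[worst]:.2f} A)")

print(f"native secondary structure: {assign_ss(native).labels}")
print(f"decoy  secondary structure: {assign_ss(decoy).labels}")

a = alr(native)
print(f"native ALR = {a.alr:+.3f} "
      "(positive: residues contact mostly earlier-synthesized residues)")
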