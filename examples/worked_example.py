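"""Cell ↔ S6 ↔ C3 conversions and Selling reduction on two small cells.

The orthorhombic cell (10, 12, 20, 90, 90, 90) maps to an S6 vector whose
first three scalars vanish (all cell angles are 90°, so the inter-axial dot
products are zero) and whose last three are minus the squared cell lengths
(the dot products with the body diagonal d = −(a+b+c)).  The 60° rhombo-
hedral cell has acute angles, hence positive scalars: it is NOT Selling
reduced, and reduction drives every scalar nonpositive while preserving the
lattice (same cell volume).
"""

import numpy as np

from s6lattice import UnitCell, cell_to_s6, s6_to_c3, s6_to_cell, selling_reduce

ortho = UnitCell(10, 12, 20, 90, 90, 90)
v = cell_to_s6(ortho)
print("orthorhombic cell  :", ortho.parameters())
print("  S6 (Å²)          :", np.round(v, 9))
print("  C3               :", np.round(s6_to_c3(v), 9))
print("  back to cell     :", tuple(round(x, 6) for x in s6_to_cell(v).parameters()))

rhombo = UnitCell(1, 1, 1, 60, 60, 60)
r = cell_to_s6(rhombo)
res = selling_reduce(r)
print("\nrhombohedral cell  :", rhombo.parameters())
print("  S6 (unreduced)   :", np.round(r, 9), " <- positive scalars: acute angles")
print("  Selling reduced  :", np.round(res.reduced, 9), f" ({res.iterations} reduction steps)")
print("  volume before/after (Å³): %.9f / %.9f" % (rhombo.volume(), s6_to_cell(res.reduced).volume()))
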