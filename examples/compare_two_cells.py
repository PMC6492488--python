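"""Lattice distances between two cells under each strategy.

The pair differs only in the c axis (20 vs 20.1 Å): both lattices sit deep
inside the reduced region, so every boundary-aware strategy agrees with the
plain Euclidean S6 difference |Δ(c·d)| = 20.1² − 20² = 4.01 Å².  The second
comparison perturbs an angle to 89.0°, putting the cells near a sign
boundary where the boundary-crossing candidates start to matter.
"""

from s6lattice import UnitCell, cs6dist

a = UnitCell(10, 12, 20, 90, 90, 90)
b = UnitCell(10, 12, 20.1, 90, 90, 90)
c = UnitCell(10, 12, 20, 89.0, 90, 90)

for label, p, q in [("length change (interior pair)", a, b), ("angle change (near boundary)", a, c)]:
    print(label)
    for strategy in ("euclidean", "vcp1", "vcp2", "mirror"):
        d = cs6dist(p, q, strategy=strategy)
        print(f"  {strategy:10s}: {d.distance:10.6f} Å²")
    print()
print("A distance of 0 means the inputs present the same lattice;")
print("vcp2 ≤ vcp1 ≤ euclidean always (larger candidate path families).")
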