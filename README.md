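# s6lattice

Selling/Delone lattice representation for crystallography: reduction,
lattice-to-lattice distances and unit-cell clustering in the six-dimensional
space **S6** of Selling scalars.

## The problem

Comparing crystal lattices — for Bravais-lattice assignment, unit-cell
database searches, or grouping the thousands of per-image cells produced by
serial crystallography — requires a distance that treats all equivalent
presentations of a lattice as one object. Raw cell parameters
(a, b, c, α, β, γ) are a poor space for this: equivalent cells can have
wildly different parameters, and popular reduced-cell metrics lose
sensitivity to angles near 90°.

This package represents a lattice by its **Selling scalars**: with cell edge
vectors **a**, **b**, **c** and the body diagonal **d** = −(**a**+**b**+**c**)
(the four vectors of the Bravais tetrahedron, summing to zero), the six
pairwise dot products

```
s = (b·c, a·c, a·b, a·d, b·d, c·d)   [Å²]
```

form a vector in S6. Equivalently **C3** packs the three "opposite" pairs
into complex scalars c₁ = s₁ + i·s₄, c₂ = s₂ + i·s₅, c₃ = s₃ + i·s₆. A
presentation is **Selling reduced** when all six scalars are ≤ 0 (every
inter-axial angle, including those to the body diagonal, is non-acute); the
reduced region is the all-nonpositive orthant with orthogonal axes and just
six sign boundaries.

What the package provides:

* exact conversions cell ↔ basis ↔ S6 ↔ C3 (`s6lattice.cells`);
* the 24-element reflection group relating equivalent presentations —
  transcribed from the published table *and* regenerated from the 4!
  tetrahedron permutations, with the C3 permutation/X-exchange form
  (`s6lattice.symmetry`);
* Selling reduction via the 12 edge-transform matrices (two per boundary,
  each an integer involution: reduction and unreduction are the same
  matrix), the equivalent C3 three-step procedure, and a canonical
  asymmetric-unit representative (`s6lattice.reduction`);
* minimal-distance algorithms (`s6lattice.distance`):
  * `euclidean` — min over the 24 reflections (baseline);
  * `vcp1` — one-boundary **virtual Cartesian points**: each boundary's
    orthogonal transform applied to the boundary projection minus the
    off-boundary component, giving 24 × (1 + 6) = 168 candidates per
    direction;
  * `vcp2` — two-boundary VCP pairs (168 × 7 cross-minimum);
  * `mirror` — tunneled mirrored boundaries: classical mirror point on the
    boundary, continued at no cost from its transformed image;
* the **Follower** validation scan with quality control (endpoint-zeroness,
  1-Lipschitz continuity, slope-break count) (`s6lattice.follower`);
* agglomerative unit-cell clustering with Newick dendrogram export, plus a
  seeded synthetic-cell generator (random cells, noisy polymorph replicates,
  deliberately unreduced presentations) (`s6lattice.cluster`).

## Worked example

```python
from s6lattice import UnitCell, cell_to_s6, s6_to_c3, selling_reduce, cs6dist

v = cell_to_s6(UnitCell(10, 12, 20, 90, 90, 90))
# [   0.    0.    0. -100. -144. -400.]   (Å²; three zeros: all angles 90°)
s6_to_c3(v)
# [0.-100.j  0.-144.j  0.-400.j]

r = cell_to_s6(UnitCell(1, 1, 1, 60, 60, 60))
# [ 0.5  0.5  0.5 -2.  -2.  -2. ]         positive scalars: not Selling reduced
selling_reduce(r).reduced
# [ 0.  -0.5 -0.5  0.  -0.5 -0.5]         after 4 reduction steps, same lattice

cs6dist(UnitCell(10, 12, 20, 90, 90, 90), UnitCell(10, 12, 20.1, 90, 90, 90)).distance
# 4.010000   (= 20.1² − 20²: an interior pair, plain Euclidean difference)
```

The distance is where the boundary machinery earns its keep. Perturbing an
angle instead of a length (α = 89°) puts the pair next to a sign boundary
(`python examples/compare_two_cells.py`):

```
angle change (near boundary)
  euclidean : 141.607318 Å²
  vcp1      :   7.254829 Å²
  vcp2      :   7.254829 Å²
  mirror    :   7.254829 Å²
```

The naive reflection-only distance is off by a factor of ~20 because the
short path runs through a boundary transform; the VCP and mirror algorithms
find it.

The `examples/` directory holds one narrative script per capability
(`worked_example.py`, `compare_two_cells.py`, `follower_scan.py`,
`cluster_polymorphs.py`); each prints what it computes and what the numbers
mean. A thin CLI exposes the same operations
(`s6lattice reduce|dist|matrix|follower|cluster|gen|symmetry`).

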