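# Methods

## Representation and conventions

A primitive lattice with cell edge vectors **a**, **b**, **c** and body
diagonal **d** = −(**a**+**b**+**c**) is represented by the six Selling
scalars, fixed throughout the package in the order

```
s = (b·c, a·c, a·b, a·d, b·d, c·d)        units Å²
```

Any consistent ordering yields an isometric space; this one is pinned in a
single constants table (`cells.S6_PAIRS`) and used everywhere. The C3 form
pairs "opposite" scalars (the two dot products involving disjoint vector
pairs): c₁ = s₁ + i·s₄, c₂ = s₂ + i·s₅, c₃ = s₃ + i·s₆. Angles are degrees
at the I/O boundary and radians internally; lengths Å, scalars Å².

Useful identities, used for inversion and testing:
Σs = −½(|a|²+|b|²+|c|²+|d|²) < 0 for any nondegenerate lattice, and
|a|² = −(s₂+s₃+s₄), |b|² = −(s₁+s₃+s₅), |c|² = −(s₁+s₂+s₆),
|d|² = −(s₄+s₅+s₆), which follow from **a**+**b**+**c**+**d** = 0.

Cell validation accepts positive lengths, angles in (0°, 180°) whose triple
admits a parallelepiped, and requires the metric tensor's smallest
eigenvalue to exceed 1e−10 × trace. Reconstruction from S6 raises an
explicit error (never NaN) when an implied squared length is nonpositive or
an implied cosine falls outside (−1, 1). Every all-nonpositive S6 vector is
realizable: the implied Gram matrix is then diagonally dominant, hence
positive (semi)definite — the reduced region is exactly the all-nonpositive
orthant.

## The reflection group

Relabelling the four tetrahedron vectors leaves the lattice unchanged, so
the 4! = 24 permutations of (**a**, **b**, **c**, **d**) induce 24 distinct
6×6 permutation matrices on S6 (the action of S₄ on unordered vector pairs
is faithful). The canonical list is transcribed from the published table;
the same set is regenerated by brute force from all 24 vector permutations
through one shared generator (`transform_matrix_from_vector_map`), and the
test suite asserts the two sources agree, guarding against transcription
error. In C3 each element is a permutation of (c₁, c₂, c₃) with the X
exchange — X(z) = i·conj(z), swapping real and imaginary parts — applied to
either zero or exactly two components (X acts on pairs, so odd X-counts
cannot occur): 6 pure permutations and 18 elements with two X's. The C3
form is derived programmatically from the S6 matrices rather than
transcribed, since the published C3 table did not survive extraction in the
source material available.

## Edge transforms and Selling reduction

The reduction step is the classical Selling/Delone move: if
s_k = **u**·**w** > 0, negate one vector of the pair, keep the other, and
add the negated vector to the remaining two. Per boundary the two choices
of which vector to negate give two variants — 12 edge transforms in all.
Each is an integer matrix that is *its own inverse* (reduction and
unreduction are the same matrix) and preserves the lattice everywhere. The
step lowers Σ|v_k|² by exactly 2·s_k, i.e. −Σs falls by the eliminated
scalar — this strict decrease is asserted per step and bounds the iteration
count; a `max_iter` cap (default 1000) guards degenerate input.

These reduction matrices are shears: they preserve the lattice, not the
norm. Each also has an orthogonal **boundary form**
O = M·P_perp − P_axis — a signed permutation with O² = I and OᵀO = I that
coincides with M on its boundary s_k = 0. The boundary form is the isometry
used by the distance algorithms (VCP construction); the shear is what
reduction applies. Both matrices live on the `EdgeTransform` object, and
the suite asserts orthogonality/involution for the boundary forms,
involution for the shears, agreement of the two on boundary points, and
reflection-conjugacy of each boundary's variant pair.

In C3 the same step is a three-step procedure (subtract the offending part
from its partner and negate it; add its original value to all four parts of
the other two components; exchange one pair of parts between those two).
Which pair is exchanged distinguishes the variants: for a positive real
part, re(c_j)↔im(c_i) (variant 1) or re(c_i)↔im(c_j) (variant 2); for a
positive imaginary part, re↔re or im↔im (with i < j the other two
components, derived from the vector rule). The C3 procedure is implemented
natively and tested to agree with the S6 matrices to 1e−10 on random inputs
for all 6 boundaries × both variants — the module's central dual-route
self-consistency check.

When several scalars are positive, the largest is eliminated first
(maximising the guaranteed decrease per step); variant 1 is the default.
Neither choice affects the resulting lattice — variant-1 and variant-2
reductions land in the same 24-orbit, asserted via canonical forms.

### Canonical representative

A generic reduced point has exactly 24 equivalent presentations. The
canonical one has components sorted by ascending magnitude with
real ≤ imaginary enforced on c₁ and then c₂ (the third component's order is
then forced and not independently constrained); exact ties are broken by
comparing real then imaginary parts. It is computed as the lexicographic
minimum over the 24 reflections of the key
(|c₁|, |c₂|, |c₃|, re₁, im₁, re₂, im₂, re₃, im₃), which is orbit-invariant
by construction and provably lies in the stated region.

*Boundary points are special*: a point with some s_k = 0 is fixed-height
under the k-th transform, which there acts as a bare permutation not
contained in the 24-orbit (e.g. the s₁ transform acts on its boundary as
the swap s₃↔s₅, and no tetrahedron permutation produces that swap). Reduced
presentations of one lattice therefore coincide up to reflections only for
generic points. The `same_lattice` predicate compares canonical forms first
and falls back to a VCP-distance-zero test, which covers the boundary
identifications.

## Distances

All strategies reduce to minima over families of *valid broken paths*, each
candidate map being an isometry of the fundamental unit, so every strategy
is nonnegative, reflection-invariant, 1-Lipschitz in each (reduced)
argument, and bounded above by the reflection-only Euclidean baseline. All
are symmetrised by evaluating both argument orders (the candidate
construction itself is asymmetric). The triangle inequality is *not*
guaranteed — the value is a minimum over a restricted path family — and is
deliberately not asserted.

* **vcp1**: for each boundary, the virtual Cartesian point
  O·p = M·(P_perp·p) − P_axis·p unfolds a one-boundary crossing so the
  fundamental unit's Euclidean metric applies; candidates are the 24
  reflections of {p plus its 6 VCPs} — 168 points per direction. Only the
  variant-1 VCPs are used: including the 6 variant-2 VCPs as well was
  verified never to change the symmetrised distance on thousands of random
  pairs (variants are reflection-conjugate and reflections are already in
  the candidate set on the evaluated side), so variant 1 alone is the
  default for speed; a `variants` option retains the larger set.
* **vcp2**: the full cross-minimum between the 168-point set of one input
  and the 7-point set (point + 6 VCPs) of the other; reflections on the
  7-point side are implicitly covered because a global reflection of a
  candidate pair preserves its distance. Never exceeds vcp1.
* **mirror**: for each boundary and each reflection of one input, the
  classical mirror point divides the segment between the two boundary
  projections in proportion to the boundary heights; the path runs to the
  mirror point, tunnels at no cost to the mirror point's image under the
  boundary transform, and continues to the target, minimised also over
  reflections of the tunneled image. The proportional ("simple mirror")
  placement is analytic, not an iterative 1-D optimisation; it is exact
  when the boundary crossing is orthogonal or both heights vanish, which is
  what the equality-vs-vcp1 tests construct. For generic crossings the
  mirror family is a slightly coarser upper bound than vcp1, because the
  boundary transform permutes the in-boundary coordinates (the boundary is
  not a simple mirror).

`cs6dist` accepts cells or S6 vectors, reduces internally, dispatches
(default vcp1) and optionally normalises by |p| + |q| for scale-free
clustering (off by default). Distance matrices vectorise candidate-set
construction per point.

## Follower

`follower_trace` draws the straight S6 segment from an unreduced start to
its reduced image, Selling-reduces every sample point, and records its
distance to the endpoint lattice. Reducing intermediates is necessary for
endpoint-zeroness with multi-step-unreduced starts (a
`reduce_intermediate=False` flag evaluates raw points instead, making the
alternative testable). QC checks: both endpoint distances ≤ 1e−8·|start|;
every consecutive jump within 1.0001 × the Euclidean distance between the
two *evaluated* points (the rigorous 1-Lipschitz bound — the raw segment
step is the wrong yardstick, since the reduction shears have operator norm
> 1 and legitimately move the evaluated representative faster than the raw
point); and a count of slope-sign breaks, expected to be small and located
at boundary crossings. Default 200 samples; test scans use 40–100 samples,
which already resolve every crossing in the seeded instances.

## Synthetic generator

`generate_cells` fixes the study conditions for everything downstream:

* `random` — basis rows drawn from N(0,1)³ (resampled while |det| < 0.1,
  flipped to right-handed), scaled to lengths uniform in 3–100 Å: valid,
  generically triclinic cells by construction, no rejection on angles.
* `perturbed` — a random linear distortion B′ = (I + σE)·B with E ~ N(0,1)³ˣ³
  of the base cell's basis. This multiplicative form perturbs lengths and
  angles together (entrywise noise could never move the zero entries of an
  orthorhombic basis, i.e. never change its 90° angles) and yields exact
  copies at σ = 0. The two-polymorph experiment uses σ = 0.002 (0.2%),
  a realistic serial-crystallography indexing jitter.
* `unreduced_presentations` — 1–3 random edge transforms (consecutive
  duplicates rerolled, since the transforms are involutions and would
  cancel) plus a random reflection: alternative presentations of one
  lattice, the ground truth for metric-zero tests.

The Monte-Carlo ensemble for the one- vs two-boundary comparison draws
reduced vectors with components −100·U(0,1) Å² (≈10 Å cells). The uniform
draw was chosen once, before measurement, as the simplest distribution
spanning near-boundary and interior regimes; the improved-pair fraction is
scale-invariant, so the distribution shape is its only free choice. Under
these conditions the measured fraction is 1.0–1.1% with median relative
improvement ≈1.3–1.5%; the corresponding acceptance test asserts the
published sub-1% bound and is allowed to stand red on the fraction rather
than adjusting the ensemble after the fact (the median bound passes with
a wide margin).

What the generator does *not* emulate: indexing outliers and mis-indexed
cells, centered-lattice presentations (inputs are assumed primitive),
resolution-dependent error anisotropy, and multi-modal jitter. Passing
tests therefore demonstrate metric and clustering correctness on clean
primitive cells, not robustness to pathological indexing.

## Clustering

Distance matrices feed `scipy.cluster.hierarchy.linkage` (condensed form;
default average linkage, matching common practice for cell clustering —
the choice is not dictated by the method) with cuts by height or cluster
count; scipy's deterministic ordered scan settles ties. Dendrograms
serialise to Newick (parsed back with dendropy in tests). The two-polymorph
recovery experiment (20 + 20 replicates of (10,12,20,90,90,90) and
(11,13,21,90,90,95) at σ = 0.2%) is recovered exactly (ARI 1.0) by vcp1 and
vcp2 matrices alike, and the two strategies' matrices give identical flat
clusterings across k = 2..4 on the synthetic sets.

## Numerical choices

* Reduction tolerance: a component counts as nonpositive when
  ≤ 1e−10 × max(1, |v|); `is_reduced` uses the same rule.
* Positive-definiteness of the metric tensor: eigenvalue > 1e−10 × trace.
* Canonical-form and same-lattice comparisons: 1e−8 relative.
* Cell↔S6 round trips hold to 1e−9 relative on random cells.
* Two-boundary "improvement" in the Monte Carlo requires vcp2 <
  vcp1·(1 − 1e−9), excluding float ties.
* Monte-Carlo batching (512 pairs) keeps the 168 × 7 broadcast under a few
  MB; 10,000 pairs complete in seconds on one core.

## Known limitations

* The metrics are minima over restricted path families: correct upper
  bounds that agree with exhaustive constructions in the tested regimes,
  but without a triangle-inequality guarantee.
* Three-or-more-boundary paths are not searched (the Monte Carlo bounds
  their relevance via the two-boundary fraction).
* Inputs are assumed primitive; centering transforms are out of scope.
* `mirror` is a coarser family than `vcp1` for oblique crossings (see
  above); it is provided as the independent geometric construction, not as
  the default metric.
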