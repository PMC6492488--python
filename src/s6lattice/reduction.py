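"""Selling reduction and the boundary (edge) transforms.

The reduced region of S6 is the all-nonpositive orthant.  When a scalar
s_k = v_i·v_j is positive, the Delone/Selling step negates one vector of the
offending pair, keeps the other and adds the negated vector to the remaining
two — a unimodular change of tetrahedron that preserves the lattice and
lowers the sum of squared vector lengths Σ|v|² by exactly 2·s_k
(equivalently, −Σs drops by s_k, since −Σs = ½Σ|v|²).  Each boundary k has
two such steps (negate either pair member): the 12 *edge transforms*.  Every
edge transform is an integer involution on S6 — its inverse is itself, so
the same matrix "unreduces".

Each edge transform M also has an orthogonal *boundary form*
O = M·P_perp − P_axis (a signed permutation with O² = I and OᵀO = I) that
agrees with M on the boundary s_k = 0; the boundary form is what the
virtual-Cartesian-point distance construction uses.

In C3 the same step is the three-step procedure: negate the offending part
(after subtracting it from its partner part), add its original value to all
four parts of the other two components, then exchange one pair of parts
between those two components (which pair distinguishes the two variants).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np

from .cells import S6_PAIRS, _as_s6, c3_to_s6, s6_to_c3
from .symmetry import reflection_matrices, transform_matrix_from_vector_map

__all__ = [
    "EdgeTransform",
    "ReductionResult",
    "ReductionError",
    "edge_transforms",
    "edge_transform",
    "selling_reduce",
    "is_reduced",
    "c3_reduce_step",
    "canonical_presentation",
    "canonical_s6",
    "same_lattice",
    "unreduce_random",
    "neg_sum",
    "DEFAULT_MAX_ITER",
]

DEFAULT_MAX_ITER = 1000
#: Relative tolerance defining "component ≤ 0" for reduction decisions.
DEFAULT_REL_TOL = 1e-10


class ReductionError(RuntimeError):
    """Raised when Selling reduction fails to terminate within the cap."""

    def __init__(self, message: str, last_state: np.ndarray | None = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass(frozen=True)
class EdgeTransform:
    """One reduction step across one sign boundary of S6.

    ``matrix`` is the reduction (and unreduction — it is an involution)
    matrix; ``boundary_matrix`` is its orthogonal signed-permutation form,
    identical to ``matrix`` on the boundary ``s_boundary = 0`` and used for
    VCP construction.  ``negated_vector`` names which tetrahedron vector the
    step negates (variant 1 negates the first pair member, variant 2 the
    second).
    """

    boundary_index: int  # 1..6
    variant: int  # 1 or 2
    matrix: np.ndarray
    boundary_matrix: np.ndarray
    negated_vector: str

    def __post_init__(self) -> None:
        for name in ("matrix", "boundary_matrix"):
            m = np.asarray(getattr(self, name), dtype=int)
            m.setflags(write=False)
            object.__setattr__(self, name, m)

    @property
    def name(self) -> str:
        return f"s{self.boundary_index}.{self.variant}"


@dataclass(frozen=True)
class ReductionResult:
    """Outcome of :func:`selling_reduce`."""

    reduced: np.ndarray
    ops_applied: tuple[EdgeTransform, ...]
    iterations: int


def _projectors(boundary_index: int) -> tuple[np.ndarray, np.ndarray]:
    axis = np.zeros((6, 6), dtype=int)
    axis[boundary_index - 1, boundary_index - 1] = 1
    return axis, np.eye(6, dtype=int) - axis


@lru_cache(maxsize=1)
def edge_transforms() -> tuple[EdgeTransform, ...]:
    """The 12 edge transforms, ordered by boundary then variant."""
    out: list[EdgeTransform] = []
    for k in range(6):
        i, j = S6_PAIRS[k]
        for variant, negate in ((1, i), (2, j)):
            keep = j if negate == i else i
            coeffs = np.zeros((4, 4), dtype=int)
            for vec in range(4):
                if vec == negate:
                    coeffs[vec, vec] = -1
                elif vec == keep:
                    coeffs[vec, vec] = 1
                else:
                    coeffs[vec, vec] = 1
                    coeffs[vec, negate] = 1
            matrix = transform_matrix_from_vector_map(coeffs)
            axis, perp = _projectors(k + 1)
            boundary_matrix = matrix @ perp - axis
            out.append(
                EdgeTransform(
                    boundary_index=k + 1,
                    variant=variant,
                    matrix=matrix,
                    boundary_matrix=boundary_matrix,
                    negated_vector="abcd"[negate],
                )
            )
    return tuple(out)


def edge_transform(boundary_index: int, variant: int = 1) -> EdgeTransform:
    """Look up one edge transform by boundary (1..6) and variant (1 or 2)."""
    if not 1 <= boundary_index <= 6 or variant not in (1, 2):
        raise ValueError(f"no edge transform s{boundary_index}.{variant}")
    return edge_transforms()[(boundary_index - 1) * 2 + (variant - 1)]


def neg_sum(v: np.ndarray) -> float:
    """−Σs: half the sum of squared tetrahedron vector lengths (Å²)."""
    return float(-np.sum(np.asarray(v, dtype=float)))


def _tolerance(v: np.ndarray, tol: float | None) -> float:
    if tol is not None:
        return float(tol)
    return DEFAULT_REL_TOL * max(1.0, float(np.linalg.norm(v)))


def is_reduced(v: Sequence[float] | np.ndarray, tol: float | None = None) -> bool:
    """True iff every Selling scalar is ≤ tol (default 1e−10·|v|, absolute floor 1e−10)."""
    arr = _as_s6(v)
    return bool(np.max(arr) <= _tolerance(arr, tol))


def selling_reduce(
    v: Sequence[float] | np.ndarray,
    tol: float | None = None,
    max_iter: int = DEFAULT_MAX_ITER,
    variant: int = 1,
) -> ReductionResult:
    """Iteratively eliminate positive scalars until all are ≤ tol.

    The largest positive scalar is eliminated first (maximising the
    guaranteed decrease of −Σs per step); which variant matrix is used is
    immaterial up to a reflection.  −Σs strictly decreases by the eliminated
    scalar at every step, which bounds the iteration count; ``max_iter`` is a
    safety cap for degenerate input.
    """
    arr = _as_s6(v).copy()
    if float(np.sum(arr)) >= 0.0:
        raise ReductionError(
            f"sum of Selling scalars is {float(np.sum(arr)):g} ≥ 0: not a nondegenerate lattice",
            last_state=arr,
        )
    eff_tol = _tolerance(arr, tol)
    ops: list[EdgeTransform] = []
    for iteration in range(max_iter):
        worst = int(np.argmax(arr))
        if arr[worst] <= eff_tol:
            return ReductionResult(arr, tuple(ops), iteration)
        op = edge_transform(worst + 1, variant)
        arr = op.matrix.astype(float) @ arr
        ops.append(op)
    raise ReductionError(
        f"Selling reduction did not converge in {max_iter} iterations "
        f"(max component {np.max(arr):g}); input may be degenerate",
        last_state=arr,
    )


def _cross_pairs(n: int) -> tuple[int, int]:
    """The two other C3 components of component n (0-based), ascending."""
    return tuple(sorted({0, 1, 2} - {n}))  # type: ignore[return-value]


def c3_reduce_step(
    w: Sequence[complex] | np.ndarray,
    component: int,
    part: Literal["real", "imag", "imaginary"],
    variant: int = 1,
) -> np.ndarray:
    """One Selling-reduction step expressed natively in C3.

    Reduces the named part (assumed positive) of component ``component``
    (1..3): (1) subtract it from its partner part and negate it; (2) add its
    original value to the real and imaginary parts of the other two
    components; (3) exchange one pair of parts between those two components —
    for a real scalar, re(c_j)↔im(c_i) (variant 1) or re(c_i)↔im(c_j)
    (variant 2); for an imaginary scalar, re(c_i)↔re(c_j) (variant 1) or
    im(c_i)↔im(c_j) (variant 2), with i < j the other two components.

    Identical to applying the matching S6 edge-transform matrix via
    ``s6_to_c3``/``c3_to_s6``.
    """
    w = np.asarray(w, dtype=complex).reshape(3).copy()
    n = component - 1
    if n not in (0, 1, 2):
        raise ValueError("component must be 1, 2 or 3")
    if variant not in (1, 2):
        raise ValueError("variant must be 1 or 2")
    imag_part = part.startswith("imag")
    i, j = _cross_pairs(n)
    if imag_part:
        p = w[n].imag
        w[n] = complex(w[n].real - p, -p)
    else:
        p = w[n].real
        w[n] = complex(-p, w[n].imag - p)
    w[i] += p * (1 + 1j)
    w[j] += p * (1 + 1j)
    ci, cj = w[i], w[j]
    if not imag_part:
        if variant == 1:  # re(c_j) ↔ im(c_i)
            w[i] = complex(ci.real, cj.real)
            w[j] = complex(ci.imag, cj.imag)
        else:  # re(c_i) ↔ im(c_j)
            w[i] = complex(cj.imag, ci.imag)
            w[j] = complex(cj.real, ci.real)
    else:
        if variant == 1:  # re(c_i) ↔ re(c_j)
            w[i] = complex(cj.real, ci.imag)
            w[j] = complex(ci.real, cj.imag)
        else:  # im(c_i) ↔ im(c_j)
            w[i] = complex(ci.real, cj.imag)
            w[j] = complex(cj.real, ci.imag)
    return w


def canonical_presentation(w: Sequence[complex] | np.ndarray, tol: float | None = None) -> np.ndarray:
    """Single representative of the 24-fold orbit of a reduced C3 vector.

    The representative has components sorted by ascending magnitude, with
    real ≤ imaginary enforced on the first then the second component (the
    third is then forced); exact ties are broken by comparing real then
    imaginary parts lexicographically.  Implemented as the lexicographic
    minimum over the 24 reflections of the key (|c1|, |c2|, |c3|, re1, im1,
    re2, im2, re3, im3), which lies in that region and is orbit-invariant by
    construction.
    """
    w = np.asarray(w, dtype=complex).reshape(3)
    v = c3_to_s6(w)
    if not is_reduced(v, tol):
        raise ValueError(
            f"canonical_presentation requires a Selling-reduced input; got max scalar {np.max(v):g}"
        )
    orbit = reflection_matrices() @ v  # (24, 6)
    keys = np.column_stack(
        [
            np.hypot(orbit[:, :3], orbit[:, 3:]),  # |c1|, |c2|, |c3|
            orbit[:, [0, 3, 1, 4, 2, 5]],  # re1, im1, re2, im2, re3, im3
        ]
    )
    best = min(range(24), key=lambda idx: tuple(keys[idx]))
    return s6_to_c3(orbit[best])


def canonical_s6(v: Sequence[float] | np.ndarray, tol: float | None = None) -> np.ndarray:
    """Canonical S6 representative of a (possibly unreduced) lattice presentation."""
    arr = _as_s6(v)
    if not is_reduced(arr, tol):
        arr = selling_reduce(arr, tol=tol).reduced
    return c3_to_s6(canonical_presentation(s6_to_c3(arr), tol=np.inf))


def same_lattice(
    p: Sequence[float] | np.ndarray,
    q: Sequence[float] | np.ndarray,
    rel_tol: float = 1e-8,
) -> bool:
    """Whether two S6 presentations describe the same lattice.

    Generic reduced presentations of one lattice are related by the 24
    reflections, so matching canonical forms decide most cases.  *Boundary*
    presentations (some scalar exactly 0) carry extra identifications — the
    boundary transform maps the boundary to itself, relating reduced
    presentations outside the 24-orbit — so a canonical-form mismatch falls
    back to a metric-zero test with the one-boundary VCP distance.
    """
    cp, cq = canonical_s6(p), canonical_s6(q)
    scale = max(1.0, float(np.linalg.norm(cp)), float(np.linalg.norm(cq)))
    if np.linalg.norm(cp - cq) <= rel_tol * scale:
        return True
    from .distance import dist_vcp1  # deferred: distance builds on this module

    rp = _as_s6(p) if is_reduced(p) else selling_reduce(p).reduced
    rq = _as_s6(q) if is_reduced(q) else selling_reduce(q).reduced
    return bool(dist_vcp1(rp, rq).distance <= rel_tol * scale)


def unreduce_random(
    v: Sequence[float] | np.ndarray,
    steps: int,
    rng: np.random.Generator,
    reflect: bool = True,
) -> np.ndarray:
    """Alternative (generally unreduced) presentation of the same lattice.

    Applies ``steps`` random edge transforms (each is its own inverse, so any
    application is a legitimate unreduction) and optionally a random
    reflection.  Because the transforms are involutions, drawing the same one
    twice in a row would silently cancel, so consecutive duplicates are
    rerolled.  The output always represents the same lattice as ``v``.
    """
    arr = _as_s6(v).copy()
    previous: tuple[int, int] | None = None
    for _ in range(steps):
        while True:
            choice = (int(rng.integers(1, 7)), int(rng.integers(1, 3)))
            if choice != previous:
                break
        previous = choice
        arr = edge_transform(*choice).matrix.astype(float) @ arr
    if reflect:
        arr = reflection_matrices()[int(rng.integers(24))] @ arr
    return arr
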