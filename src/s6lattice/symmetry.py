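"""The 24 equivalent presentations (reflections) of a Selling-reduced lattice.

There is no crystallographic reason to prefer one labelling of the Bravais
tetrahedron vectors (a, b, c, d) over another, so every lattice has 24
equivalent S6 presentations, one per permutation of the four vectors.  Each
permutation induces a permutation of the six pairwise dot products, i.e. a
6×6 permutation matrix acting on S6.

In C3 the same group acts by permuting the three complex components and, for
some elements, swapping the real and imaginary parts of a *pair* of
components (the "X" exchange, X(z) = i·conj(z)).

The canonical ordering of the 24 operations follows the published table of
reflection matrices; the same set is regenerated from the 4! vector
permutations, and the test suite asserts the two sources agree.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .cells import S6_PAIRS, SQ_LENGTH_TERMS, c3_to_s6, s6_to_c3

__all__ = [
    "SymOp",
    "reflections",
    "reflection_matrices",
    "apply_sym",
    "apply_sym_c3",
    "transform_matrix_from_vector_map",
    "reflections_from_permutations",
]

#: Published table of the 24 reflection matrices, row notation: each "/"-field
#: is one matrix row, a 1 marking which input scalar feeds that output slot.
REFLECTION_TABLE: tuple[str, ...] = (
    "100000/010000/001000/000100/000010/000001",
    "100000/001000/010000/000100/000001/000010",
    "100000/000010/000001/000100/010000/001000",
    "100000/000001/000010/000100/001000/010000",
    "010000/100000/001000/000010/000100/000001",
    "010000/001000/100000/000010/000001/000100",
    "010000/000100/000001/000010/100000/001000",
    "010000/000001/000100/000010/001000/100000",
    "001000/100000/010000/000001/000100/000010",
    "001000/010000/100000/000001/000010/000100",
    "001000/000100/000010/000001/100000/010000",
    "001000/000010/000100/000001/010000/100000",
    "000100/010000/000001/100000/000010/001000",
    "000100/001000/000010/100000/000001/010000",
    "000100/000010/001000/100000/010000/000001",
    "000100/000001/010000/100000/001000/000010",
    "000010/100000/000001/010000/000100/001000",
    "000010/001000/000100/010000/000001/100000",
    "000010/000100/001000/010000/100000/000001",
    "000010/000001/100000/010000/001000/000100",
    "000001/100000/000010/001000/000100/010000",
    "000001/010000/000100/001000/000010/100000",
    "000001/000100/010000/001000/100000/000010",
    "000001/000010/100000/001000/010000/000100",
)


@dataclass(frozen=True)
class SymOp:
    """One reflection: a 6×6 permutation matrix on S6 plus its C3 description.

    ``c3_source[j]`` is the C3 component feeding output component j and
    ``c3_exchange[j]`` whether that component passes through the X exchange
    (real/imaginary swap).  ``vector_perm`` is the underlying permutation of
    the tetrahedron vectors (a, b, c, d).
    """

    index: int
    name: str
    matrix: np.ndarray
    vector_perm: tuple[int, int, int, int]
    c3_source: tuple[int, int, int]
    c3_exchange: tuple[bool, bool, bool]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=int)
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    @property
    def c3_form(self) -> str:
        """Human-readable C3 action, e.g. ``(c2, X(c1), X(c3))``."""
        parts = [
            f"X(c{src + 1})" if ex else f"c{src + 1}"
            for src, ex in zip(self.c3_source, self.c3_exchange)
        ]
        return "(" + ", ".join(parts) + ")"

    def row_notation(self) -> str:
        return "/".join("".join(str(x) for x in row) for row in self.matrix)


def transform_matrix_from_vector_map(coeffs: np.ndarray) -> np.ndarray:
    """6×6 integer matrix on S6 induced by a relabelling of the tetrahedron.

    ``coeffs`` is a 4×4 integer matrix giving the new vectors as integer
    combinations of the old: v'_i = Σ_j coeffs[i, j] v_j.  The new scalars are
    the entries of C·G·Cᵀ at the pair positions, expanded exactly over the
    old scalars using |v_i|² = −(sum of that vector's three scalars).

    This one generator produces both the 24 reflections (``coeffs`` a
    permutation matrix) and the 12 edge transforms (reduction steps).
    """
    coeffs = np.asarray(coeffs, dtype=int)
    if coeffs.shape != (4, 4):
        raise ValueError("coeffs must be 4×4")
    out = np.zeros((6, 6), dtype=int)
    for k in range(6):
        # Gram matrix for s = e_k: off-diagonals at the pair, diagonals from
        # the squared-length identities.
        g = np.zeros((4, 4), dtype=int)
        i, j = S6_PAIRS[k]
        g[i, j] = g[j, i] = 1
        for vec, terms in enumerate(SQ_LENGTH_TERMS):
            if k in terms:
                g[vec, vec] = -1
        g_new = coeffs @ g @ coeffs.T
        for m, (p, q) in enumerate(S6_PAIRS):
            out[m, k] = g_new[p, q]
    return out


def _perm_name(perm: tuple[int, ...]) -> str:
    return "".join("abcd"[i] for i in perm)


def _c3_decomposition(matrix: np.ndarray) -> tuple[tuple[int, int, int], tuple[bool, bool, bool]]:
    """Decompose a reflection matrix into C3 component sources and X flags."""
    sources: list[int] = []
    exchanges: list[bool] = []
    for j in range(3):
        src_re = int(np.argmax(matrix[j]))
        src_im = int(np.argmax(matrix[j + 3]))
        if src_re < 3:
            if src_im != src_re + 3:
                raise ValueError("matrix does not map opposite pairs to opposite pairs")
            sources.append(src_re)
            exchanges.append(False)
        else:
            if src_im != src_re - 3:
                raise ValueError("matrix does not map opposite pairs to opposite pairs")
            sources.append(src_re - 3)
            exchanges.append(True)
    return tuple(sources), tuple(exchanges)  # type: ignore[return-value]


def reflections_from_permutations() -> dict[tuple[int, ...], np.ndarray]:
    """Brute-force regeneration: all 4! tetrahedron permutations → S6 matrices."""
    out: dict[tuple[int, ...], np.ndarray] = {}
    for perm in itertools.permutations(range(4)):
        coeffs = np.zeros((4, 4), dtype=int)
        for i, p in enumerate(perm):
            coeffs[i, p] = 1
        out[perm] = transform_matrix_from_vector_map(coeffs)
    return out


@lru_cache(maxsize=1)
def reflections() -> tuple[SymOp, ...]:
    """The 24 reflections, in the published table order (element 0 = identity)."""
    generated = reflections_from_permutations()
    by_key = {m.tobytes(): perm for perm, m in generated.items()}
    ops: list[SymOp] = []
    for idx, row_spec in enumerate(REFLECTION_TABLE):
        matrix = np.array(
            [[int(ch) for ch in row] for row in row_spec.split("/")], dtype=int
        )
        perm = by_key.get(matrix.tobytes())
        if perm is None:
            raise RuntimeError(
                f"transcribed reflection {idx} is not generated by any vector permutation"
            )
        sources, exchanges = _c3_decomposition(matrix)
        ops.append(
            SymOp(
                index=idx,
                name=_perm_name(perm),
                matrix=matrix,
                vector_perm=perm,
                c3_source=sources,
                c3_exchange=exchanges,
            )
        )
    if len({op.matrix.tobytes() for op in ops}) != 24:
        raise RuntimeError("reflection table contains duplicates")
    return tuple(ops)


@lru_cache(maxsize=1)
def reflection_matrices() -> np.ndarray:
    """All 24 matrices stacked as a float array of shape (24, 6, 6)."""
    arr = np.stack([op.matrix for op in reflections()]).astype(float)
    arr.setflags(write=False)
    return arr


def apply_sym(op: SymOp | int, v: np.ndarray) -> np.ndarray:
    """Apply a reflection (object or table index) to an S6 vector."""
    if isinstance(op, (int, np.integer)):
        op = reflections()[int(op)]
    return op.matrix.astype(float) @ np.asarray(v, dtype=float)


def _x_exchange(z: np.ndarray | complex) -> np.ndarray | complex:
    """The X operation: swap real and imaginary parts, X(z) = i·conj(z)."""
    return 1j * np.conj(z)


def apply_sym_c3(op: SymOp | int, w: np.ndarray) -> np.ndarray:
    """Apply a reflection to a C3 vector natively (permutation + X exchanges).

    Agrees exactly with routing through S6: s6_to_c3(apply_sym(op, c3_to_s6(w))).
    """
    if isinstance(op, (int, np.integer)):
        op = reflections()[int(op)]
    w = np.asarray(w, dtype=complex)
    out = np.empty(3, dtype=complex)
    for j in range(3):
        z = w[op.c3_source[j]]
        out[j] = _x_exchange(z) if op.c3_exchange[j] else z
    return out


def _check_cross_representation(op: SymOp, w: np.ndarray) -> bool:  # pragma: no cover
    """Debug helper: native C3 action vs the S6 route."""
    via_s6 = s6_to_c3(apply_sym(op, c3_to_s6(w)))
    return bool(np.array_equal(apply_sym_c3(op, w), via_s6))
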