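"""Unit cells and their Selling-scalar representations.

A primitive lattice is described equivalently by

* a :class:`UnitCell` — six cell parameters (a, b, c in Å; α, β, γ in degrees),
* a basis triple — three edge vectors **a**, **b**, **c** plus the body
  diagonal **d** = −(**a**+**b**+**c**) (the Bravais tetrahedron),
* an S6 vector — the six pairwise dot products among (**a**, **b**, **c**,
  **d**), in the fixed order (b·c, a·c, a·b, a·d, b·d, c·d), units Å²,
* a C3 vector — the same scalars as three complex numbers pairing each
  scalar with its "opposite": c1 = s1 + i·s4, c2 = s2 + i·s5, c3 = s3 + i·s6.

A presentation is *Selling reduced* when all six scalars are ≤ 0 (every
inter-axial angle, including those to the body diagonal, is non-acute).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "UnitCell",
    "BasisTriple",
    "CellValidationError",
    "S6RealizationError",
    "cell_to_basis",
    "basis_to_cell",
    "cell_to_s6",
    "s6_to_cell",
    "s6_to_c3",
    "c3_to_s6",
    "s6_implied_squared_lengths",
    "read_cells",
    "write_cells",
    "read_s6",
    "write_s6",
]

#: Vector-pair behind each S6 component, as indices into (a, b, c, d).
#: s1 = b·c, s2 = a·c, s3 = a·b, s4 = a·d, s5 = b·d, s6 = c·d.
S6_PAIRS: tuple[tuple[int, int], ...] = ((1, 2), (0, 2), (0, 1), (0, 3), (1, 3), (2, 3))

#: Which S6 components enter each squared length:
#: |a|² = −(s2+s3+s4), |b|² = −(s1+s3+s5), |c|² = −(s1+s2+s6), |d|² = −(s4+s5+s6).
SQ_LENGTH_TERMS: tuple[tuple[int, int, int], ...] = ((1, 2, 3), (0, 2, 4), (0, 1, 5), (3, 4, 5))

#: Eigenvalue tolerance (relative to trace) for metric-tensor positive definiteness.
PD_EIGENVALUE_TOL = 1e-10


class CellValidationError(ValueError):
    """Raised when six cell parameters do not describe a valid parallelepiped."""


class S6RealizationError(ValueError):
    """Raised when an S6 vector does not correspond to any nondegenerate lattice."""


@dataclass(frozen=True)
class UnitCell:
    """Primitive unit cell: lengths in Å, angles in degrees.

    Validation enforces positive lengths, angles in (0, 180) and a positive
    definite metric tensor (the three angles must admit a parallelepiped).
    """

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    label: str | None = None

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if not getattr(self, name) > 0:
                raise CellValidationError(f"cell length {name} must be > 0, got {getattr(self, name)}")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise CellValidationError(f"cell angle {name} must lie in (0, 180) degrees, got {ang}")
        al, be, ga = self.alpha, self.beta, self.gamma
        if al + be + ga >= 360.0:
            raise CellValidationError(f"angle sum {al + be + ga} ≥ 360°: no parallelepiped exists")
        for lhs, desc in (
            (al + be - ga, "alpha + beta - gamma"),
            (al - be + ga, "alpha - beta + gamma"),
            (-al + be + ga, "-alpha + beta + gamma"),
        ):
            if lhs <= 0.0:
                raise CellValidationError(f"angle condition violated: {desc} = {lhs} ≤ 0")
        g = self.metric_tensor()
        eigvals = np.linalg.eigvalsh(g)
        if eigvals.min() <= PD_EIGENVALUE_TOL * np.trace(g):
            raise CellValidationError(
                f"metric tensor not positive definite (min eigenvalue {eigvals.min():g}); degenerate cell"
            )

    def lengths(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c], dtype=float)

    def angles(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma], dtype=float)

    def metric_tensor(self) -> np.ndarray:
        """3×3 Gram matrix of the cell basis (Å²)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    def volume(self) -> float:
        """Cell volume in Å³ (square root of the metric-tensor determinant)."""
        return float(math.sqrt(np.linalg.det(self.metric_tensor())))

    def with_label(self, label: str | None) -> "UnitCell":
        return UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma, label)

    def parameters(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


@dataclass(frozen=True)
class BasisTriple:
    """Cartesian edge vectors of a cell plus d = −(a+b+c), each shape (3,) in Å."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))

    @property
    def d(self) -> np.ndarray:
        return -(self.a + self.b + self.c)

    def vectors(self) -> np.ndarray:
        """All four tetrahedron vectors stacked, shape (4, 3); rows sum to 0 exactly."""
        return np.stack([self.a, self.b, self.c, self.d])


def _as_s6(v: Sequence[float] | np.ndarray) -> np.ndarray:
    arr = np.asarray(v, dtype=float).reshape(-1)
    if arr.shape != (6,):
        raise ValueError(f"S6 vector must have 6 components, got shape {np.asarray(v).shape}")
    return arr


def _as_c3(w: Sequence[complex] | np.ndarray) -> np.ndarray:
    arr = np.asarray(w, dtype=complex).reshape(-1)
    if arr.shape != (3,):
        raise ValueError(f"C3 vector must have 3 components, got shape {np.asarray(w).shape}")
    return arr


def cell_to_basis(cell: UnitCell) -> BasisTriple:
    """Right-handed Cartesian basis with **a** ∥ x and **b** in the x–y plane."""
    a_len, b_len, c_len = cell.a, cell.b, cell.c
    al, be, ga = (math.radians(x) for x in (cell.alpha, cell.beta, cell.gamma))
    ca, cb, cg = math.cos(al), math.cos(be), math.cos(ga)
    sg = math.sin(ga)
    a_vec = np.array([a_len, 0.0, 0.0])
    b_vec = np.array([b_len * cg, b_len * sg, 0.0])
    cx = c_len * cb
    cy = c_len * (ca - cb * cg) / sg
    cz_sq = c_len * c_len - cx * cx - cy * cy
    if cz_sq <= 0.0:
        raise CellValidationError(
            f"degenerate angle combination (α={cell.alpha}, β={cell.beta}, γ={cell.gamma}): "
            "the c axis has no out-of-plane component"
        )
    c_vec = np.array([cx, cy, math.sqrt(cz_sq)])
    return BasisTriple(a_vec, b_vec, c_vec)


def basis_to_cell(basis: BasisTriple, label: str | None = None) -> UnitCell:
    """Cell parameters of a basis triple (inverse of :func:`cell_to_basis` up to orientation)."""
    a, b, c = basis.a, basis.b, basis.c
    la, lb, lc = (float(np.linalg.norm(v)) for v in (a, b, c))

    def angle(u: np.ndarray, v: np.ndarray) -> float:
        cosang = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
        return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))

    return UnitCell(la, lb, lc, angle(b, c), angle(a, c), angle(a, b), label)


def cell_to_s6(cell: UnitCell) -> np.ndarray:
    """Selling scalars (b·c, a·c, a·b, a·d, b·d, c·d) of a cell, in Å²."""
    vecs = cell_to_basis(cell).vectors()
    return np.array([vecs[i] @ vecs[j] for i, j in S6_PAIRS])


def s6_implied_squared_lengths(v: Sequence[float] | np.ndarray) -> np.ndarray:
    """(|a|², |b|², |c|², |d|²) implied by an S6 vector via a+b+c+d = 0."""
    arr = _as_s6(v)
    return np.array([-(arr[i] + arr[j] + arr[k]) for i, j, k in SQ_LENGTH_TERMS])


def s6_to_cell(v: Sequence[float] | np.ndarray, label: str | None = None) -> UnitCell:
    """Recover the unit cell whose Selling scalars are ``v``.

    Raises :class:`S6RealizationError` if the implied squared lengths are not
    positive or an implied cosine falls outside (−1, 1); never returns NaN.
    """
    arr = _as_s6(v)
    sq = s6_implied_squared_lengths(arr)
    if np.any(sq <= 0.0):
        bad = int(np.argmin(sq))
        raise S6RealizationError(
            f"S6 vector {arr.tolist()} is not realizable: implied |{'abcd'[bad]}|² = {sq[bad]:g} ≤ 0"
        )
    la, lb, lc = (math.sqrt(x) for x in sq[:3])
    cosines = {
        "alpha": arr[0] / (lb * lc),
        "beta": arr[1] / (la * lc),
        "gamma": arr[2] / (la * lb),
    }
    for name, cosang in cosines.items():
        if not -1.0 < cosang < 1.0:
            raise S6RealizationError(
                f"S6 vector {arr.tolist()} is not realizable: implied cos({name}) = {cosang:g}"
            )
    try:
        return UnitCell(
            la,
            lb,
            lc,
            math.degrees(math.acos(cosines["alpha"])),
            math.degrees(math.acos(cosines["beta"])),
            math.degrees(math.acos(cosines["gamma"])),
            label,
        )
    except CellValidationError as exc:
        raise S6RealizationError(f"S6 vector {arr.tolist()} is not realizable: {exc}") from exc


def s6_to_c3(v: Sequence[float] | np.ndarray) -> np.ndarray:
    """Pair opposite scalars: (s1+i·s4, s2+i·s5, s3+i·s6)."""
    arr = _as_s6(v)
    return arr[:3] + 1j * arr[3:]


def c3_to_s6(w: Sequence[complex] | np.ndarray) -> np.ndarray:
    """Inverse of :func:`s6_to_c3`; bit-exact round trip."""
    arr = _as_c3(w)
    return np.concatenate([arr.real, arr.imag])


# ---------------------------------------------------------------------------
# Plain-text I/O: one cell (or S6 vector) per line, CSV or whitespace
# delimited, optional trailing label, '#' comments skipped.
# ---------------------------------------------------------------------------

def _parse_line(line: str, n_numeric: int) -> tuple[list[float], str | None] | None:
    stripped = line.split("#", 1)[0].strip()
    if not stripped:
        return None
    tokens = [t for t in stripped.replace(",", " ").split() if t]
    if len(tokens) < n_numeric:
        raise ValueError(f"expected at least {n_numeric} columns, got {len(tokens)}: {line!r}")
    values = [float(t) for t in tokens[:n_numeric]]
    label = " ".join(tokens[n_numeric:]) or None
    return values, label


def read_cells(path: str | Path) -> list[UnitCell]:
    """Read cells from text: columns ``a b c alpha beta gamma [label]``."""
    cells: list[UnitCell] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        parsed = _parse_line(line, 6)
        if parsed is None:
            continue
        values, label = parsed
        cells.append(UnitCell(*values, label=label or f"cell{len(cells) + 1}"))
    return cells


def write_cells(path: str | Path, cells: Iterable[UnitCell]) -> None:
    lines = ["# a b c alpha beta gamma label"]
    for cell in cells:
        nums = " ".join(f"{x:.6f}" for x in cell.parameters())
        lines.append(f"{nums} {cell.label or ''}".rstrip())
    Path(path).write_text("\n".join(lines) + "\n")


def read_s6(path: str | Path) -> tuple[np.ndarray, list[str | None]]:
    """Read S6 vectors from text (6 numeric columns [+ label]); returns (n, 6) array."""
    rows: list[list[float]] = []
    labels: list[str | None] = []
    for line in Path(path).read_text().splitlines():
        parsed = _parse_line(line, 6)
        if parsed is None:
            continue
        values, label = parsed
        rows.append(values)
        labels.append(label)
    return np.array(rows, dtype=float).reshape(-1, 6), labels


def write_s6(
    path: str | Path,
    vectors: np.ndarray,
    labels: Sequence[str | None] | None = None,
) -> None:
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    lines = ["# s1 s2 s3 s4 s5 s6 label"]
    for i, row in enumerate(vectors):
        nums = " ".join(f"{x:.9g}" for x in row)
        label = labels[i] if labels is not None else None
        lines.append(f"{nums} {label or ''}".rstrip())
    Path(path).write_text("\n".join(lines) + "\n")
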