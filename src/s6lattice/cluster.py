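"""Unit-cell clustering on the S6 metric, and the synthetic cell generator.

Serial-crystallography pipelines index one unit cell per diffraction image
and must group the images by lattice before merging; agglomerative
clustering on a lattice distance matrix is the standard approach.  The
generator emulates the relevant inputs without any downloads: random valid
cells, noisy replicates of a base cell (polymorph groups), and deliberately
unreduced re-presentations of a single lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform

from .cells import UnitCell, basis_to_cell, cell_to_basis, cell_to_s6, s6_to_cell
from .distance import Strategy, distance_matrix_s6
from .reduction import selling_reduce, unreduce_random

__all__ = [
    "CellSet",
    "LinkageTree",
    "generate_cells",
    "distance_matrix",
    "cluster_cells",
    "linkage_to_newick",
]

GeneratorMode = Literal["random", "perturbed", "unreduced_presentations"]


@dataclass(frozen=True)
class CellSet:
    """A labelled list of cells plus the generator provenance that made it."""

    cells: tuple[UnitCell, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [c.label for c in self.cells]
        if len(set(labels)) != len(labels):
            raise ValueError("cell labels must be unique")

    def __len__(self) -> int:
        return len(self.cells)

    def labels(self) -> list[str]:
        return [c.label or "" for c in self.cells]

    def s6(self) -> np.ndarray:
        return np.stack([cell_to_s6(c) for c in self.cells])


@dataclass(frozen=True)
class LinkageTree:
    """Agglomerative merge list (scipy linkage matrix) with its method name."""

    merges: np.ndarray  # (n-1, 4) scipy linkage matrix; heights in Å²
    method: str
    labels: tuple[str, ...]

    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def _random_basis(rng: np.random.Generator, length_range: tuple[float, float]) -> np.ndarray:
    """Random well-conditioned basis: random directions scaled to target lengths."""
    while True:
        m = rng.normal(size=(3, 3))
        if np.abs(np.linalg.det(m)) < 0.1:
            continue  # nearly coplanar axes: resample
        if np.linalg.det(m) < 0:
            m[2] = -m[2]
        lengths = rng.uniform(*length_range, size=3)
        m *= (lengths / np.linalg.norm(m, axis=1))[:, None]
        return m


def generate_cells(
    n: int,
    mode: GeneratorMode = "random",
    base: UnitCell | None = None,
    sigma: float = 0.0,
    seed: int | np.random.Generator = 0,
    k_max: int = 3,
    length_range: tuple[float, float] = (3.0, 100.0),
    label_prefix: str = "cell",
) -> CellSet:
    """Synthetic cells with a fixed seed (bit-identical across runs).

    ``random`` samples valid cells from random basis vectors (validity is
    guaranteed by construction).  ``perturbed`` applies a random linear
    distortion B′ = (I + σE)·B, E ~ N(0,1)³ˣ³, to the base cell's basis —
    multiplicative noise that perturbs lengths and angles together and
    degenerates to exact copies at σ = 0.  ``unreduced_presentations``
    applies 1..k_max random edge transforms plus a random reflection to the
    base lattice, yielding alternative presentations of one lattice.
    """
    if sigma < 0:
        raise ValueError("sigma must be ≥ 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mode in ("perturbed", "unreduced_presentations") and base is None:
        raise ValueError(f"mode {mode!r} requires a base cell")
    cells: list[UnitCell] = []
    for i in range(n):
        label = f"{label_prefix}{i:04d}"
        if mode == "random":
            cells.append(basis_to_cell(_basis_triple(_random_basis(rng, length_range)), label))
        elif mode == "perturbed":
            b0 = cell_to_basis(base).vectors()[:3]
            b = (np.eye(3) + sigma * rng.normal(size=(3, 3))) @ b0
            cells.append(basis_to_cell(_basis_triple(b), label))
        elif mode == "unreduced_presentations":
            reduced = selling_reduce(cell_to_s6(base)).reduced
            k = int(rng.integers(1, k_max + 1))
            v = unreduce_random(reduced, k, rng, reflect=True)
            cells.append(s6_to_cell(v, label))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    provenance = {
        "mode": mode,
        "n": n,
        "sigma": sigma,
        "seed": None if isinstance(seed, np.random.Generator) else int(seed),
        "base": base.parameters() if base is not None else None,
        "k_max": k_max,
        "length_range": length_range,
    }
    return CellSet(tuple(cells), provenance)


def _basis_triple(rows: np.ndarray):
    from .cells import BasisTriple

    return BasisTriple(rows[0], rows[1], rows[2])


def distance_matrix(cells: CellSet | Sequence[UnitCell], strategy: Strategy = "vcp1") -> np.ndarray:
    """Square symmetric lattice-distance matrix (Å²) over a cell set."""
    cell_list = cells.cells if isinstance(cells, CellSet) else tuple(cells)
    reduced = np.stack([selling_reduce(cell_to_s6(c)).reduced for c in cell_list])
    return distance_matrix_s6(reduced, strategy=strategy)


def cluster_cells(
    matrix: np.ndarray,
    method: Literal["single", "complete", "average"] = "average",
    cut_height: float | None = None,
    k: int | None = None,
    labels: Sequence[str] | None = None,
) -> tuple[LinkageTree, np.ndarray]:
    """Agglomerative clustering of a precomputed dissimilarity matrix.

    Returns the linkage tree and flat cluster assignments (1-based, as scipy
    numbers them).  Cut either at a height (Å²) or into ``k`` clusters; with
    neither, every point gets its own cluster.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if n == 0:
        raise ValueError("empty distance matrix")
    if labels is None:
        labels = [f"cell{i:04d}" for i in range(n)]
    if n == 1:
        tree = LinkageTree(np.zeros((0, 4)), method, tuple(labels))
        return tree, np.array([1])
    condensed = squareform(np.maximum(matrix, matrix.T), checks=False)
    merges = linkage(condensed, method=method)
    tree = LinkageTree(merges, method, tuple(labels))
    if cut_height is not None:
        assign = fcluster(merges, t=cut_height, criterion="distance")
    elif k is not None:
        assign = fcluster(merges, t=k, criterion="maxclust")
    else:
        assign = np.arange(1, n + 1)
    return tree, np.asarray(assign)


def linkage_to_newick(tree: LinkageTree) -> str:
    """Serialise the dendrogram as a Newick string (branch lengths in Å²)."""
    if tree.merges.shape[0] == 0:
        return f"({tree.labels[0]}:0);" if tree.labels else "();"
    root = to_tree(tree.merges)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{tree.labels[node.id]}:{length:.9g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.9g}"

    return render(root, root.dist).rsplit(":", 1)[0] + ";"
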