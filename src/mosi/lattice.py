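"""Spatial data model: voxel lattice, 26-connectivity adjacency, parcellations.

Dense voxel indices enumerate in-mask lattice cells in row-major (x, y, z)
order. Two voxels are adjacent when their unit cubes share a face, an edge or
a corner, i.e. when all three coordinate differences are at most 1 — each
voxel therefore has at most 26 neighbors. All algorithmic topology in this
package is defined on that lattice graph; any NIfTI affine is carried for
round-trip I/O only and never interpreted.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph

__all__ = [
    "VoxelLattice",
    "AdjacencyGraph",
    "Parcellation",
    "build_voxel_adjacency",
    "connected_components",
    "module_neighbor_pairs",
    "split_disconnected_modules",
]

# the 13 lexicographically positive offsets; symmetrizing yields all 26
_HALF_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) > (0, 0, 0)
    ],
    dtype=np.int64,
)


class VoxelLattice:
    """A 3D grid with a boolean mask and dense in-mask voxel indexing.

    Parameters
    ----------
    mask : (nx, ny, nz) bool array
        True for in-mask (e.g. cortical) voxels. Must contain at least one
        True cell.
    affine : (4, 4) array, optional
        Voxel-to-world transform carried through I/O. Defaults to identity.

    Attributes
    ----------
    dims : tuple of int
        Lattice shape ``(nx, ny, nz)``.
    coords : (V, 3) int array
        Lattice coordinates of in-mask voxels, in dense-index order.
    index_of : (nx, ny, nz) int array
        Dense index per cell, -1 outside the mask.
    """

    def __init__(self, mask: np.ndarray, affine: np.ndarray | None = None):
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {mask.shape}")
        if not mask.any():
            raise ValueError("empty lattice")
        self.mask = mask
        self.dims: tuple[int, int, int] = mask.shape
        self.affine = np.eye(4) if affine is None else np.asarray(affine, float)
        self.coords = np.argwhere(mask)
        self.n_voxels = int(self.coords.shape[0])
        vol = np.full(self.dims, -1, dtype=np.int64)
        vol[mask] = np.arange(self.n_voxels)
        self.index_of = vol
        self._adjacency: AdjacencyGraph | None = None

    @classmethod
    def full(cls, dims: Sequence[int], affine: np.ndarray | None = None) -> "VoxelLattice":
        """Lattice whose mask covers the entire box ``dims``."""
        return cls(np.ones(tuple(int(d) for d in dims), dtype=bool), affine=affine)

    def adjacency(self) -> "AdjacencyGraph":
        """The (cached) 26-connectivity graph over in-mask voxels."""
        if self._adjacency is None:
            self._adjacency = build_voxel_adjacency(self)
        return self._adjacency

    def __repr__(self) -> str:  # pragma: no cover
        return f"VoxelLattice(dims={self.dims}, n_voxels={self.n_voxels})"


class AdjacencyGraph:
    """Undirected 26-neighborhood graph over dense voxel indices."""

    def __init__(self, matrix: sparse.csr_array, n_voxels: int):
        self.matrix = matrix
        self.n_voxels = n_voxels

    def neighbors(self, i: int) -> np.ndarray:
        """Dense indices adjacent to voxel ``i`` (sorted ascending)."""
        start, stop = self.matrix.indptr[i], self.matrix.indptr[i + 1]
        return self.matrix.indices[start:stop]

    @property
    def degrees(self) -> np.ndarray:
        return np.diff(self.matrix.indptr)

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Edges as (i, j) arrays with i < j, deterministic order."""
        coo = sparse.triu(self.matrix, k=1).tocoo()
        order = np.lexsort((coo.col, coo.row))
        return coo.row[order], coo.col[order]


def build_voxel_adjacency(lattice: VoxelLattice) -> AdjacencyGraph:
    """Build the 26-connectivity graph of a lattice.

    An edge joins two in-mask voxels iff they differ by at most 1 in each of
    the three coordinates (and are distinct). Masked-out cells contribute no
    node and no edge.
    """
    dims = np.asarray(lattice.dims)
    rows, cols = [], []
    for off in _HALF_OFFSETS:
        nb = lattice.coords + off
        valid = np.all((nb >= 0) & (nb < dims), axis=1)
        j = lattice.index_of[tuple(nb[valid].T)]
        keep = j >= 0
        i = np.flatnonzero(valid)[keep]
        rows.append(i)
        cols.append(j[keep])
    i = np.concatenate(rows)
    j = np.concatenate(cols)
    data = np.ones(2 * len(i), dtype=bool)
    mat = sparse.coo_array(
        (data, (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(lattice.n_voxels, lattice.n_voxels),
    ).tocsr()
    mat.sort_indices()
    return AdjacencyGraph(mat, lattice.n_voxels)


def connected_components(
    voxels: Iterable[int], adjacency: AdjacencyGraph
) -> list[np.ndarray]:
    """Partition a voxel set into maximal 26-connected components.

    Returns components as sorted index arrays, ordered by their smallest
    member. An empty input yields an empty list.
    """
    idx = np.unique(np.fromiter(voxels, dtype=np.int64, count=-1))
    if idx.size == 0:
        return []
    if idx[0] < 0 or idx[-1] >= adjacency.n_voxels:
        raise ValueError("voxel indices outside the lattice")
    sub = adjacency.matrix[idx][:, idx]
    n_comp, labels = csgraph.connected_components(sub, directed=False)
    comps = [idx[labels == c] for c in range(n_comp)]
    comps.sort(key=lambda a: int(a[0]))
    return comps


class Parcellation:
    """Integer module label (>= 1) per dense voxel index."""

    def __init__(self, labels: np.ndarray):
        labels = np.asarray(labels)
        if labels.ndim != 1:
            raise ValueError("labels must be a 1D array over dense voxel indices")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if labels.size == 0 or labels.min() < 1:
            raise ValueError("every in-mask voxel needs a positive module label")
        self.labels = labels.astype(np.int64, copy=True)

    @property
    def n_voxels(self) -> int:
        return self.labels.size

    @property
    def module_ids(self) -> np.ndarray:
        return np.unique(self.labels)

    @property
    def n_modules(self) -> int:
        return int(np.unique(self.labels).size)

    def sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels, return_counts=True)
        return {int(u): int(c) for u, c in zip(ids, counts)}

    def voxels_of(self, module_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == module_id)

    def canonicalized(self) -> "Parcellation":
        """Renumber modules 1..M in order of first voxel occurrence."""
        _, first = np.unique(self.labels, return_index=True)
        order = self.labels[np.sort(first)]
        mapping = {int(old): new for new, old in enumerate(order, start=1)}
        return Parcellation(np.array([mapping[int(l)] for l in self.labels]))

    def copy(self) -> "Parcellation":
        return Parcellation(self.labels)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Parcellation) and np.array_equal(
            self.labels, other.labels
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"Parcellation(n_voxels={self.n_voxels}, n_modules={self.n_modules})"


def module_neighbor_pairs(
    parc: Parcellation, adjacency: AdjacencyGraph
) -> set[tuple[int, int]]:
    """Unordered pairs of distinct modules with at least one 26-adjacent
    voxel contact."""
    if parc.n_voxels != adjacency.n_voxels:
        raise ValueError("parcellation and adjacency cover different voxel sets")
    i, j = adjacency.edge_arrays()
    lu, lv = parc.labels[i], parc.labels[j]
    differ = lu != lv
    lo = np.minimum(lu[differ], lv[differ])
    hi = np.maximum(lu[differ], lv[differ])
    return {(int(a), int(b)) for a, b in zip(lo, hi)}


def split_disconnected_modules(
    parc: Parcellation, adjacency: AdjacencyGraph
) -> Parcellation:
    """Enforce the contiguity invariant.

    Every module whose voxel set falls into several 26-connected components
    is separated into one module per component. Labels are renumbered 1..M,
    ordered by (original label, smallest voxel index).
    """
    i, j = adjacency.edge_arrays()
    same = parc.labels[i] == parc.labels[j]
    mat = sparse.coo_array(
        (
            np.ones(2 * int(same.sum()), dtype=bool),
            (
                np.concatenate([i[same], j[same]]),
                np.concatenate([j[same], i[same]]),
            ),
        ),
        shape=(parc.n_voxels, parc.n_voxels),
    ).tocsr()
    _, comp = csgraph.connected_components(mat, directed=False)
    # order new labels by (old label, first voxel) for determinism
    first = np.full(comp.max() + 1, parc.n_voxels, dtype=np.int64)
    np.minimum.at(first, comp, np.arange(parc.n_voxels))
    old = parc.labels[first]
    order = np.lexsort((first, old))
    rank = np.empty_like(order)
    rank[order] = np.arange(1, order.size + 1)
    return Parcellation(rank[comp])
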