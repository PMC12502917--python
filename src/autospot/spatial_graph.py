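"""Spot neighborhood graphs for spatial transcriptomics lattices.

Spots are points in the plane; two spots are neighbors when their Euclidean
distance is at most a radius ``delta`` (distance exactly ``delta`` is
included).  On regular Visium-like unit grids with ``delta = 1`` this yields
rook adjacency: interior spots have four neighbors, edge spots three, corner
spots two.  The per-spot neighbor count ``|N(i)|`` enters the autologistic
model as the boundary adjustment that divides the spatial coupling among
however many neighbors a spot actually has.

An optional rectangular period turns the plane into a torus (wrap-around
distance), which is the layout used for exactness checks: on a torus every
spot has the same neighbor count, so the per-spot conditionals are consistent
with a joint Ising-type law.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "NeighborGraph",
    "build_neighbor_graph",
    "neighbor_label_fraction",
    "neighbor_fractions",
    "read_coords",
    "write_edge_list",
    "read_edge_list",
]


@dataclass
class NeighborGraph:
    """Symmetric neighbor structure under a distance threshold.

    Attributes
    ----------
    n_spots : int
        Number of spots.
    neighbor_sets : list of ndarray
        ``neighbor_sets[i]`` holds the sorted indices of the neighbors of
        spot ``i`` (never including ``i`` itself).
    neighbor_counts : ndarray of int
        ``|N(i)|`` for every spot.
    delta : float
        The distance threshold the graph was built with.
    period : tuple or None
        ``(Lx, Ly)`` when distances wrap around a torus, else ``None``.
    """

    n_spots: int
    neighbor_sets: list
    neighbor_counts: np.ndarray
    delta: float
    period: tuple | None = None
    _flat: tuple = field(default=None, repr=False, compare=False)

    def flat(self):
        """CSR-style view ``(indices, indptr)`` over all neighbor sets."""
        if self._flat is None:
            indptr = np.zeros(self.n_spots + 1, dtype=np.int64)
            np.cumsum(self.neighbor_counts, out=indptr[1:])
            if self.n_spots and indptr[-1]:
                indices = np.concatenate(self.neighbor_sets)
            else:
                indices = np.empty(0, dtype=np.int64)
            self._flat = (indices.astype(np.int64), indptr)
        return self._flat


def build_neighbor_graph(coords, delta, period=None) -> NeighborGraph:
    """Build the Euclidean-distance neighbor graph ``N(i) = {j : ||si-sj|| <= delta}``.

    Parameters
    ----------
    coords : (n, 2) array-like
        Spot coordinates, in arbitrary real units.  No grid structure is
        assumed.  Duplicated coordinates are rejected (merging them silently
        would corrupt spot-level labels).
    delta : float
        Positive distance threshold; ties at exactly ``delta`` are neighbors.
    period : tuple of two floats, optional
        When given, distances wrap modulo ``(Lx, Ly)`` (toroidal layout).
        Coordinates must then lie in ``[0, Lx) x [0, Ly)``.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError(f"coords must be an (n, 2) array, got shape {coords.shape}")
    if not np.all(np.isfinite(coords)):
        bad = np.where(~np.isfinite(coords).all(axis=1))[0]
        raise ValueError(f"non-finite coordinates at spot indices {bad.tolist()}")
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    n = coords.shape[0]

    _, inv, counts = np.unique(coords, axis=0, return_inverse=True, return_counts=True)
    if np.any(counts > 1):
        dup_groups = [np.where(inv == g)[0].tolist() for g in np.where(counts > 1)[0]]
        raise ValueError(f"duplicate coordinates at spot index groups {dup_groups}")

    boxsize = None
    if period is not None:
        boxsize = np.asarray(period, dtype=float)
        if boxsize.shape != (2,) or np.any(boxsize <= 0):
            raise ValueError("period must be two positive lengths (Lx, Ly)")
        if np.any(coords < 0) or np.any(coords >= boxsize):
            raise ValueError("toroidal coordinates must lie in [0, Lx) x [0, Ly)")

    sets = [np.empty(0, dtype=np.int64) for _ in range(n)]
    if n > 1:
        tree = cKDTree(coords, boxsize=boxsize)
        pairs = tree.query_pairs(r=float(delta), output_type="ndarray")
        if len(pairs):
            i, j = pairs[:, 0], pairs[:, 1]
            order = np.argsort(np.concatenate([i, j]), kind="stable")
            src = np.concatenate([i, j])[order]
            dst = np.concatenate([j, i])[order]
            starts = np.searchsorted(src, np.arange(n))
            ends = np.searchsorted(src, np.arange(n), side="right")
            sets = [np.sort(dst[a:b]) for a, b in zip(starts, ends)]
    counts_arr = np.array([len(s) for s in sets], dtype=np.int64)
    return NeighborGraph(
        n_spots=n,
        neighbor_sets=sets,
        neighbor_counts=counts_arr,
        delta=float(delta),
        period=tuple(period) if period is not None else None,
    )


def neighbor_label_fraction(graph: NeighborGraph, i: int, y) -> float:
    """Fraction of the neighbors of spot ``i`` carrying label 1.

    Returns ``(1/|N(i)|) * sum_{j in N(i)} y_j``, the quantity multiplying the
    spatial coupling in the autologistic conditional.  Isolated spots
    (``|N(i)| = 0``) return 0 so the spatial term vanishes for them.
    """
    if not 0 <= i < graph.n_spots:
        raise IndexError(f"spot index {i} out of range [0, {graph.n_spots})")
    nbrs = graph.neighbor_sets[i]
    if len(nbrs) == 0:
        return 0.0
    y = np.asarray(y, dtype=float)
    return float(y[nbrs].mean())


def neighbor_fractions(graph: NeighborGraph, y) -> np.ndarray:
    """Vectorized :func:`neighbor_label_fraction` over every spot."""
    y = np.asarray(y, dtype=float)
    if y.shape[0] != graph.n_spots:
        raise ValueError("y must have one entry per spot")
    indices, _ = graph.flat()
    counts = graph.neighbor_counts
    owner = np.repeat(np.arange(graph.n_spots), counts)
    sums = np.bincount(owner, weights=y[indices], minlength=graph.n_spots)
    out = np.zeros(graph.n_spots)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    return out


def read_coords(path):
    """Read a delimited (spot_id, x, y) table; returns (spot_ids, (n,2) coords)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    for col in ("spot_id", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"coordinate table {path} lacks required column {col!r}")
    return df["spot_id"].astype(str).tolist(), df[["x", "y"]].to_numpy(dtype=float)


def write_edge_list(graph: NeighborGraph, path, spot_ids=None):
    """Export the graph as a deduplicated two-column edge list (i < j once per pair)."""
    rows = []
    for i in range(graph.n_spots):
        for j in graph.neighbor_sets[i]:
            if i < j:
                rows.append((i, int(j)))
    df = pd.DataFrame(rows, columns=["spot_i", "spot_j"])
    if spot_ids is not None:
        df["spot_i"] = [spot_ids[i] for i in df["spot_i"]]
        df["spot_j"] = [spot_ids[j] for j in df["spot_j"]]
    df.to_csv(path, sep="\t", index=False)
    return df


def read_edge_list(path, n_spots, delta=np.nan):
    """Rebuild a :class:`NeighborGraph` from a deduplicated integer edge list."""
    df = pd.read_csv(path, sep="\t")
    sets = [[] for _ in range(n_spots)]
    for i, j in df.itertuples(index=False):
        sets[int(i)].append(int(j))
        sets[int(j)].append(int(i))
    sets = [np.array(sorted(s), dtype=np.int64) for s in sets]
    counts = np.array([len(s) for s in sets], dtype=np.int64)
    return NeighborGraph(n_spots=n_spots, neighbor_sets=sets, neighbor_counts=counts, delta=float(delta))
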