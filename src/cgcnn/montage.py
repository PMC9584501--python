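"""Electrode montage, the 8-neighbourhood EEG graph, and its spectral operators.

The montage abstracts a scalp layout to an integer grid: each electrode
occupies one (row, col) cell.  Two electrodes are connected iff their cells
are within Chebyshev distance 1 on the grid, so an interior node has eight
neighbours (up, down, left, right and the four diagonals).  Every node also
carries a self-loop.  From the resulting adjacency the symmetric normalized
Laplacian, its rescaled variant and the Chebyshev polynomial basis used by
the graph convolution are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Montage",
    "ElectrodeGraph",
    "SpectralOperators",
    "read_montage",
    "build_graph",
    "build_spectral_operators",
]


class MontageError(ValueError):
    """Raised when a montage table violates its invariants."""


@dataclass(frozen=True)
class Montage:
    """Electrode layout on an integer grid.

    Parameters
    ----------
    names : tuple of str
        Electrode names, unique, in node order.
    rows, cols : tuple of int
        Grid coordinates, one (row, col) cell per electrode, cells unique.
    """

    names: tuple
    rows: tuple
    cols: tuple

    def __post_init__(self):
        if not (len(self.names) == len(self.rows) == len(self.cols)):
            raise MontageError("names, rows and cols must have equal length")
        if len(self.names) == 0:
            raise MontageError("montage must contain at least one electrode")
        seen = {}
        for name in self.names:
            if name in seen:
                raise MontageError(f"duplicate electrode name: {name!r}")
            seen[name] = True
        cells = {}
        for name, r, c in zip(self.names, self.rows, self.cols):
            if r < 0 or c < 0:
                raise MontageError(f"negative grid coordinate for {name!r}")
            if (r, c) in cells:
                raise MontageError(
                    f"electrodes {cells[(r, c)]!r} and {name!r} share grid cell {(r, c)}"
                )
            cells[(r, c)] = name

    @property
    def n_electrodes(self) -> int:
        return len(self.names)

    @classmethod
    def from_table(cls, names, rows, cols) -> "Montage":
        return cls(tuple(names), tuple(int(r) for r in rows), tuple(int(c) for c in cols))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"name": self.names, "row": self.rows, "col": self.cols})


@dataclass(frozen=True)
class ElectrodeGraph:
    """Undirected electrode graph with self-loops.

    ``adjacency`` is the dense binary matrix A with A[i, i] = 1 and
    A[i, j] = 1 iff (i, j) is an edge; ``edges`` holds the unordered
    off-diagonal pairs and ``neighbor_sets`` the 8-neighbourhood relation.
    """

    n_nodes: int
    edges: frozenset
    adjacency: np.ndarray = field(repr=False)

    @property
    def neighbor_sets(self) -> list:
        out = [set() for _ in range(self.n_nodes)]
        for i, j in self.edges:
            out[i].add(j)
            out[j].add(i)
        return out


@dataclass(frozen=True)
class SpectralOperators:
    """Degree matrix, normalized/scaled Laplacians and the Chebyshev basis.

    ``cheb_basis`` stacks T_0(L~) .. T_K(L~) along the first axis, computed
    by the recursion T_k = 2 L~ T_{k-1} - T_{k-2} with T_0 = I, T_1 = L~.
    """

    degree: np.ndarray = field(repr=False)
    laplacian_norm: np.ndarray = field(repr=False)
    lambda_max: float = 0.0
    laplacian_scaled: np.ndarray = field(repr=False, default=None)
    cheb_order: int = 3
    cheb_basis: np.ndarray = field(repr=False, default=None)

    @property
    def n_nodes(self) -> int:
        return self.laplacian_norm.shape[0]


def read_montage(path) -> Montage:
    """Read a montage CSV with header ``name,row,col``.

    Raises
    ------
    MontageError
        On duplicate names, duplicate cells or non-integer coordinates.
    """
    df = pd.read_csv(path, dtype={"name": str})
    missing = {"name", "row", "col"} - set(df.columns)
    if missing:
        raise MontageError(f"montage CSV missing columns: {sorted(missing)}")
    for col in ("row", "col"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or not np.allclose(vals, vals.round()):
            bad = df.loc[vals.isna() | ~np.isclose(vals, vals.round()), "name"].tolist()
            raise MontageError(f"non-integer {col} coordinate for electrodes {bad}")
        df[col] = vals.astype(int)
    return Montage.from_table(df["name"], df["row"], df["col"])


def build_graph(montage: Montage) -> ElectrodeGraph:
    """Connect electrodes whose grid cells are at Chebyshev distance 1."""
    n = montage.n_electrodes
    rows = np.asarray(montage.rows)
    cols = np.asarray(montage.cols)
    dr = np.abs(rows[:, None] - rows[None, :])
    dc = np.abs(cols[:, None] - cols[None, :])
    adj = ((np.maximum(dr, dc) == 1)).astype(np.int8)
    np.fill_diagonal(adj, 1)
    ii, jj = np.nonzero(np.triu(adj, k=1))
    edges = frozenset((int(i), int(j)) for i, j in zip(ii, jj))
    return ElectrodeGraph(n_nodes=n, edges=edges, adjacency=adj.astype(float))


def build_spectral_operators(graph: ElectrodeGraph, K: int = 3) -> SpectralOperators:
    """Compute D, L = I - D^{-1/2} A D^{-1/2}, L~ = 2L/lambda_max - I and T_k(L~).

    lambda_max is computed exactly with a symmetric eigensolver; graphs here
    are tiny so the cost is negligible.  Isolated nodes (degree 1 from the
    self-loop alone) are handled by the ordinary normalization.
    """
    if K < 0:
        raise ValueError(f"Chebyshev order K must be >= 0, got {K}")
    A = np.asarray(graph.adjacency, dtype=float)
    n = A.shape[0]
    deg = A.sum(axis=1)
    D = np.diag(deg)
    with np.errstate(divide="ignore"):
        d_isqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
    L = np.eye(n) - (d_isqrt[:, None] * A) * d_isqrt[None, :]
    L = (L + L.T) / 2.0  # enforce exact symmetry
    lam_max = float(np.linalg.eigvalsh(L)[-1])
    if lam_max <= 0:
        lam_max = 2.0  # degenerate single-node / edgeless graph
    L_scaled = 2.0 * L / lam_max - np.eye(n)
    basis = np.empty((K + 1, n, n))
    basis[0] = np.eye(n)
    if K >= 1:
        basis[1] = L_scaled
    for k in range(2, K + 1):
        basis[k] = 2.0 * L_scaled @ basis[k - 1] - basis[k - 2]
    return SpectralOperators(
        degree=D,
        laplacian_norm=L,
        lambda_max=lam_max,
        laplacian_scaled=L_scaled,
        cheb_order=K,
        cheb_basis=basis,
    )
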