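"""Density-thresholded graph series, node strength, and strength AUC.

The hubness statistic works on whole-brain Pearson correlation matrices.
A connected backbone (maximum spanning tree on ``|r|``) guarantees every
thresholded graph stays connected; remaining edges are appended in
descending order of ``|r|`` (a negative and a positive correlation of equal
magnitude share a rank), producing a nested series of signed-weight graphs
at densities 5%..50% in 1% steps.  Node strength is the signed sum of the
weights of a node's retained edges; the per-node summary is the trapezoidal
area under the strength-vs-density curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree

DENSITIES = np.round(np.arange(0.05, 0.501, 0.01), 2)  # 46 values


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def edge_count_at_density(density: float, n_nodes: int) -> int:
    """Number of retained edges at a given density (never below the backbone)."""
    n_pairs = n_nodes * (n_nodes - 1) // 2
    return max(n_nodes - 1, _round_half_away(density * n_pairs))


def validate_matrix(matrix: np.ndarray) -> None:
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix must be square, got shape {m.shape}")
    if not np.isfinite(m[~np.eye(len(m), dtype=bool)]).all():
        raise ValueError("matrix contains non-finite off-diagonal entries")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("matrix is not symmetric")


def maximum_spanning_tree_edges(matrix: np.ndarray) -> np.ndarray:
    """Backbone edge indices: maximum spanning tree on |r|.

    Returns an array of (i, j) pairs, i < j, with n_nodes - 1 rows.
    """
    validate_matrix(matrix)
    n = matrix.shape[0]
    absw = np.abs(np.asarray(matrix, dtype=float))
    np.fill_diagonal(absw, 0.0)
    # scipy finds a minimum spanning tree; negate to get the maximum one.
    # Shift below zero so zero-weight edges are still explicit graph edges.
    mst = minimum_spanning_tree(csr_matrix(np.triu(-(absw + 1.0), k=1)))
    ii, jj = mst.nonzero()
    lo, hi = np.minimum(ii, jj), np.maximum(ii, jj)
    order = np.lexsort((hi, lo))
    edges = np.column_stack([lo[order], hi[order]])
    if len(edges) != n - 1:
        raise ValueError("backbone is not a spanning tree; is the graph connected?")
    return edges


@dataclass
class DensityGraphSeries:
    """Nested signed-weight graphs over the density sweep.

    Edges are stored once in inclusion order: the backbone first, then the
    remaining node pairs in descending ``|r|`` (ties broken by ascending
    (i, j)).  The graph at density ``rho`` consists of the first
    ``counts[k]`` edges.
    """

    n_nodes: int
    edges: np.ndarray  # (n_pairs, 2) int, inclusion order
    weights: np.ndarray  # (n_pairs,) signed weights, same order
    densities: np.ndarray = field(default_factory=lambda: DENSITIES.copy())

    @property
    def counts(self) -> np.ndarray:
        return np.array(
            [edge_count_at_density(d, self.n_nodes) for d in self.densities]
        )

    @property
    def backbone(self) -> np.ndarray:
        return self.edges[: self.n_nodes - 1]

    def edge_set(self, k: int) -> set[tuple[int, int]]:
        """Retained edge set at the k-th density."""
        c = self.counts[k]
        return {tuple(e) for e in self.edges[:c]}

    def strength_curves(self) -> np.ndarray:
        """Signed node strength at every density: (n_densities, n_nodes)."""
        return _strength_curves(self, signed=True)

    def strength_curves_absolute(self) -> np.ndarray:
        """Node strength using absolute weights: (n_densities, n_nodes)."""
        return _strength_curves(self, signed=False)


def _strength_curves(series: DensityGraphSeries, signed: bool) -> np.ndarray:
    w = series.weights if signed else np.abs(series.weights)
    counts = series.counts
    out = np.zeros((len(counts), series.n_nodes))
    s = np.zeros(series.n_nodes)
    prev = 0
    for k, c in enumerate(counts):
        if c > prev:
            e = series.edges[prev:c]
            np.add.at(s, e[:, 0], w[prev:c])
            np.add.at(s, e[:, 1], w[prev:c])
            prev = c
        out[k] = s
    return out


def build_density_series(
    matrix: np.ndarray, densities: np.ndarray | None = None
) -> DensityGraphSeries:
    """Build the nested density-thresholded graph series for one matrix."""
    validate_matrix(matrix)
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = m[iu, ju]
    absw = np.abs(w)

    bb = maximum_spanning_tree_edges(m)
    pair_id = iu * n + ju
    bb_id = bb[:, 0] * n + bb[:, 1]
    is_backbone = np.isin(pair_id, bb_id)

    rest = np.flatnonzero(~is_backbone)
    # descending |r|; ties by ascending (i, j)
    order = rest[np.lexsort((ju[rest], iu[rest], -absw[rest]))]
    bb_rows = np.flatnonzero(is_backbone)
    full = np.concatenate([bb_rows, order])
    edges = np.column_stack([iu[full], ju[full]])
    weights = w[full]
    kw = {} if densities is None else {"densities": np.asarray(densities)}
    return DensityGraphSeries(n_nodes=n, edges=edges, weights=weights, **kw)


def node_strength(series: DensityGraphSeries, k: int, signed: bool = True) -> np.ndarray:
    """Per-node strength at the k-th density of the series."""
    curves = _strength_curves(series, signed=signed)
    return curves[k]


def strength_auc(curve: np.ndarray, densities: np.ndarray = DENSITIES) -> float:
    """Trapezoidal area under a strength-vs-density curve.

    For the default sweep (0.05..0.50) a constant curve ``c`` integrates to
    ``0.45 * c``.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.shape[-1] != len(densities):
        raise ValueError(
            f"curve has {curve.shape[-1]} values, expected {len(densities)}"
        )
    return np.trapezoid(curve, densities, axis=-1)


def strength_auc_matrix(matrix: np.ndarray, signed: bool = True) -> np.ndarray:
    """Strength AUC for every node of a connectivity matrix."""
    series = build_density_series(matrix)
    curves = _strength_curves(series, signed=signed)
    return strength_auc(curves.T)


def strength_auc_table(
    matrices: dict[str, np.ndarray], labels: list[str], signed: bool = True
) -> pd.DataFrame:
    """Strength AUC per subject x region.

    Parameters
    ----------
    matrices
        subject_id -> connectivity matrix, all label-aligned.
    labels
        region labels, in matrix order.
    """
    rows = {}
    for sid, m in matrices.items():
        if m.shape != (len(labels), len(labels)):
            raise ValueError(f"matrix for {sid} does not match label count")
        rows[sid] = strength_auc_matrix(m, signed=signed)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    table.index.name = "subject_id"
    return table


def extract_thalamic_edges(
    matrix: np.ndarray, atlas, subdivision: str, side: str
) -> pd.Series:
    """Edge values from one thalamic subdivision to every other region.

    Returns a Series of length ``n_nodes - 1`` indexed by target label.
    """
    validate_matrix(matrix)
    i = atlas.thalamic_index(subdivision, side)
    targets = [lab for lab in atlas.labels if lab != atlas.labels[i]]
    idx = [atlas.index(lab) for lab in targets]
    return pd.Series(np.asarray(matrix, dtype=float)[i, idx], index=targets)
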