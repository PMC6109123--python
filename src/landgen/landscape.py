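"""Raster resistance graphs, circuit-theory and least-cost distances.

The landscape raster becomes a conductance-weighted graph (8-neighbourhood,
water excluded); effective resistance between focal cells is computed from
Laplacian solves, least-cost distances from Dijkstra over reciprocal
conductances. Candidate resistance models enumerate a step-10 grid for the
urban and managed-vegetation classes with urban > managed, forest fixed at 1
and water at 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.sparse.linalg import splu

from .datatypes import (
    FOREST,
    MANAGED_VEGETATION,
    URBAN,
    WATER,
    LandscapeRaster,
    PairwiseMatrix,
    ResistanceModel,
)

__all__ = [
    "RasterGraph",
    "build_graph",
    "effective_resistance",
    "least_cost_distance",
    "enumerate_candidate_models",
    "snap_to_nodes",
]


@dataclass
class RasterGraph:
    """Conductance graph over non-water raster cells."""

    n_nodes: int
    conductance: sp.csr_matrix     # symmetric, positive entries
    cell_index: np.ndarray         # (nrows, ncols) node id or -1 for water
    raster: LandscapeRaster

    def laplacian(self) -> sp.csr_matrix:
        C = self.conductance
        return (sp.diags(np.asarray(C.sum(axis=1)).ravel()) - C).tocsc()


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def build_graph(raster: LandscapeRaster, model: ResistanceModel) -> RasterGraph:
    """Per-cell resistance from the model; neighbour conductance 2/(r_a+r_b),
    scaled by 1/sqrt(2) on diagonal edges (average-resistance convention)."""
    classes = raster.classes
    present = set(np.unique(classes).tolist()) - {WATER}
    missing = present - set(model.values)
    if missing:
        raise KeyError(f"resistance model lacks classes {sorted(missing)}")
    nonwater = classes != WATER
    cell_index = -np.ones(classes.shape, dtype=int)
    cell_index[nonwater] = np.arange(nonwater.sum())
    res = np.zeros(classes.shape)
    for cls in present:
        res[classes == cls] = model[cls]

    rows_i, cols_j, data = [], [], []
    nrows, ncols = classes.shape
    for dr, dc in _NEIGHBORS:
        if (dr, dc) < (0, 0) or (dr, dc) == (0, -1):
            continue  # each undirected edge once
        r0, r1 = max(0, -dr), min(nrows, nrows - dr)
        c0, c1 = max(0, -dc), min(ncols, ncols - dc)
        a = cell_index[r0:r1, c0:c1]
        b = cell_index[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        ra = res[r0:r1, c0:c1]
        rb = res[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        ok = (a >= 0) & (b >= 0)
        cond = 2.0 / (ra[ok] + rb[ok])
        if dr != 0 and dc != 0:
            cond = cond / np.sqrt(2.0)
        rows_i.append(a[ok])
        cols_j.append(b[ok])
        data.append(cond)
    i = np.concatenate(rows_i)
    j = np.concatenate(cols_j)
    d = np.concatenate(data)
    n = int(nonwater.sum())
    C = sp.coo_matrix((np.r_[d, d], (np.r_[i, j], np.r_[j, i])), shape=(n, n)).tocsr()
    return RasterGraph(n_nodes=n, conductance=C, cell_index=cell_index, raster=raster)


def effective_resistance(graph: RasterGraph, focal_nodes: np.ndarray,
                         labels: list[str] | None = None) -> PairwiseMatrix:
    """Pairwise effective resistance between focal nodes.

    Solved from the graph Laplacian with one node grounded per connected
    component; pairs in different components get infinite resistance (flagged,
    not raised).
    """
    focal = np.asarray(focal_nodes, dtype=int)
    k = len(focal)
    labels = labels or [str(f) for f in focal]
    n_comp, comp = connected_components(graph.conductance, directed=False)
    R = np.full((k, k), np.inf)
    np.fill_diagonal(R, 0.0)
    Lap = graph.laplacian()
    for c in np.unique(comp[focal]):
        nodes = np.flatnonzero(comp == c)
        sel = np.flatnonzero(comp[focal] == c)
        if len(sel) < 2:
            continue
        sub = Lap[np.ix_(nodes, nodes)].tocsc()
        ground = len(nodes) - 1
        reduced = sub[:ground, :ground].tocsc()
        lu = splu(reduced)
        pos = {node: idx for idx, node in enumerate(nodes)}
        fidx = np.array([pos[f] for f in focal[sel]])
        # columns of the grounded inverse for each focal node
        cols = np.zeros((ground, len(sel)))
        for a, fi in enumerate(fidx):
            if fi == ground:
                continue  # grounded node: column is zero
            e = np.zeros(ground)
            e[fi] = 1.0
            cols[:, a] = lu.solve(e)
        aug = np.vstack([cols, np.zeros((1, len(sel)))])  # grounded row = 0
        S = aug[fidx, :]                                  # S_ab = (L+)_fa,fb style
        diag = np.diag(S)
        R[np.ix_(sel, sel)] = diag[:, None] + diag[None, :] - S - S.T
    R = np.maximum(R, 0.0)
    np.fill_diagonal(R, 0.0)
    return PairwiseMatrix(labels=labels, values=R, kind="effective_resistance")


def least_cost_distance(graph: RasterGraph, focal_nodes: np.ndarray,
                        labels: list[str] | None = None) -> PairwiseMatrix:
    """Dijkstra least-cost distances with edge cost = 1/conductance."""
    focal = np.asarray(focal_nodes, dtype=int)
    labels = labels or [str(f) for f in focal]
    C = graph.conductance.tocoo()
    cost = sp.coo_matrix((1.0 / C.data, (C.row, C.col)), shape=C.shape).tocsr()
    D = dijkstra(cost, directed=False, indices=focal)
    out = D[:, focal]
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 0.0)
    return PairwiseMatrix(labels=labels, values=out, kind="least_cost")


def enumerate_candidate_models(step: int = 10) -> list[ResistanceModel]:
    """All (urban, managed) pairs from the step grid with urban > managed.

    With step=10 over 10..100 this yields exactly 45 candidate models;
    forest is fixed at 1 (no resistance) and water at 100 (maximum).
    """
    grid = list(range(step, 101, step))
    models = []
    for managed in grid:
        for urban in grid:
            if urban > managed:
                models.append(ResistanceModel({
                    FOREST: 1.0,
                    MANAGED_VEGETATION: float(managed),
                    URBAN: float(urban),
                    WATER: 100.0,
                }))
    return models


def snap_to_nodes(graph: RasterGraph, coords_km: np.ndarray) -> np.ndarray:
    """Nearest non-water cell node for each (x, y) coordinate.

    Ties (and water hits) resolve to the nearest non-water cell in row-major
    order of the raster.
    """
    raster = graph.raster
    xs, ys = raster.cell_centers()
    valid = graph.cell_index.ravel() >= 0
    xs, ys = xs[valid], ys[valid]
    node_ids = graph.cell_index.ravel()[valid]
    out = np.empty(len(coords_km), dtype=int)
    for i, (x, y) in enumerate(np.asarray(coords_km, dtype=float)):
        d2 = (xs - x) ** 2 + (ys - y) ** 2
        out[i] = node_ids[int(np.argmin(d2))]  # argmin takes first = row-major
    return out
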