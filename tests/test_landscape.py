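import numpy as np
import pytest
import scipy.sparse as sp

from landgen.datatypes import (
    FOREST,
    MANAGED_VEGETATION,
    URBAN,
    WATER,
    LandscapeRaster,
    ResistanceModel,
)
from landgen.landscape import (
    RasterGraph,
    build_graph,
    effective_resistance,
    enumerate_candidate_models,
    least_cost_distance,
    snap_to_nodes,
)


def _uniform_raster(shape, cls=FOREST, cellsize=1.0):
    return LandscapeRaster(classes=np.full(shape, cls), cellsize_km=cellsize)


def _graph_from_edges(n, edges):
    """Hand-built conductance graph (for resistor-network analytics)."""
    i, j, c = zip(*edges)
    C = sp.coo_matrix((list(c) + list(c), (list(i) + list(j), list(j) + list(i))),
                      shape=(n, n)).tocsr()
    dummy = _uniform_raster((1, n))
    idx = np.arange(n).reshape(1, n)
    return RasterGraph(n_nodes=n, conductance=C, cell_index=idx, raster=dummy)


# --------------------------------------------------------- conductances

def test_edge_conductances():
    r = LandscapeRaster(classes=np.array([[FOREST, FOREST]]), cellsize_km=1.0)
    g = build_graph(r, ResistanceModel({FOREST: 1.0}))
    assert g.conductance[0, 1] == pytest.approx(1.0)

    r2 = LandscapeRaster(classes=np.array([[FOREST, URBAN]]), cellsize_km=1.0)
    g2 = build_graph(r2, ResistanceModel({FOREST: 1.0, URBAN: 3.0}))
    assert g2.conductance[0, 1] == pytest.approx(0.5)  # 2/(1+3)

    r3 = _uniform_raster((2, 2))
    g3 = build_graph(r3, ResistanceModel({FOREST: 1.0}))
    # diagonal neighbours scaled by 1/sqrt(2)
    assert g3.conductance[0, 3] == pytest.approx(1 / np.sqrt(2))


def test_unmapped_class_is_error():
    r = LandscapeRaster(classes=np.array([[FOREST, URBAN]]), cellsize_km=1.0)
    with pytest.raises(KeyError):
        build_graph(r, ResistanceModel({FOREST: 1.0}))


def test_water_cells_excluded():
    r = LandscapeRaster(classes=np.array([[FOREST, WATER, FOREST]]), cellsize_km=1.0)
    g = build_graph(r, ResistanceModel({FOREST: 1.0}))
    assert g.n_nodes == 2
    R = effective_resistance(g, np.array([0, 1]))
    assert np.isinf(R.values[0, 1])  # disconnected, flagged not raised


# --------------------------------------------------- resistor analytics

def test_series_resistance():
    g = _graph_from_edges(3, [(0, 1, 1.0), (1, 2, 1.0)])
    R = effective_resistance(g, np.array([0, 2]))
    assert R.values[0, 1] == pytest.approx(2.0, abs=1e-8)


def test_parallel_resistance():
    # two disjoint 2-edge unit paths joining nodes 0 and 3
    g = _graph_from_edges(4, [(0, 1, 1.0), (1, 3, 1.0), (0, 2, 1.0), (2, 3, 1.0)])
    R = effective_resistance(g, np.array([0, 3]))
    assert R.values[0, 1] == pytest.approx(1.0, abs=1e-8)


def test_effective_resistance_monotone_along_line():
    r = _uniform_raster((1, 8))
    g = build_graph(r, ResistanceModel({FOREST: 1.0}))
    R = effective_resistance(g, np.arange(8)).values
    assert (np.diff(R[0, 1:]) > 0).all()


def test_least_cost_uniform_row():
    r = _uniform_raster((1, 5))
    g = build_graph(r, ResistanceModel({FOREST: 1.0}))
    D = least_cost_distance(g, np.array([0, 3]))
    assert D.values[0, 1] == pytest.approx(3.0)


def test_least_cost_equals_brute_force_on_3x3():
    rng = np.random.default_rng(0)
    classes = rng.choice([FOREST, MANAGED_VEGETATION, URBAN], size=(3, 3))
    r = LandscapeRaster(classes=classes, cellsize_km=1.0)
    model = ResistanceModel({FOREST: 1.0, MANAGED_VEGETATION: 40.0, URBAN: 90.0})
    g = build_graph(r, model)
    D = least_cost_distance(g, np.arange(g.n_nodes)).values

    # brute force: enumerate all simple paths on the small graph
    import networkx as nx
    C = g.conductance.tocoo()
    nxg = nx.Graph()
    for i, j, c in zip(C.row, C.col, C.data):
        nxg.add_edge(int(i), int(j), w=1.0 / c)
    for s in range(g.n_nodes):
        for t in range(s + 1, g.n_nodes):
            best = min(
                sum(nxg[u][v]["w"] for u, v in zip(path, path[1:]))
                for path in nx.all_simple_paths(nxg, s, t)
            )
            assert D[s, t] == pytest.approx(best, rel=1e-10)


def test_effective_le_least_cost_random_rasters():
    rng = np.random.default_rng(1)
    for _ in range(10):
        classes = rng.choice([FOREST, MANAGED_VEGETATION, URBAN], size=(5, 5))
        r = LandscapeRaster(classes=classes, cellsize_km=1.0)
        model = ResistanceModel({FOREST: 1.0, MANAGED_VEGETATION: float(rng.integers(10, 90)),
                                 URBAN: float(rng.integers(50, 100))})
        g = build_graph(r, model)
        focal = rng.choice(g.n_nodes, size=4, replace=False)
        Re = effective_resistance(g, focal).values
        Dl = least_cost_distance(g, focal).values
        assert (Re <= Dl + 1e-9).all()


def test_rayleigh_edge_addition_never_increases_resistance():
    rng = np.random.default_rng(2)
    for _ in range(5):
        n = 8
        edges = [(i, i + 1, float(rng.uniform(0.5, 2))) for i in range(n - 1)]
        extra = [(int(rng.integers(0, n - 2)), n - 1, float(rng.uniform(0.5, 2)))]
        g1 = _graph_from_edges(n, edges)
        g2 = _graph_from_edges(n, edges + extra)
        focal = np.arange(n)
        R1 = effective_resistance(g1, focal).values
        R2 = effective_resistance(g2, focal).values
        assert (R2 <= R1 + 1e-9).all()


# ------------------------------------------------------ candidate models

def test_enumerate_candidate_models():
    models = enumerate_candidate_models()
    assert len(models) == 45
    assert all(m.urban > m.managed_vegetation for m in models)
    assert any(m.urban == 90 and m.managed_vegetation == 50 for m in models)
    assert all(m[FOREST] == 1.0 and m[WATER] == 100.0 for m in models)


def test_snap_to_nodes_prefers_nonwater():
    classes = np.array([[WATER, FOREST], [FOREST, FOREST]])
    r = LandscapeRaster(classes=classes, cellsize_km=1.0)
    g = build_graph(r, ResistanceModel({FOREST: 1.0}))
    # coordinate in the middle of the water cell snaps to nearest forest cell
    nodes = snap_to_nodes(g, np.array([[0.5, 1.5]]))
    assert nodes[0] in g.cell_index[g.cell_index >= 0]
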