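import numpy as np
import pytest

from landgen.datatypes import GenotypeMatrix
from landgen import spatial
from landgen.landscape import enumerate_candidate_models
from landgen.pipeline import resistance_distances

from conftest import panmictic_matrix


# ---------------------------------------------------------- codistance

def test_codistance_values():
    G = np.array([[0, 0, 1], [2, 0, 0]])
    gm = GenotypeMatrix(["a", "b"], ["l1", "l2", "l3"], G)
    D2 = spatial.genetic_codistance(gm)
    # opposite homozygotes (4) + identical (0) + het-hom (1)
    assert D2[0, 1] == pytest.approx(5.0)
    assert D2[0, 0] == 0.0


# --------------------------------------------------------- correlogram

def test_correlogram_null_calibration():
    rng = np.random.default_rng(0)
    gm = panmictic_matrix(rng, n=30, L=400)
    coords = rng.uniform(0, 12, (30, 2))
    cg = spatial.spatial_autocorrelogram(gm, coords, n_perm=199, n_boot=99, seed=1)
    t = cg.table.dropna(subset=["r"])
    inside = ((t["r"] >= t["env_lo"]) & (t["r"] <= t["env_hi"])).mean()
    assert inside >= 0.8
    # envelope roughly centred near zero under no structure
    mid = 0.5 * (t["env_lo"] + t["env_hi"])
    assert np.abs(mid).mean() < 0.01


def test_correlogram_ibd_pattern(full_bundle):
    gm, sf = full_bundle["gm"], full_bundle["sf"]
    cg = spatial.spatial_autocorrelogram(gm, sf.coords(), n_perm=199,
                                         n_boot=99, seed=2)
    assert cg.significant_positive()[0]        # first km bin positive
    far = cg.table.iloc[6:13]
    assert (far["r"].dropna() < 0).mean() > 0.5  # far bins mostly negative


def test_correlogram_needs_min_sample():
    rng = np.random.default_rng(1)
    gm = panmictic_matrix(rng, n=30, L=50)
    with pytest.raises(ValueError):
        spatial.spatial_autocorrelogram(gm.subset(individuals=gm.individuals[:5]),
                                        rng.uniform(0, 1, (5, 2)))


# ----------------------------------------------------------------- MEM

def test_mem_orthogonality_and_trace():
    rng = np.random.default_rng(2)
    coords = rng.uniform(0, 10, (25, 2))
    basis = spatial.mem_eigenvectors(coords)
    G = basis.vectors.T @ basis.vectors
    np.testing.assert_allclose(G, np.eye(G.shape[0]), atol=1e-8)
    # eigenvalue sum equals trace of the Gower-centred matrix
    D = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    t = basis.truncation
    Dstar = np.where(D <= t, D, 4 * t)
    np.fill_diagonal(Dstar, 0.0)
    A = -0.5 * Dstar**2
    H = np.eye(25) - np.ones((25, 25)) / 25
    assert basis.values.sum() == pytest.approx(np.trace(H @ A @ H), rel=1e-8)


def test_mem_first_positive_monotone_on_line():
    coords = np.column_stack([np.arange(4.0), np.zeros(4)])
    basis = spatial.mem_eigenvectors(coords)
    v = basis.positive_vectors()[:, 0]
    assert (np.diff(v) > 0).all() or (np.diff(v) < 0).all()


def test_mem_duplicate_points_error():
    coords = np.array([[0.0, 0.0], [0.0, 0.0], [1, 0], [2, 0]])
    with pytest.raises(ValueError, match="jitter"):
        spatial.mem_eigenvectors(coords)


def test_mem_large_truncation_matches_pcoa():
    # with truncation beyond the data span no distance is modified, so the MEM
    # eigensystem is classical PCoA of the raw distances
    rng = np.random.default_rng(3)
    coords = rng.uniform(0, 5, (12, 2))
    D = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    basis = spatial.mem_from_distances(D, truncation=1e6)
    A = -0.5 * D**2
    H = np.eye(12) - np.ones((12, 12)) / 12
    vals = np.sort(np.linalg.eigvalsh(H @ A @ H))[::-1]
    np.testing.assert_allclose(basis.values, vals[: len(basis.values)], atol=1e-6)


# ----------------------------------------------------------- partition

def test_partition_deterministic(bundle):
    gm, sf = bundle["gm"], bundle["sf"]
    p1 = spatial.memgene_partition(gm, sf.coords(), n_perm=99, seed=3)
    p2 = spatial.memgene_partition(gm, sf.coords(), n_perm=99, seed=3)
    assert p1.r2adj_ibd == p2.r2adj_ibd
    assert p1.ibd_selected == p2.ibd_selected


def test_partition_ibd_signal_magnitude(bundle):
    gm, sf = bundle["gm"], bundle["sf"]
    part = spatial.memgene_partition(gm, sf.coords(), n_perm=199, seed=4)
    assert part.p_global < 0.05
    assert 0.0 < part.r2adj_ibd < 0.15  # small share of total variance


def test_partition_combined_dominates(bundle):
    gm, sf, raster = bundle["gm"], bundle["sf"], bundle["raster"]
    model = enumerate_candidate_models()[-1]
    rd = resistance_distances(raster, model, sf.coords())
    part = spatial.memgene_partition(gm, sf.coords(), resistance_dists=rd,
                                     n_perm=99, seed=5)
    assert part.r2adj_combined >= max(part.r2adj_ibd, part.r2adj_ibr) - 1e-9


def test_partition_pure_noise_returns_empty():
    rng = np.random.default_rng(6)
    gm = panmictic_matrix(rng, n=25, L=150)
    coords = rng.uniform(0, 10, (25, 2))
    # fixed seed chosen only for determinism; with no spatial signal the
    # global gate almost always returns the empty partition
    hits = 0
    for k in range(6):
        part = spatial.memgene_partition(gm, coords, n_perm=99, seed=100 + k)
        hits += part.p_global < 0.05
    assert hits <= 1


# ---------------------------------------------------------- optimizer

def test_optimize_single_candidate(bundle):
    gm, sf, raster = bundle["gm"], bundle["sf"], bundle["raster"]
    model = enumerate_candidate_models()[10]
    best, ranking, corr = spatial.optimize_resistance(
        gm, sf.coords(), raster, [model], n_perm=49, seed=0)
    assert best is model
    assert len(ranking) == 1
    assert -1 <= corr <= 1


def test_optimize_order_invariant(bundle):
    gm, sf, raster = bundle["gm"], bundle["sf"], bundle["raster"]
    cands = enumerate_candidate_models()[:6]
    best1, rank1, _ = spatial.optimize_resistance(
        gm, sf.coords(), raster, cands, n_perm=49, seed=1)
    best2, rank2, _ = spatial.optimize_resistance(
        gm, sf.coords(), raster, cands[::-1], n_perm=49, seed=1)
    assert (best1.urban, best1.managed_vegetation) == (best2.urban, best2.managed_vegetation)
    assert rank1[["urban", "managed", "r2adj_ibr"]].equals(
        rank2[["urban", "managed", "r2adj_ibr"]])
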