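import numpy as np
import pandas as pd
import pytest

from landgen.datatypes import GenotypeMatrix, PairwiseMatrix
from landgen import popgen

from conftest import panmictic_matrix


# --------------------------------------------------- W&C theta basics

def test_theta_one_for_fixed_difference():
    G = np.array([[0]] * 10 + [[2]] * 10)
    pops = np.array(["a"] * 10 + ["b"] * 10)
    assert popgen.multilocus_theta(G, pops) == pytest.approx(1.0)


def test_theta_near_zero_without_differentiation():
    rng = np.random.default_rng(0)
    gm = panmictic_matrix(rng, n=40, L=1000)
    pops = np.array(["a"] * 20 + ["b"] * 20)
    assert abs(popgen.multilocus_theta(gm.G, pops)) < 0.005


def test_all_monomorphic_is_error():
    G = np.zeros((8, 3), dtype=int)
    pops = np.array(["a"] * 4 + ["b"] * 4)
    with pytest.raises(ValueError, match="monomorphic"):
        popgen.multilocus_theta(G, pops)


def test_pairwise_fst_bootstrap_ci_contains_estimate(bundle):
    res = popgen.pairwise_fst_wc(bundle["gm"], bundle["sf"].pops,
                                 n_boot=199, seed=1)
    for pair in res.pop_pairs:
        lo, hi = res.ci[pair]
        assert lo <= res.theta[pair] <= hi
        assert -1 < res.theta[pair] <= 1


# -------------------------------------------------------------- AMOVA

def test_amova_components_sum_to_100(bundle):
    res = popgen.amova(bundle["gm"], bundle["sf"].pops, n_perm=49, seed=0)
    assert sum(res.percent.values()) == pytest.approx(100.0)


def test_amova_fixture_fst_matches_construction(bundle):
    res = popgen.amova(bundle["gm"], bundle["sf"].pops, n_perm=99, seed=0)
    assert 0.01 <= res.fst <= 0.04
    assert res.p_fst <= 0.05


def test_amova_single_pop_is_error(bundle):
    with pytest.raises(ValueError):
        popgen.amova(bundle["gm"], np.array(["x"] * bundle["gm"].n))


# ---------------------------------------------------- diversity table

def test_diversity_hand_example():
    G = np.array([[0], [1], [2]])
    gm = GenotypeMatrix(["a", "b", "c"], ["l1"], G)
    t = popgen.diversity_table(gm, np.array(["p", "p", "p"]), per_locus_sites=90)
    row = t[t["pop"] == "p"].iloc[0]
    assert row["Hobs_poly"] == pytest.approx(1 / 3)
    assert row["pi_poly"] == pytest.approx((6 / 5) * 0.5)  # 2n/(2n-1) * 2pq
    assert row["P_poly"] == pytest.approx(0.5)


def test_diversity_fixed_matrix():
    G = np.column_stack([np.zeros(4, dtype=int), np.array([0, 1, 2, 1])])
    gm = GenotypeMatrix(list("abcd"), ["l1", "l2"], G)
    t = popgen.diversity_table(gm, np.array(["p"] * 4))
    row = t[t["pop"] == "p"].iloc[0]
    # the fixed locus contributes zero H and pi, and P = 1
    assert row["Hobs_poly"] == pytest.approx(0.25)
    assert row["pi_all"] <= row["pi_poly"]


def test_diversity_polymorphic_ge_allsites(bundle):
    t = popgen.diversity_table(bundle["gm"], bundle["sf"].pops)
    assert (t["pi_poly"] >= t["pi_all"]).all()
    assert (t["Hobs_poly"] >= t["Hobs_all"]).all()
    assert t["Private"].ge(0).all()
    assert t[t["pop"] == "overall"]["Private"].iloc[0] == 0


# ------------------------------------------------ relatedness and kin

def test_qg_self_relatedness_near_one(bundle):
    gm = bundle["gm"]
    rel = popgen.qg_relatedness(gm)
    truth = bundle["truth"]
    inbred_ids = set(truth[truth["kind"] == "inbred"]["id_a"])
    diag = [rel.values[i, i] for i, lab in enumerate(rel.labels)
            if lab not in inbred_ids]
    assert np.allclose(diag, 1.0, atol=0.1)


def test_qg_unrelated_mean_near_zero():
    rng = np.random.default_rng(3)
    gm = panmictic_matrix(rng, n=30, L=1500)
    rel = popgen.qg_relatedness(gm)
    off = rel.values[np.triu_indices(gm.n, k=1)]
    assert abs(off.mean()) < 0.02


def test_qg_spiked_sibs_recovered(full_bundle):
    rel = popgen.qg_relatedness(full_bundle["gm"])
    truth = full_bundle["truth"]
    for _, row in truth[truth["kind"] == "kin"].iterrows():
        assert 0.35 <= rel.pair(row["id_a"], row["id_b"]) <= 0.65


def test_kin_filter_identity_and_single_pair():
    labels = ["a", "b", "c"]
    R = np.zeros((3, 3))
    rel = PairwiseMatrix(labels=labels, values=R, kind="r")
    assert popgen.kin_filter(rel) == labels

    R2 = R.copy()
    R2[0, 1] = R2[1, 0] = 0.4
    rel2 = PairwiseMatrix(labels=labels, values=R2, kind="r")
    kept = popgen.kin_filter(rel2)
    assert len(kept) == 2 and "c" in kept


def test_kin_filter_removes_eleven_of_fortysix(bundle):
    rel = popgen.qg_relatedness(bundle["gm"])
    kept = popgen.kin_filter(rel)
    assert len(kept) == 35
    sub = rel.to_frame().loc[kept, kept].to_numpy()
    np.fill_diagonal(sub, 0.0)
    assert (sub <= 0.25).all()


# ----------------------------------------------------------- inbreeding

def test_ml_inbreeding_null_recovery():
    rng = np.random.default_rng(4)
    gm = panmictic_matrix(rng, n=40, L=3849)
    F = popgen.ml_inbreeding(gm)
    assert F.mean() <= 0.02


def test_ml_inbreeding_all_heterozygous():
    G = np.ones((4, 50), dtype=int)
    G[0, :25] = 0  # keep loci polymorphic for the others
    gm = GenotypeMatrix(list("abcd"), [f"l{j}" for j in range(50)], G)
    F = popgen.ml_inbreeding(gm)
    assert F["b"] == pytest.approx(0.0, abs=1e-5)


def test_ml_inbreeding_spiked(full_bundle):
    truth = full_bundle["truth"]
    F = popgen.ml_inbreeding(full_bundle["gm"])
    for _, row in truth[truth["kind"] == "inbred"].iterrows():
        assert 0.10 <= F[row["id_a"]] <= 0.22


def test_realized_inbreeding_basics():
    assert popgen.realized_inbreeding_from_H(0.5, 0.5) == 0.0
    with pytest.warns(UserWarning):
        assert popgen.realized_inbreeding_from_H(0.6, 0.5) < 0


# ------------------------------------------------------------------ PCA

def test_pca_fraction_properties(bundle):
    scores, frac = popgen.pca_genotypes(bundle["gm"])
    assert frac.sum() <= 1 + 1e-9
    assert (np.diff(frac) <= 1e-12).all()
    # weak structure: leading axis explains little variance
    assert frac[0] < 0.10


def test_pca_strong_structure_separates_pops():
    rng = np.random.default_rng(5)
    L = 500
    pa = rng.uniform(0.1, 0.4, L)
    pb = np.clip(pa + 0.45, 0, 0.95)
    G = np.vstack([rng.binomial(2, pa, (15, L)), rng.binomial(2, pb, (15, L))])
    gm = GenotypeMatrix([f"i{k}" for k in range(30)],
                        [f"l{j}" for j in range(L)], G.astype(np.int8))
    scores, _ = popgen.pca_genotypes(gm)
    a, b = scores[:15, 0], scores[15:, 0]
    assert a.max() < b.min() or b.max() < a.min()  # no overlap on PC1


def test_pca_order_invariance(bundle):
    gm = bundle["gm"]
    perm = np.random.default_rng(6).permutation(gm.n)
    gm2 = GenotypeMatrix([gm.individuals[i] for i in perm], list(gm.loci),
                         gm.G[perm])
    s1, f1 = popgen.pca_genotypes(gm)
    s2, f2 = popgen.pca_genotypes(gm2)
    np.testing.assert_allclose(f1[:5], f2[:5], atol=1e-8)
    inv = np.argsort(perm)
    for k in range(3):
        a, b = s1[:, k], s2[inv, k]
        assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-6


def test_pca_constant_matrix_is_error():
    G = np.ones((4, 5), dtype=int)
    gm = GenotypeMatrix(list("abcd"), [f"l{j}" for j in range(5)], G)
    with pytest.raises(ValueError):
        popgen.pca_genotypes(gm)


# ------------------------------------------------------ subsampling

def test_subsample_precision_shrinks_with_loci(bundle):
    gm, pops = bundle["gm"], bundle["sf"].pops
    tab = popgen.subsample_precision(gm, pops, [50, 200, 800], n_reps=20, seed=0)
    for stat in ("hobs", "pi", "fst"):
        sds = tab[tab["statistic"] == stat].sort_values("n_loci")["sd"].to_numpy()
        assert sds[0] > sds[-1]


def test_subsample_full_set_has_zero_sd(bundle):
    gm, pops = bundle["gm"], bundle["sf"].pops
    tab = popgen.subsample_precision(gm, pops, [gm.L], n_reps=5, seed=0)
    assert (tab["sd"].fillna(0.0) == 0.0).all()


def test_subsample_tiny_pop_remains_finite(bundle):
    gm, sf = bundle["gm"], bundle["sf"]
    admiralty = [i for i, p in zip(sf.ids, sf.pops) if p == "admiralty"]
    keep = admiralty + [i for i, p in zip(sf.ids, sf.pops) if p == "central"][:5]
    sub = gm.subset(individuals=keep)
    pops = np.array(["admiralty"] * 3 + ["central"] * 5)
    tab = popgen.subsample_precision(sub, pops, [500], n_reps=5, seed=1)
    assert np.isfinite(tab["mean"]).all()


# ------------------------------------------------- property tests

from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    G=hnp.arrays(np.int8, shape=st.tuples(st.just(8), st.integers(1, 6)),
                 elements=st.integers(0, 2)),
    split=st.integers(2, 6),
)
def test_theta_oracle_property(G, split):
    """W&C components equal the allele-level ANOVA route on any instance."""
    from test_acceptance import wc_oracle_components
    pops = np.array(["a"] * split + ["b"] * (8 - split))
    a1, b1, c1 = popgen.wc_fst_components(G, pops)
    a2, b2, c2 = wc_oracle_components(G.tolist(), pops.tolist())
    assert np.abs(a1 - a2).max() < 1e-12
    assert np.abs(np.nan_to_num(b1 - b2)).max() < 1e-12
    assert np.abs(c1 - c2).max() < 1e-12


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    R=hnp.arrays(np.float64, shape=(7, 7), elements=st.floats(0, 0.6)),
    thr=st.floats(0.1, 0.5),
)
def test_kin_filter_leaves_no_residual_pairs(R, thr):
    R = 0.5 * (R + R.T)
    rel = PairwiseMatrix(labels=[f"i{k}" for k in range(7)], values=R, kind="r")
    kept = popgen.kin_filter(rel, threshold=thr)
    assert kept  # never removes everyone: a single individual has no pairs
    idx = [rel.labels.index(k) for k in kept]
    sub = R[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, 0.0)
    assert (sub <= thr).all()
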