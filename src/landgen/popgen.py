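"""Diversity, differentiation, relatedness and inbreeding statistics.

Implements Weir & Cockerham's (1984) theta with locus bootstraps, a
dosage-ANOVA AMOVA with permutation tests, Stacks-style diversity tables,
Queller & Goodnight (1989) relatedness with greedy kin filtering, a
per-individual maximum-likelihood inbreeding estimator, genotype PCA, and the
locus-subsampling precision study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import GenotypeMatrix, PairwiseMatrix

__all__ = [
    "wc_fst_components",
    "pairwise_fst_wc",
    "amova",
    "diversity_table",
    "qg_relatedness",
    "kin_filter",
    "ml_inbreeding",
    "realized_inbreeding_from_H",
    "pca_genotypes",
    "subsample_precision",
    "FstResult",
    "AmovaResult",
]


def _pop_onehot(pops: np.ndarray) -> tuple[np.ndarray, list]:
    labels = list(pd.unique(np.asarray(pops)))
    M = np.stack([np.asarray(pops) == lab for lab in labels]).astype(float)
    return M, labels  # (r, n)


# ------------------------------------------------------- Weir & Cockerham

def wc_fst_components(G: np.ndarray, pops: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir & Cockerham (1984) variance components (a, b, c).

    a: among populations; b: among individuals within populations; c: within
    individuals. Loci monomorphic across all populations contribute zeros.
    """
    G = np.asarray(G, dtype=float)
    M, _ = _pop_onehot(pops)
    r = M.shape[0]
    if r < 2:
        raise ValueError("need at least two populations")
    n_i = M.sum(axis=1)  # (r,)
    if (n_i < 2).any():
        raise ValueError("every population needs n >= 2")
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)

    p_il = (M @ G) / (2 * n_i[:, None])          # (r, L) alt freq per pop
    h_il = (M @ (G == 1)) / n_i[:, None]          # observed het freq per pop
    pbar = (n_i[:, None] * p_il).sum(axis=0) / (r * nbar)
    s2 = (n_i[:, None] * (p_il - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i[:, None] * h_il).sum(axis=0) / (r * nbar)

    inner = pbar * (1 - pbar) - s2 * (r - 1) / r
    a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (inner - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2
    mono = (pbar == 0) | (pbar == 1)
    a[mono] = b[mono] = c[mono] = 0.0
    return a, b, c


def multilocus_theta(G: np.ndarray, pops: np.ndarray) -> float:
    a, b, c = wc_fst_components(G, pops)
    denom = (a + b + c).sum()
    if denom == 0:
        raise ValueError("all loci monomorphic: theta undefined")
    return float(a.sum() / denom)


@dataclass
class FstResult:
    pop_pairs: list[tuple[str, str]]
    theta: dict[tuple[str, str], float]
    ci: dict[tuple[str, str], tuple[float, float]]
    components: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        repr=False, default_factory=dict
    )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"pop1": p1, "pop2": p2, "theta": self.theta[(p1, p2)],
             "ci_lo": self.ci[(p1, p2)][0], "ci_hi": self.ci[(p1, p2)][1]}
            for p1, p2 in self.pop_pairs
        ]
        return pd.DataFrame(rows)


def pairwise_fst_wc(
    gm: GenotypeMatrix,
    pops: np.ndarray,
    n_boot: int = 9999,
    seed: int | None = None,
) -> FstResult:
    """Pairwise W&C theta with percentile bootstrap CIs over loci."""
    rng = np.random.default_rng(seed)
    pops = np.asarray(pops)
    labels = list(pd.unique(pops))
    result = FstResult(pop_pairs=[], theta={}, ci={})
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            pair = (labels[i], labels[j])
            mask = (pops == labels[i]) | (pops == labels[j])
            a, b, c = wc_fst_components(gm.G[mask], pops[mask])
            tot = a + b + c
            if tot.sum() == 0:
                raise ValueError(f"all loci monomorphic for pair {pair}")
            theta = float(a.sum() / tot.sum())
            L = len(a)
            if n_boot > 0:
                idx = rng.integers(0, L, size=(n_boot, L))
                boot_num = a[idx].sum(axis=1)
                boot_den = tot[idx].sum(axis=1)
                ok = boot_den != 0
                boots = boot_num[ok] / boot_den[ok]
                lo, hi = np.percentile(boots, [2.5, 97.5])
            else:
                lo = hi = theta
            result.pop_pairs.append(pair)
            result.theta[pair] = theta
            result.ci[pair] = (float(min(lo, theta)), float(max(hi, theta)))
            result.components[pair] = (a, b, c)
    return result


# ------------------------------------------------------------------ AMOVA

def _amova_ms(G: np.ndarray, pops: np.ndarray):
    """Per-locus mean squares of the nested allele-dosage ANOVA."""
    G = np.asarray(G, dtype=float)
    M, _ = _pop_onehot(pops)
    r, n = M.shape
    n_i = M.sum(axis=1)
    p_pop = (M @ G) / (2 * n_i[:, None])        # (r, L)
    pbar = G.mean(axis=0) / 2                   # (L,)
    # SS within individuals: each heterozygote contributes 0.5
    SSG = 0.5 * (G == 1).sum(axis=0)
    # SS among individuals within pops (2 allele copies per individual)
    dev = G / 2 - M.T @ p_pop                   # (n, L) individual minus pop mean
    SSI = 2 * (dev**2).sum(axis=0)
    SSP = 2 * (n_i[:, None] * (p_pop - pbar) ** 2).sum(axis=0)
    MSP = SSP / (r - 1)
    MSI = SSI / (n - r)
    MSG = SSG / n
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    return MSP, MSI, MSG, nc


def _amova_components(G, pops):
    MSP, MSI, MSG, nc = _amova_ms(G, pops)
    sig_c = MSG.sum()
    sig_b = ((MSI - MSG) / 2).sum()
    sig_a = ((MSP - MSI) / (2 * nc)).sum()
    return sig_a, sig_b, sig_c


@dataclass
class AmovaResult:
    sigma_among_pops: float
    sigma_among_ind: float
    sigma_within_ind: float
    fst: float
    fis: float
    p_fst: float
    p_fis: float

    @property
    def percent(self) -> dict[str, float]:
        tot = self.sigma_among_pops + self.sigma_among_ind + self.sigma_within_ind
        return {
            "among_pops": 100 * self.sigma_among_pops / tot,
            "among_individuals": 100 * self.sigma_among_ind / tot,
            "within_individuals": 100 * self.sigma_within_ind / tot,
        }


def _sample_het_counts(alt_counts: np.ndarray, n_ind: int, rng) -> np.ndarray:
    """Sample per-locus heterozygote counts under random pairing of alleles.

    For a locus with A alt alleles among 2n slots, drawing the alt slots
    uniformly without replacement is exactly the random-union-of-gametes null;
    the het count h has parity A and pmf proportional to
    C(n,h) C(n-h,(A-h)/2) 2^h.
    """
    A = np.asarray(alt_counts, dtype=int)
    L = len(A)
    h = np.arange(n_ind + 1)
    Hh, Aa = np.meshgrid(h, A)  # (L, n+1)
    rem = Aa - Hh
    valid = (rem >= 0) & (rem % 2 == 0) & (rem // 2 <= n_ind - Hh)
    half = np.where(valid, rem // 2, 0)
    with np.errstate(invalid="ignore"):
        logpmf = (
            gammaln(n_ind + 1)
            - gammaln(Hh + 1)
            - gammaln(half + 1)
            - gammaln(n_ind - Hh - half + 1)
            + Hh * np.log(2.0)
        )
    logpmf[~valid] = -np.inf
    logpmf -= logpmf.max(axis=1, keepdims=True)
    pmf = np.exp(logpmf)
    pmf /= pmf.sum(axis=1, keepdims=True)
    u = rng.random(L)
    return (pmf.cumsum(axis=1) < u[:, None]).sum(axis=1)


def amova(
    gm: GenotypeMatrix,
    pops: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    n_perm_fis: int | None = None,
) -> AmovaResult:
    """Nested allele-dosage AMOVA with permutation p-values.

    F_ST is tested by permuting individuals among populations; F_IS by
    re-pairing alleles within populations (random union of gametes).
    n_perm_fis defaults to n_perm; pass 0 to skip the F_IS test (p_fis NaN).
    """
    pops = np.asarray(pops)
    if len(pd.unique(pops)) < 2:
        raise ValueError("AMOVA needs at least two populations")
    rng = np.random.default_rng(seed)
    G = gm.G
    sa, sb, sc = _amova_components(G, pops)
    tot = sa + sb + sc
    fst = sa / tot
    fis = sb / (sb + sc)

    # F_ST: permute individuals among pops
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pops))
        pa, pb, pc = _amova_components(G, pops[perm])
        if pa / (pa + pb + pc) >= fst:
            exceed += 1
    p_fst = (1 + exceed) / (n_perm + 1)

    # F_IS: re-pair alleles within each pop per locus
    if n_perm_fis is None:
        n_perm_fis = n_perm
    M, labels = _pop_onehot(pops)
    exceed = 0
    for _ in range(n_perm_fis):
        Gp = np.empty_like(G)
        for k, lab in enumerate(labels):
            rows = np.flatnonzero(pops == lab)
            sub = G[rows]
            A = sub.sum(axis=0)
            hets = _sample_het_counts(A, len(rows), rng)
            # rebuild dosage columns with given alt totals and het counts
            n_i = len(rows)
            homalt = (A - hets) // 2
            new = np.zeros((n_i, sub.shape[1]), dtype=G.dtype)
            # random assignment of which individuals are het / hom-alt
            order = np.argsort(rng.random((n_i, sub.shape[1])), axis=0)
            rank = np.argsort(order, axis=0)
            new[rank < hets] = 1
            new[(rank >= hets) & (rank < hets + homalt)] = 2
            Gp[rows] = new
        pa2, pb2, pc2 = _amova_components(Gp, pops)
        if pb2 / (pb2 + pc2) >= fis:
            exceed += 1
    p_fis = (1 + exceed) / (n_perm_fis + 1) if n_perm_fis else float("nan")

    return AmovaResult(
        sigma_among_pops=float(sa), sigma_among_ind=float(sb),
        sigma_within_ind=float(sc), fst=float(fst), fis=float(fis),
        p_fst=float(p_fst), p_fis=float(p_fis),
    )


# ------------------------------------------------------- diversity table

def diversity_table(
    gm: GenotypeMatrix, pops: np.ndarray, per_locus_sites: int = 90
) -> pd.DataFrame:
    """Stacks-style diversity table, per population and overall.

    Polymorphic-only rows average over the variant loci of the matrix; the
    "fixed & polymorphic" rows divide the same locus sums by the total number
    of assayed sites (L x per_locus_sites), emulating per-RAD-locus windows of
    the given read length.
    """
    pops = np.asarray(pops)
    labels = list(pd.unique(pops)) + ["overall"]
    G = gm.G
    n, L = G.shape
    total_sites = L * per_locus_sites

    # presence of each allele per pop, for private-allele counts
    pop_list = list(pd.unique(pops))
    has_alt = np.stack([G[pops == lab].sum(axis=0) > 0 for lab in pop_list])
    has_ref = np.stack([(2 * (pops == lab).sum() - G[pops == lab].sum(axis=0)) > 0
                        for lab in pop_list])
    priv_alt = has_alt & (has_alt.sum(axis=0) == 1)
    priv_ref = has_ref & (has_ref.sum(axis=0) == 1)

    rows = []
    for lab in labels:
        sub = G if lab == "overall" else G[pops == lab]
        n_i = sub.shape[0]
        if n_i < 2:
            raise ValueError(f"population {lab!r} has n < 2: pi undefined")
        p = sub.mean(axis=0) / 2
        q = 1 - p
        hobs_l = (sub == 1).mean(axis=0)
        pi_l = (2 * n_i / (2 * n_i - 1)) * 2 * p * q
        P_l = np.maximum(p, q)
        if lab == "overall":
            private = 0
        else:
            k = pop_list.index(lab)
            private = int(priv_alt[k].sum() + priv_ref[k].sum())
        rows.append({
            "pop": lab, "N": n_i, "Private": private,
            "P_poly": float(P_l.mean()),
            "Hobs_poly": float(hobs_l.mean()),
            "pi_poly": float(pi_l.mean()),
            "P_all": float((P_l.sum() + (total_sites - L)) / total_sites),
            "Hobs_all": float(hobs_l.sum() / total_sites),
            "pi_all": float(pi_l.sum() / total_sites),
        })
    return pd.DataFrame(rows)


# ------------------------------------------------- relatedness & kin filter

def _qg_directional(gx, gy, p):
    """Queller-Goodnight numerator/denominator sums with x as proband."""
    q = 1 - p
    matches = gx * gy + (2 - gx) * (2 - gy)
    px_sum = gx * p + (2 - gx) * q
    num = 0.5 * matches - px_sum
    den = 1 + (gx != 1) - px_sum
    return num.sum(), den.sum()


def qg_relatedness(gm: GenotypeMatrix, warn_loci: int = 100) -> PairwiseMatrix:
    """Symmetrized Queller & Goodnight (1989) relatedness.

    Reference allele frequencies for each pair are computed from all
    individuals excluding the focal pair. The diagonal holds self-relatedness
    (frequencies excluding the focal individual once).
    """
    if gm.L < warn_loci:
        warnings.warn(f"only {gm.L} loci: relatedness estimates will be noisy")
    G = gm.G.astype(float)
    n = gm.n
    tot = G.sum(axis=0)  # 2n * p
    R = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                p = (tot - G[i]) / (2 * (n - 1))
            else:
                p = (tot - G[i] - G[j]) / (2 * (n - 2))
            ok = (p > 0) & (p < 1)
            gi, gj, pk = G[i, ok], G[j, ok], p[ok]
            n1, d1 = _qg_directional(gi, gj, pk)
            n2, d2 = _qg_directional(gj, gi, pk)
            R[i, j] = R[j, i] = 0.5 * (n1 / d1 + n2 / d2)
    return PairwiseMatrix(labels=list(gm.individuals), values=R, kind="qg_relatedness")


def kin_filter(rel: PairwiseMatrix, threshold: float = 0.25) -> list[str]:
    """Greedily drop individuals until no pair exceeds the threshold.

    At each step the individual participating in the most super-threshold
    pairs is removed (ties broken by lower ID), mirroring half-sib pruning.
    Returns the retained IDs in original order.
    """
    R = rel.values.copy()
    np.fill_diagonal(R, 0.0)
    labels = list(rel.labels)
    alive = np.ones(len(labels), dtype=bool)
    while True:
        over = (R > threshold) & alive[:, None] & alive[None, :]
        if not over.any():
            break
        degree = over.sum(axis=1)
        worst = degree.max()
        cands = [i for i in np.flatnonzero(degree == worst)]
        victim = min(cands, key=lambda i: labels[i])
        alive[victim] = False
    return [lab for lab, keep in zip(labels, alive) if keep]


# --------------------------------------------------------------- inbreeding

def ml_inbreeding(gm: GenotypeMatrix, tol: float = 1e-6) -> pd.Series:
    """Per-individual ML inbreeding coefficient F-hat on [0, 1].

    Mixture likelihood per locus: with probability F the two gene copies are
    identical by descent (genotype probability p for alt-hom, q for ref-hom,
    0 for het), else Hardy-Weinberg. Frequencies exclude the focal individual;
    loci fixed after exclusion are skipped. Golden-section maximization.
    """
    G = gm.G.astype(float)
    n = gm.n
    tot = G.sum(axis=0)
    out = {}
    invphi = (np.sqrt(5) - 1) / 2
    for i in range(n):
        p = (tot - G[i]) / (2 * (n - 1))
        ok = (p > 0) & (p < 1)
        g, pk = G[i, ok], p[ok]
        qk = 1 - pk
        p_hwe = np.where(g == 0, qk**2, np.where(g == 1, 2 * pk * qk, pk**2))
        p_ibd = np.where(g == 0, qk, np.where(g == 1, 0.0, pk))

        def nll(F):
            return -np.log(F * p_ibd + (1 - F) * p_hwe + 1e-300).sum()

        a, b = 0.0, 1.0
        c, d = b - invphi * (b - a), a + invphi * (b - a)
        fc, fd = nll(c), nll(d)
        while b - a > tol:
            if fc < fd:
                b, d, fd = d, c, fc
                c = b - invphi * (b - a)
                fc = nll(c)
            else:
                a, c, fc = c, d, fd
                d = a + invphi * (b - a)
                fd = nll(d)
        F = 0.5 * (a + b)
        # snap to the boundary when the optimum sits against it
        if nll(0.0) <= nll(F):
            F = 0.0
        out[gm.individuals[i]] = F
    return pd.Series(out, name="F_hat")


def realized_inbreeding_from_H(H: float, H0: float) -> float:
    """Realized inbreeding from the heterozygosity ratio, F = 1 - H/H0.

    Reported to two decimals, matching how mean observed heterozygosities are
    tabulated. H > H0 yields a negative F with a warning rather than an error.
    """
    if H0 <= 0:
        raise ValueError("H0 must be positive")
    F = 1 - H / H0
    if F < 0:
        warnings.warn("H exceeds H0: negative realized inbreeding")
    return round(F, 2)


# --------------------------------------------------------------------- PCA

def pca_genotypes(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Genotype PCA on column-centred dosages (no scaling).

    Returns (scores, explained-variance fractions); scores[:, k] is PC k+1.
    """
    X = gm.G.astype(float)
    X = X - X.mean(axis=0)
    if not X.any():
        raise ValueError("constant genotype matrix: PCA undefined")
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    frac = S**2 / (S**2).sum()
    return U * S, frac


# ------------------------------------------------- subsampling precision

def subsample_precision(
    gm: GenotypeMatrix,
    pops: np.ndarray,
    loci_grid: list[int],
    n_reps: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Precision of H_obs, pi, multi-pop theta and mean F-hat vs locus count.

    For each locus count, draws n_reps random locus subsets (without
    replacement) and reports mean, SD and 2.5/97.5 percentiles per statistic.
    """
    rng = np.random.default_rng(seed)
    pops = np.asarray(pops)
    rows = []
    for n_loci in loci_grid:
        if n_loci > gm.L:
            raise ValueError(f"requested {n_loci} loci but matrix has {gm.L}")
        stats = {"hobs": [], "pi": [], "fst": [], "mean_F": []}
        for _ in range(n_reps):
            idx = rng.choice(gm.L, size=n_loci, replace=False)
            sub = gm.subset(loci_idx=np.sort(idx))
            p = sub.alt_freqs()
            q = 1 - p
            stats["hobs"].append(float((sub.G == 1).mean()))
            stats["pi"].append(float(((2 * sub.n / (2 * sub.n - 1)) * 2 * p * q).mean()))
            try:
                stats["fst"].append(multilocus_theta(sub.G, pops))
            except ValueError:
                stats["fst"].append(np.nan)
            stats["mean_F"].append(float(ml_inbreeding(sub).mean()))
        for stat, vals in stats.items():
            v = np.asarray(vals, dtype=float)
            rows.append({
                "n_loci": n_loci, "statistic": stat,
                "mean": np.nanmean(v), "sd": np.nanstd(v, ddof=1),
                "q025": np.nanpercentile(v, 2.5),
                "q975": np.nanpercentile(v, 97.5),
            })
    return pd.DataFrame(rows)
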