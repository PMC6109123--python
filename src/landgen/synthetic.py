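"""Synthetic fixture generator for the landscape-genomic analyses.

Emulates the study system: ~46 individuals in three subpopulations (one small
isolated northern patch, one large central patch, one large southern patch
connected by stepping stones), ~3,849 unlinked biallelic SNPs with weak
structure (overall F_ST ~ 0.02), spatial autocorrelation decaying within
~1 km, a few planted kin pairs, and one strongly inbred individual.

Individual allele frequencies follow a clamped Gaussian random field over the
sampling coordinates with exponential covariance sigma^2 exp(-d/kappa); sigma
is calibrated numerically so the realized multi-locus Weir-Cockerham theta
across the three patches matches the requested target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    FOREST,
    MANAGED_VEGETATION,
    URBAN,
    WATER,
    GenotypeMatrix,
    LandscapeRaster,
    SampleFrame,
)
from . import io as lgio
from .popgen import multilocus_theta

__all__ = ["SyntheticSpec", "make_landscape", "patch_cells", "sample_coords",
           "make_ibd_genotypes", "spike_kin_and_inbred", "generate_bundle",
           "write_bundle"]

# patch geometry in (row, col) slices of the default 40x24 grid (0.5 km cells);
# row 0 is the northern edge
PATCHES = {
    "admiralty": (slice(2, 6), slice(10, 14)),     # small isolated, north
    "central": (slice(10, 23), slice(4, 20)),      # large, middle
    "southern": (slice(30, 38), slice(4, 20)),     # large, south
}


@dataclass
class SyntheticSpec:
    """Study-condition defaults for the fixture generator."""

    seed: int
    n_per_patch: dict = field(default_factory=lambda: {
        "admiralty": 3, "central": 27, "southern": 16})
    L: int = 3849
    fst: float = 0.023
    kappa_km: float = 0.7         # autocorrelation decay length
    kin_per_patch: dict = field(default_factory=lambda: {
        "southern": 5, "admiralty": 1, "central": 5})
    inbred: dict = field(default_factory=lambda: {"admiralty": [0.16]})
    nrows: int = 40
    ncols: int = 24
    cellsize_km: float = 0.5
    stepping_stones: int = 7      # managed-vegetation rows bridging the south gap

    def __post_init__(self) -> None:
        if not 0 <= self.fst <= 0.5:
            raise ValueError("target F_ST must lie in [0, 0.5]")
        if self.kappa_km <= 0:
            raise ValueError("kappa must be positive")


def make_landscape(spec: SyntheticSpec) -> LandscapeRaster:
    """Two large forest patches on a north-south axis plus one small isolated
    patch >= 2 km from the nearest large patch; managed-vegetation stepping
    stones bridge the southern gap; water strips on the east/west edges."""
    grid = np.full((spec.nrows, spec.ncols), URBAN, dtype=int)
    grid[:, 0] = WATER
    grid[:, -1] = WATER
    seen = np.zeros_like(grid, dtype=bool)
    for rs, cs in PATCHES.values():
        if seen[rs, cs].any():
            raise ValueError("patch geometry overlaps")
        grid[rs, cs] = FOREST
        seen[rs, cs] = True
    # stepping stones between central (ends row 22) and southern (starts row 30)
    stone_rows = np.linspace(23, 29, spec.stepping_stones).round().astype(int) \
        if spec.stepping_stones > 0 else []
    for r in stone_rows:
        grid[r, 9:15] = MANAGED_VEGETATION
    return LandscapeRaster(classes=grid, cellsize_km=spec.cellsize_km)


def patch_cells(raster: LandscapeRaster, patch: str) -> np.ndarray:
    """(row, col) cells of a named forest patch."""
    rs, cs = PATCHES[patch]
    rows, cols = np.meshgrid(
        np.arange(rs.start, rs.stop), np.arange(cs.start, cs.stop), indexing="ij"
    )
    return np.column_stack([rows.ravel(), cols.ravel()])


def _cell_center(raster: LandscapeRaster, row: np.ndarray, col: np.ndarray):
    x = raster.xllcorner + (col + 0.5) * raster.cellsize_km
    y = raster.yllcorner + (raster.nrows - row - 0.5) * raster.cellsize_km
    return x, y


def sample_coords(spec: SyntheticSpec, raster: LandscapeRaster,
                  rng: np.random.Generator) -> SampleFrame:
    """Place individuals on distinct forest cells of their patch (jittered)."""
    rows = []
    counter = 1
    for patch, n in spec.n_per_patch.items():
        cells = patch_cells(raster, patch)
        if n > len(cells):
            raise ValueError(f"patch {patch} too small for {n} individuals")
        pick = cells[rng.choice(len(cells), size=n, replace=False)]
        x, y = _cell_center(raster, pick[:, 0], pick[:, 1])
        jitter = rng.uniform(-0.2, 0.2, size=(n, 2)) * raster.cellsize_km
        for k in range(n):
            rows.append({
                "id": f"K{counter:04d}",
                "x_km": x[k] + jitter[k, 0],
                "y_km": y[k] + jitter[k, 1],
                "pop": patch,
            })
            counter += 1
    return SampleFrame(pd.DataFrame(rows))


def _draw_matrix(coords: np.ndarray, pops: np.ndarray | None, L: int,
                 sigma_patch: float, sigma_local: float, kappa: float,
                 rng: np.random.Generator, max_attempts: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Draw (G, p0, P) with two-scale clamped Gaussian frequency fields.

    P is the realized per-individual frequency surface (n, L) -- the "local"
    allele frequencies at each sampling location.

    Per locus: a patch-level shift ~ N(0, sigma_patch^2) shared by patch
    members (drives among-patch differentiation) plus a smooth short-range
    field with covariance sigma_local^2 exp(-d/kappa) (drives the first-km
    autocorrelation without inflating individual homozygosity). Loci
    monomorphic across the whole sample are redrawn up to max_attempts times,
    then dropped with a warning.
    """
    n = len(coords)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    K = np.exp(-d / kappa) + 1e-8 * np.eye(n)
    chol = np.linalg.cholesky(K)
    if pops is not None:
        pop_labels = pd.unique(np.asarray(pops))
        pop_idx = np.array([list(pop_labels).index(p) for p in np.asarray(pops)])
    else:
        pop_idx = np.zeros(n, dtype=int)
        pop_labels = np.array(["all"])

    def draw(nl):
        p0 = rng.uniform(0.05, 0.95, size=nl)
        u = sigma_patch * rng.standard_normal((len(pop_labels), nl))
        f = sigma_local * (chol @ rng.standard_normal((n, nl)))
        p = np.clip(p0[None, :] + u[pop_idx] + f, 0.01, 0.99)
        return rng.binomial(2, p).astype(np.int8), p0, p

    G, p0, P = draw(L)
    for _ in range(max_attempts):
        mono = (G.sum(axis=0) == 0) | (G.sum(axis=0) == 2 * n)
        if not mono.any():
            break
        Gf, p0f, Pf = draw(int(mono.sum()))
        G[:, mono], p0[mono], P[:, mono] = Gf, p0f, Pf
    mono = (G.sum(axis=0) == 0) | (G.sum(axis=0) == 2 * n)
    if mono.any():
        warnings.warn(f"dropping {mono.sum()} stubbornly monomorphic loci")
        G, p0, P = G[:, ~mono], p0[~mono], P[:, ~mono]
    return G, p0, P


def make_ibd_genotypes(
    coords: np.ndarray,
    L: int,
    kappa: float,
    fst_scale: float,
    seed: int,
    pops: np.ndarray | None = None,
    sigma_local: float = 0.05,
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Genotypes with isolation-by-distance structure over the coordinates.

    Returns (matrix, ancestral frequencies, per-individual local frequency
    surface). When fst_scale > 0, pops labels are required: the patch-level
    scale is calibrated by bisection so the realized multi-locus theta across
    pops matches fst_scale.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 3:
        raise ValueError("need at least 3 individuals")
    rng = np.random.default_rng(seed)
    sigma = 0.0
    if fst_scale > 0:
        if pops is None:
            raise ValueError("pops labels required to calibrate the F_ST target")
        cal_rng = np.random.default_rng(seed + 7_777)
        L_cal = 400

        def realized(s):
            G, _, _ = _draw_matrix(coords, pops, L_cal, s, sigma_local, kappa,
                                np.random.default_rng(cal_rng.integers(2**31)))
            return multilocus_theta(G, pops)

        lo, hi = 0.002, 0.8
        for _ in range(12):
            mid = 0.5 * (lo + hi)
            if realized(mid) < fst_scale:
                lo = mid
            else:
                hi = mid
        sigma = 0.5 * (lo + hi)
    G, p0, P = _draw_matrix(coords, pops, L, sigma, sigma_local, kappa, rng)
    ids = [f"K{i + 1:04d}" for i in range(len(coords))]
    loci = [f"snp{j + 1:05d}" for j in range(G.shape[1])]
    return GenotypeMatrix(ids, loci, G), p0, P


def spike_kin_and_inbred(
    gm: GenotypeMatrix,
    freqs: np.ndarray,
    kin_pairs: list[tuple[str, str]],
    inbred_F: dict[str, float],
    seed: int,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Plant kin pairs and inbred individuals; returns matrix + truth table.

    For each (keep, regen) pair the second member is regenerated locus-wise as
    an offspring of the first and a random parent drawn from the local
    frequencies (expected relatedness 0.5). Inbred individuals are regenerated
    under P(het) = (1-F) 2pq, P(alt hom) = (1-F)p^2 + Fp,
    P(ref hom) = (1-F)q^2 + Fq. `freqs` is either one (L,) frequency vector
    or a per-individual (n, L) surface (each target then uses its own row).
    """
    rng = np.random.default_rng(seed)
    G = gm.G.copy()
    freqs = np.asarray(freqs, dtype=float)

    def local(idx: int) -> np.ndarray:
        return freqs if freqs.ndim == 1 else freqs[idx]

    truth_rows = []
    for keep, regen in kin_pairs:
        a, b = gm.individuals.index(keep), gm.individuals.index(regen)
        from_mate = rng.binomial(1, G[a] / 2.0)
        from_random = rng.binomial(1, local(b))
        G[b] = (from_mate + from_random).astype(G.dtype)
        truth_rows.append({"kind": "kin", "id_a": keep, "id_b": regen,
                           "expected_r": 0.5, "F": np.nan})
    for ind, F in inbred_F.items():
        if not 0.0 <= F <= 1.0:
            raise ValueError(f"inbreeding coefficient out of [0,1]: {F}")
        i = gm.individuals.index(ind)
        p = local(i)
        q = 1 - p
        probs = np.stack([(1 - F) * q**2 + F * q,
                          (1 - F) * 2 * p * q,
                          (1 - F) * p**2 + F * p])
        u = rng.random(gm.L)
        G[i] = (u > probs[0]).astype(G.dtype) + (u > probs[0] + probs[1])
        truth_rows.append({"kind": "inbred", "id_a": ind, "id_b": "",
                           "expected_r": np.nan, "F": F})
    truth = pd.DataFrame(truth_rows,
                         columns=["kind", "id_a", "id_b", "expected_r", "F"])
    return GenotypeMatrix(list(gm.individuals), list(gm.loci), G), truth


def generate_bundle(spec: SyntheticSpec):
    """Full fixture: landscape, coordinates, spiked genotype matrix, truth."""
    rng = np.random.default_rng(spec.seed)
    raster = make_landscape(spec)
    sf = sample_coords(spec, raster, rng)
    gm, p0, local_freqs = make_ibd_genotypes(
        sf.coords(), spec.L, spec.kappa_km, spec.fst, spec.seed + 1,
        pops=sf.pops,
    )
    # realign IDs: genotype IDs follow coordinate order
    gm = GenotypeMatrix(sf.ids, gm.loci, gm.G)
    # spike kin and inbred individuals; the regenerated genotypes draw from
    # each target's own local frequency surface, so spiked individuals look
    # like residents rather than immigrants
    pair_rng = np.random.default_rng(spec.seed + 2)
    kin_pairs = []
    for patch, n_pairs in spec.kin_per_patch.items():
        members = [i for i, p in zip(sf.ids, sf.pops) if p == patch]
        pick = pair_rng.choice(len(members), size=2 * n_pairs, replace=False)
        kin_pairs.extend((members[pick[2 * k]], members[pick[2 * k + 1]])
                         for k in range(n_pairs))
    inbred = {}
    taken = {m for pr in kin_pairs for m in pr}
    for patch, fvals in spec.inbred.items():
        members = [i for i, p in zip(sf.ids, sf.pops) if p == patch]
        free = [m for m in members if m not in taken] or members
        for k, F in enumerate(fvals):
            inbred[free[k % len(free)]] = F
    gm, truth = spike_kin_and_inbred(gm, local_freqs, kin_pairs, inbred,
                                     spec.seed + 3)
    return gm, sf, raster, truth


def write_bundle(spec: SyntheticSpec, outdir: str | Path):
    """Write Genepop + VCF + coordinates CSV + ASCII grid + truth CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gm, sf, raster, truth = generate_bundle(spec)
    lgio.write_genepop(gm, sf.pops, outdir / "genotypes.genepop")
    lgio.write_vcf_lite(gm, outdir / "genotypes.vcf")
    lgio.write_coords_csv(sf, outdir / "coords.csv")
    lgio.write_ascii_grid(raster, outdir / "landcover.asc")
    truth.to_csv(outdir / "truth.csv", index=False)
    return gm, sf, raster, truth
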