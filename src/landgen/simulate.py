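"""Forward-in-time, spatially explicit, individual-based simulator.

Individuals occupy fixed home sites on the landscape (one occupant per site,
non-overlapping generations). Each generation: females choose a mate among
males within the maximum dispersal distance with probability proportional to
(1+d)^-beta, produce Poisson(fecundity) offspring with Mendelian inheritance,
offspring disperse to vacant sites under the same kernel (truncated at the
maximum distance; unplaced offspring die), and all adults die. No mutation:
loci are neutral and the horizon is ~100 generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import FOREST, GenotypeMatrix, LandscapeRaster, SampleFrame

__all__ = [
    "SimConfig",
    "SimState",
    "SimulationHalt",
    "home_sites_from_landscape",
    "init_population",
    "step_generation",
    "run_replicates",
    "sample_at_locations",
]


class SimulationHalt(RuntimeError):
    """Total extinction; carries the generation index."""

    def __init__(self, generation: int):
        super().__init__(f"population extinct at generation {generation}")
        self.generation = generation


@dataclass
class SimConfig:
    site_coords: np.ndarray               # (n_sites, 2) km
    site_patch: np.ndarray                # per-site patch label (str array)
    n_loci: int = 99
    n_generations: int = 100
    sample_every: int = 10
    n_replicates: int = 100
    max_dispersal_km: float = 1.0
    beta: float = 1.0                     # kernel decay exponent
    mating: str = "monogamy"              # or "random"
    fecundity: float = 4.0
    distance_mode: str = "euclidean"      # least_cost / effective_resistance
    seed: int = 0

    def __post_init__(self):
        self.site_coords = np.asarray(self.site_coords, dtype=float)
        self.site_patch = np.asarray(self.site_patch)
        if self.max_dispersal_km <= 0:
            raise ValueError("max dispersal must be positive")
        if min(self.n_loci, self.n_generations, self.sample_every,
               self.n_replicates) < 1:
            raise ValueError("counts must be >= 1")
        if self.mating not in ("monogamy", "random", "wright_fisher"):
            raise ValueError(f"unknown mating system {self.mating}")

    @property
    def n_sites(self) -> int:
        return len(self.site_coords)


@dataclass
class SimState:
    genotypes: np.ndarray     # (n_sites, L) int8; rows of vacant sites unused
    occupied: np.ndarray      # (n_sites,) bool
    sex: np.ndarray           # (n_sites,) 0 = female, 1 = male
    generation: int
    founder_freqs: np.ndarray = field(default=None, repr=False)
    # (mom_site, dad_site) of each placed offspring from the last step;
    # supports realized offspring-number variance (effective-size) audits
    parents: tuple | None = field(default=None, repr=False)


def home_sites_from_landscape(
    raster: LandscapeRaster, n_sites: int, rng: np.random.Generator,
    patches: dict[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Place home sites on forest cells, allocated to patches by area.

    `patches` maps labels to (k, 2) arrays of (row, col) cells; when omitted,
    every forest cell belongs to one patch 'forest'.
    """
    if patches is None:
        rows, cols = np.nonzero(raster.classes == FOREST)
        patches = {"forest": np.column_stack([rows, cols])}
    areas = {k: len(v) for k, v in patches.items()}
    total = sum(areas.values())
    coords, labels = [], []
    for name, cells in patches.items():
        k = max(1, round(n_sites * areas[name] / total))
        if k > 4 * len(cells):
            raise ValueError(f"requested density infeasible in patch {name}")
        pick = cells[rng.choice(len(cells), size=k, replace=k > len(cells))]
        x = raster.xllcorner + (pick[:, 1] + 0.5) * raster.cellsize_km
        y = raster.yllcorner + (raster.nrows - pick[:, 0] - 0.5) * raster.cellsize_km
        jit = rng.uniform(-0.3, 0.3, size=(k, 2)) * raster.cellsize_km
        coords.append(np.column_stack([x, y]) + jit)
        labels.extend([name] * k)
    return np.vstack(coords), np.array(labels)


def init_population(config: SimConfig, rng: np.random.Generator) -> SimState:
    """All sites occupied; founder genotypes Binomial(2, p_l) with per-locus
    founder frequencies ~ Uniform(0.05, 0.95)."""
    n = config.n_sites
    p = rng.uniform(0.05, 0.95, size=config.n_loci)
    G = rng.binomial(2, p, size=(n, config.n_loci)).astype(np.int8)
    sex = (rng.random(n) < 0.5).astype(np.int8)
    return SimState(genotypes=G, occupied=np.ones(n, dtype=bool), sex=sex,
                    generation=0, founder_freqs=p)


def _neighbor_lists(distances: np.ndarray, max_d: float, beta: float):
    """Per-site in-range site indices and kernel weights (1+d)^-beta."""
    neigh, weights = [], []
    for i in range(distances.shape[0]):
        d = distances[i]
        idx = np.flatnonzero(d <= max_d)
        neigh.append(idx)
        weights.append((1.0 + d[idx]) ** (-beta))
    return neigh, weights


def step_generation(
    state: SimState,
    config: SimConfig,
    distances: np.ndarray,
    rng: np.random.Generator,
    _cache: dict | None = None,
) -> SimState:
    """Advance one non-overlapping generation (mate, reproduce, disperse)."""
    if _cache is None or "neigh" not in _cache:
        neigh, w = _neighbor_lists(distances, config.max_dispersal_km, config.beta)
        if _cache is not None:
            _cache["neigh"], _cache["w"] = neigh, w
    else:
        neigh, w = _cache["neigh"], _cache["w"]

    occ = np.flatnonzero(state.occupied)
    females = occ[state.sex[occ] == 0]
    males = occ[state.sex[occ] == 1]
    if len(females) == 0 or len(males) == 0:
        raise SimulationHalt(state.generation)
    is_male = np.zeros(config.n_sites, dtype=bool)
    is_male[males] = True

    # --- mating
    if config.mating == "wright_fisher":
        # no pair bonds: mother and father drawn per offspring (classic
        # random-union-of-gametes null; assumes global mate access)
        n_off = rng.poisson(config.fecundity * len(females))
        if n_off == 0:
            raise SimulationHalt(state.generation)
        mom = rng.choice(females, size=n_off)
        dad = rng.choice(males, size=n_off)
        return _disperse(state, config, neigh, w, mom, dad, rng)

    mothers, fathers = [], []
    taken = np.zeros(config.n_sites, dtype=bool)  # males already paired
    for f in rng.permutation(females):
        cand = neigh[f]
        ok = is_male[cand] & state.occupied[cand]
        if config.mating == "monogamy":
            ok &= ~taken[cand]
        if not ok.any():
            continue
        wk = w[f][ok]
        mate = rng.choice(cand[ok], p=wk / wk.sum())
        if config.mating == "monogamy":
            taken[mate] = True
        mothers.append(f)
        fathers.append(mate)
    if not mothers:
        raise SimulationHalt(state.generation)

    # --- reproduction (Mendelian, Poisson fecundity per mated female)
    litter = rng.poisson(config.fecundity, size=len(mothers))
    mom = np.repeat(mothers, litter)
    dad = np.repeat(fathers, litter)
    if len(mom) == 0:
        raise SimulationHalt(state.generation)
    return _disperse(state, config, neigh, w, mom, dad, rng)


def _disperse(state, config, neigh, w, mom, dad, rng) -> SimState:
    """Mendelian offspring from (mom, dad) site pairs, dispersed from the
    maternal site to vacant sites under the truncated kernel."""
    n_off = len(mom)
    Gm = state.genotypes[mom]
    Gd = state.genotypes[dad]
    off_G = (rng.binomial(1, Gm / 2.0) + rng.binomial(1, Gd / 2.0)).astype(np.int8)
    off_sex = (rng.random(n_off) < 0.5).astype(np.int8)
    natal = mom

    new_G = np.zeros_like(state.genotypes)
    new_occ = np.zeros(config.n_sites, dtype=bool)
    new_sex = np.zeros(config.n_sites, dtype=np.int8)
    placed_mom, placed_dad = [], []
    order = rng.permutation(n_off)
    for k in order:
        cand = neigh[natal[k]]
        free = ~new_occ[cand]
        if not free.any():
            continue
        wk = w[natal[k]][free]
        site = rng.choice(cand[free], p=wk / wk.sum())
        new_occ[site] = True
        new_G[site] = off_G[k]
        new_sex[site] = off_sex[k]
        placed_mom.append(mom[k])
        placed_dad.append(dad[k])
    if not new_occ.any():
        raise SimulationHalt(state.generation)
    return SimState(genotypes=new_G, occupied=new_occ, sex=new_sex,
                    generation=state.generation + 1,
                    founder_freqs=state.founder_freqs,
                    parents=(np.array(placed_mom), np.array(placed_dad)))


@dataclass
class Snapshot:
    replicate: int
    generation: int
    state: SimState
    patch_counts: dict[str, int]
    flagged: bool                 # some labelled patch extinct


def run_replicates(config: SimConfig, distances: np.ndarray,
                   flag_patches: list[str] | None = None) -> list[Snapshot]:
    """Run the replicate simulations, recording full state at every sampling
    generation; replicates where a flagged patch (default: every labelled
    patch) is extinct at a snapshot are flagged and excluded downstream.
    Corridor/stepping-stone patches are typically left out of flag_patches."""
    snapshots: list[Snapshot] = []
    patch_labels = (pd.unique(config.site_patch) if flag_patches is None
                    else np.asarray(flag_patches))
    cache: dict = {}
    for r in range(config.n_replicates):
        rng = np.random.default_rng(config.seed + r)
        state = init_population(config, rng)
        flagged = False
        try:
            for gen in range(1, config.n_generations + 1):
                state = step_generation(state, config, distances, rng, cache)
                if gen % config.sample_every == 0:
                    counts = {
                        str(lab): int((state.occupied
                                       & (config.site_patch == lab)).sum())
                        for lab in patch_labels
                    }
                    flagged = flagged or any(v == 0 for v in counts.values())
                    snapshots.append(Snapshot(
                        replicate=r, generation=gen, state=state,
                        patch_counts=counts, flagged=flagged))
        except SimulationHalt:
            # mark this replicate's existing snapshots unusable
            for s in snapshots:
                if s.replicate == r:
                    s.flagged = True
    return snapshots


def snapshot_matrix(config: SimConfig, snap: Snapshot) -> tuple[GenotypeMatrix, SampleFrame]:
    """All occupants of a snapshot as a genotype matrix + sample frame."""
    occ = np.flatnonzero(snap.state.occupied)
    ids = [f"s{r}" for r in occ]
    gm = GenotypeMatrix(ids, [f"l{j}" for j in range(config.n_loci)],
                        snap.state.genotypes[occ])
    sf = SampleFrame(pd.DataFrame({
        "id": ids,
        "x_km": config.site_coords[occ, 0],
        "y_km": config.site_coords[occ, 1],
        "pop": config.site_patch[occ],
    }))
    return gm, sf


def sample_at_locations(
    config: SimConfig, state: SimState, coords: np.ndarray,
    ids: list[str] | None = None,
) -> tuple[GenotypeMatrix, SampleFrame]:
    """Occupant of the nearest occupied home site per target coordinate.

    Each occupant is used at most once: a target whose nearest occupant is
    already taken falls through to the next-nearest unused one.
    """
    coords = np.asarray(coords, dtype=float)
    occ = np.flatnonzero(state.occupied)
    if len(occ) < len(coords):
        raise ValueError(
            f"only {len(occ)} occupants for {len(coords)} targets "
            f"(shortfall {len(coords) - len(occ)})")
    used = np.zeros(len(occ), dtype=bool)
    chosen = np.empty(len(coords), dtype=int)
    for i, (x, y) in enumerate(coords):
        d2 = ((config.site_coords[occ, 0] - x) ** 2
              + (config.site_coords[occ, 1] - y) ** 2)
        d2[used] = np.inf
        j = int(np.argmin(d2))
        used[j] = True
        chosen[i] = occ[j]
    ids = ids or [f"t{i}" for i in range(len(coords))]
    gm = GenotypeMatrix(ids, [f"l{j}" for j in range(config.n_loci)],
                        state.genotypes[chosen])
    sf = SampleFrame(pd.DataFrame({
        "id": ids, "x_km": coords[:, 0], "y_km": coords[:, 1],
        "pop": config.site_patch[chosen],
    }))
    return gm, sf
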