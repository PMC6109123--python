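"""End-to-end workflows: the empirical-style analysis chain and the
simulation-based type-I-error study for IBD vs IBD+IBR detection."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import LandscapeRaster, ResistanceModel, SampleFrame
from . import popgen, spatial, demography
from .landscape import build_graph, effective_resistance, snap_to_nodes
from .simulate import SimConfig, run_replicates, sample_at_locations
from .synthetic import SyntheticSpec, generate_bundle

__all__ = ["EmpiricalConfig", "run_empirical_workflow",
           "TypeIReport", "run_typeI_study", "resistance_distances"]


def resistance_distances(raster: LandscapeRaster, model: ResistanceModel,
                         coords: np.ndarray) -> np.ndarray:
    """Effective-resistance distances between coordinates snapped to cells."""
    graph = build_graph(raster, model)
    nodes = snap_to_nodes(graph, coords)
    R = effective_resistance(graph, nodes).values
    geo = np.linalg.norm(np.asarray(coords)[:, None] - np.asarray(coords)[None, :],
                         axis=2)
    return R + 1e-9 * geo  # break exact ties from shared snap cells


@dataclass
class EmpiricalConfig:
    seed: int = 1
    n_boot_fst: int = 999
    n_perm: int = 199
    abc_sims_per_scenario: int = 1000
    abc_loci: int = 100
    correlogram_class_km: float = 1.0
    synthetic: dict = field(default_factory=dict)  # SyntheticSpec overrides


def _config_hash(cfg: EmpiricalConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True).encode()).hexdigest()[:12]


def run_empirical_workflow(cfg: EmpiricalConfig, outdir: str | Path | None = None):
    """Run the full empirical-style analysis chain on the synthetic bundle.

    Stages: kin filter, PCA, diversity tables and pairwise F_ST (unfiltered
    and kin-filtered arms), AMOVA, correlogram, MEM partition with optimized
    resistance, LD-Ne (both arms), ABC model choice, migrant calls. Returns a
    dict of stage outputs; writes tables and a run log when outdir is given.
    """
    spec = SyntheticSpec(seed=cfg.seed, **cfg.synthetic)
    gm, sf, raster, truth = generate_bundle(spec)
    pops = sf.pops
    out: dict = {"truth": truth, "config_hash": _config_hash(cfg)}

    rel = popgen.qg_relatedness(gm)
    retained = popgen.kin_filter(rel)
    out["kin_retained"] = retained
    gm_f = gm.subset(individuals=retained)
    sf_f = SampleFrame(sf.table[sf.table["id"].isin(retained)])
    pops_f = sf_f.pops

    scores, frac = popgen.pca_genotypes(gm_f)
    out["pca_fractions"] = frac[:3]

    out["diversity_unfiltered"] = popgen.diversity_table(gm, pops)
    out["diversity_filtered"] = popgen.diversity_table(gm_f, pops_f)
    out["fst_unfiltered"] = popgen.pairwise_fst_wc(
        gm, pops, n_boot=cfg.n_boot_fst, seed=cfg.seed)
    out["fst_filtered"] = popgen.pairwise_fst_wc(
        gm_f, pops_f, n_boot=cfg.n_boot_fst, seed=cfg.seed)
    out["amova"] = popgen.amova(gm, pops, n_perm=cfg.n_perm, seed=cfg.seed)

    out["correlogram"] = spatial.spatial_autocorrelogram(
        gm_f, sf_f.coords(), class_km=cfg.correlogram_class_km,
        n_perm=cfg.n_perm, n_boot=max(cfg.n_perm, 100), seed=cfg.seed)

    from .landscape import enumerate_candidate_models
    best, ranking, corr = spatial.optimize_resistance(
        gm_f, sf_f.coords(), raster, enumerate_candidate_models(),
        n_perm=cfg.n_perm, seed=cfg.seed)
    out["best_model"] = best
    out["model_ranking"] = ranking
    out["ibr_ibd_correlation"] = corr
    rd = resistance_distances(raster, best, sf_f.coords())
    out["partition"] = spatial.memgene_partition(
        gm_f, sf_f.coords(), resistance_dists=rd,
        n_perm=cfg.n_perm, seed=cfg.seed)

    out["ne_unfiltered"] = demography.ld_ne(gm)
    out["ne_filtered"] = demography.ld_ne(gm_f)

    rng = np.random.default_rng(cfg.seed)
    obs_stats = demography.summary_stats(
        gm_f.G[:, :cfg.abc_loci].astype(np.int8), rng)
    out["abc"] = demography.abc_model_choice(
        obs_stats, n_sims_per_scenario=cfg.abc_sims_per_scenario,
        n=gm_f.n, L=cfg.abc_loci, seed=cfg.seed)

    out["migrants"] = demography.lhome_migrants(gm, pops, seed=cfg.seed)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        out["diversity_unfiltered"].to_csv(outdir / "diversity_unfiltered.csv", index=False)
        out["diversity_filtered"].to_csv(outdir / "diversity_filtered.csv", index=False)
        out["fst_unfiltered"].to_frame().to_csv(outdir / "fst_unfiltered.csv", index=False)
        out["fst_filtered"].to_frame().to_csv(outdir / "fst_filtered.csv", index=False)
        out["correlogram"].table.to_csv(outdir / "correlogram.csv", index=False)
        out["model_ranking"].to_csv(outdir / "resistance_ranking.csv", index=False)
        out["migrants"].to_csv(outdir / "migrants.csv", index=False)
        log = {
            "config": asdict(cfg), "config_hash": out["config_hash"],
            "kin_retained": retained,
            "amova_fst": out["amova"].fst, "amova_fis": out["amova"].fis,
            "ne_unfiltered": out["ne_unfiltered"].ne,
            "ne_filtered": out["ne_filtered"].ne,
            "abc_best": out["abc"].best_scenario,
        }
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return out


# ----------------------------------------------------------- type-I study

@dataclass
class TypeIReport:
    detection: pd.DataFrame    # generation, n_usable, n_detect, fraction
    fst_trajectories: pd.DataFrame  # generation, pair, mean, sd


def run_typeI_study(
    config: SimConfig,
    design: SampleFrame,
    resistance_dists: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 199,
    detect_generations: tuple[int, ...] = (10, 20, 30, 40, 50),
    flag_patches: list[str] | None = None,
    seed: int | None = None,
) -> TypeIReport:
    """Type-I error of IBD+IBR detection under IBD-only truth.

    The simulator runs with Euclidean distances (pure IBD); at each sampling
    generation the design coordinates are sampled and the MEM partition is
    offered the candidate resistance-distance predictors. Any IBR predictor
    entering after the IBD set counts as a spurious IBD+IBR detection.
    F_ST trajectories per subpopulation pair are computed for all sampling
    generations over non-flagged replicates.
    """
    if config.distance_mode != "euclidean":
        raise ValueError("type-I study requires IBD-only (euclidean) truth")
    distances = np.linalg.norm(
        config.site_coords[:, None] - config.site_coords[None, :], axis=2)
    snapshots = run_replicates(config, distances, flag_patches=flag_patches)
    flagged_reps = {s.replicate for s in snapshots if s.flagged}
    coords = design.coords()
    design_pops = design.pops

    det_rows: dict[int, list[bool]] = {g: [] for g in detect_generations}
    fst_rows = []
    rng = np.random.default_rng(seed)
    for snap in snapshots:
        if snap.replicate in flagged_reps:
            continue
        try:
            gm, _ = sample_at_locations(config, snap.state, coords,
                                        ids=design.ids)
        except ValueError:
            continue
        if len(pd.unique(design_pops)) >= 2:
            fst = popgen.pairwise_fst_wc(gm, design_pops, n_boot=0,
                                         seed=int(rng.integers(2**31)))
            for pair in fst.pop_pairs:
                fst_rows.append({"replicate": snap.replicate,
                                 "generation": snap.generation,
                                 "pair": f"{pair[0]}-{pair[1]}",
                                 "theta": fst.theta[pair]})
        if snap.generation in det_rows:
            part = spatial.memgene_partition(
                gm, coords, resistance_dists=resistance_dists,
                alpha=alpha, n_perm=n_perm, seed=int(rng.integers(2**31)))
            det_rows[snap.generation].append(part.ibr_after_ibd)

    detection = pd.DataFrame([
        {"generation": g, "n_usable": len(v), "n_detect": int(np.sum(v)),
         "fraction": float(np.mean(v)) if v else np.nan}
        for g, v in sorted(det_rows.items())
    ])
    if fst_rows:
        traj = (pd.DataFrame(fst_rows)
                .groupby(["generation", "pair"])["theta"]
                .agg(["mean", "std", "count"]).reset_index())
    else:
        traj = pd.DataFrame(columns=["generation", "pair", "mean", "std", "count"])
    return TypeIReport(detection=detection, fst_trajectories=traj)
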