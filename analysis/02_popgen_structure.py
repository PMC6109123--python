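#!/usr/bin/env python
"""Population-genetic structure of the synthetic bundle.

Reads results/bundle/, applies the half-sib kin filter, and computes both
analysis arms (unfiltered n=46 and kin-filtered n=35): diversity tables,
pairwise Weir-Cockerham F_ST with locus bootstraps, AMOVA, PCA, inbreeding
coefficients, and the locus-subsampling precision study. Tables land in
results/popgen/.
"""

from pathlib import Path

import pandas as pd

from landgen import io as lgio
from landgen import popgen
from landgen.datatypes import SampleFrame

BUNDLE = Path("results/bundle")
OUT = Path("results/popgen")
SEED = 2


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    gm, _ = lgio.read_genepop(BUNDLE / "genotypes.genepop")
    sf = lgio.read_coords_csv(BUNDLE / "coords.csv").aligned_to(gm)
    pops = sf.pops

    rel = popgen.qg_relatedness(gm)
    retained = popgen.kin_filter(rel)
    print(f"kin filter: {gm.n - len(retained)} pruned, {len(retained)} retained")
    gm_f = gm.subset(individuals=retained)
    sf_f = SampleFrame(sf.table[sf.table["id"].isin(retained)])

    for arm, g, p in (("unfiltered", gm, pops), ("kin_filtered", gm_f, sf_f.pops)):
        div = popgen.diversity_table(g, p)
        div.to_csv(OUT / f"diversity_{arm}.csv", index=False)
        fst = popgen.pairwise_fst_wc(g, p, n_boot=9999, seed=SEED)
        fst.to_frame().to_csv(OUT / f"fst_{arm}.csv", index=False)
        print(f"[{arm}] overall H_obs={div.iloc[-1]['Hobs_poly']:.4f} "
              f"pi={div.iloc[-1]['pi_poly']:.4f}")
        for pair in fst.pop_pairs:
            lo, hi = fst.ci[pair]
            print(f"  F_ST {pair[0]}-{pair[1]}: {fst.theta[pair]:.4f} "
                  f"({lo:.4f}, {hi:.4f})")

    am = popgen.amova(gm, pops, n_perm=999, seed=SEED)
    print(f"AMOVA: F_ST={am.fst:.4f} (p={am.p_fst:.3f}), "
          f"F_IS={am.fis:.4f} (p={am.p_fis:.3f}); "
          f"{am.percent['within_individuals']:.1f}% of variance within individuals")

    scores, frac = popgen.pca_genotypes(gm_f)
    print(f"PCA: first three axes explain "
          f"{', '.join(f'{100 * f:.2f}%' for f in frac[:3])}")
    pd.DataFrame({"id": gm_f.individuals, "pc1": scores[:, 0],
                  "pc2": scores[:, 1]}).to_csv(OUT / "pca_scores.csv", index=False)

    F = popgen.ml_inbreeding(gm)
    F.to_csv(OUT / "inbreeding.csv")
    by_pop = F.groupby(pops).mean()
    print(f"mean inbreeding by pop: {by_pop.round(4).to_dict()}; "
          f"max {F.max():.3f} ({F.idxmax()})")
    # realized inbreeding of the least diverse patch from H = H0(1-F)
    div_u = popgen.diversity_table(gm, pops).set_index("pop")
    h_low = div_u["Hobs_poly"].drop("overall").min()
    h_ref = div_u["Hobs_poly"].drop("overall").max()
    print(f"realized F from H = H0(1-F): "
          f"{popgen.realized_inbreeding_from_H(h_low, h_ref):.2f}")

    grid = [50, 100, 250, 500, 1000, 2000, 3500]
    prec = popgen.subsample_precision(gm, pops, grid, n_reps=100, seed=SEED)
    prec.to_csv(OUT / "subsample_precision.csv", index=False)
    sd500 = prec[(prec.n_loci == 500)].set_index("statistic")["sd"]
    print(f"subsampling SD at 500 loci: {sd500.round(4).to_dict()}")


if __name__ == "__main__":
    main()
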