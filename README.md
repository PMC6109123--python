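# landgen

Landscape population genomics of a small, recently fragmented songbird
population: how much population structure accumulates within a few dozen
generations of habitat fragmentation, and can the structure that does appear
be attributed to landscape resistance rather than to plain isolation by
distance?

`landgen` re-implements, as a tested library plus a sequence of analysis
scripts, the full analytical chain of a fine-scale landscape-genomic study of
an edge-tolerant forest bird sampled across an urbanized island: 46
individuals in three forest patches (one small isolated patch and two large
patch networks), ~3,850 unlinked biallelic SNPs, and a heterogeneous
land-cover mosaic. Because the study's SNP matrix and rasters are not
redistributable, the package ships a synthetic-data generator that emulates
the study conditions, so every stage runs end-to-end and every estimator can
be validated against planted truth.

## What it computes

**Diversity and differentiation.** Observed heterozygosity H_obs and
nucleotide diversity π per subpopulation (for polymorphic loci and for all
assayed sites), private alleles, pairwise Weir–Cockerham θ (F_ST) with
percentile bootstraps over loci (B = 9,999), and a nested allele-dosage AMOVA
with permutation tests for F_ST (individuals among populations) and F_IS
(random union of gametes within populations).

**Relatedness, kin filtering, inbreeding.** Queller–Goodnight relatedness
with pair-excluded reference frequencies, greedy pruning of pairs with
r̂ > 0.25 (half-sib threshold), a per-individual maximum-likelihood
inbreeding coefficient F̂ (mixture of identity-by-descent and Hardy–Weinberg
genotype laws), and the realized-inbreeding derivation F = 1 − H/H₀.

**Spatial structure.** Smouse–Peakall multivariate autocorrelograms (1-km
distance classes, 999 location permutations, 1,000 pair bootstraps),
distance-based Moran eigenvector maps (dbMEM, MST truncation), and a
MEMGENE-style partition of the spatial genetic signal into isolation-by-
distance (IBD) and isolation-by-resistance (IBR) components by forward
selection of MEM predictors with a global permutation gate and Ezekiel-
adjusted R².

**Landscape resistance.** Raster-to-graph conversion (8-neighbourhood,
average-resistance conductances), exact circuit-theory effective resistance
via Laplacian solves, least-cost distances, and enumeration of the 45
candidate resistance models (urban and managed-vegetation resistance on a
step-10 grid with resistance_urban > resistance_managed, forest = 1,
water = 100), ranked by explained genetic variance.

**Demography.** LD-based contemporary N̂e (Burrows composite r² with the
random-mating sampling correction and jackknife CIs), ABC model choice among
constant / contraction / expansion single-population histories (vectorized
fixed-S coalescent, rejection + multinomial-logistic posteriors, Beaumont
local-linear parameter adjustment), and first-generation migrant detection
with the L_home statistic against an exactly calibrated conditional
Monte-Carlo null.

**Forward simulation.** A CDPOP-style spatially explicit individual-based
simulator (fixed home sites, truncated (1+d)^−β kernels for mating and natal
dispersal, Mendelian inheritance, no mutation) used for F_ST-accumulation
trajectories and for measuring the type-I error of IBD+IBR detection when
the simulated truth is IBD-only.

## Worked example

```bash
python analysis/01_make_synthetic_data.py
python analysis/02_popgen_structure.py
```

prints (seed 1):

```
kin filter: 11 pruned, 35 retained
[unfiltered] overall H_obs=0.3535 pi=0.3611
  F_ST admiralty-central: 0.0566 (0.0503, 0.0630)
  F_ST admiralty-southern: 0.0621 (0.0552, 0.0690)
  F_ST central-southern: 0.0297 (0.0273, 0.0321)
[kin_filtered] ...
  F_ST admiralty-central: 0.0300 (0.0225, 0.0376)
  F_ST central-southern: 0.0231 (0.0206, 0.0256)
AMOVA: F_ST=0.0365 (p=0.001), F_IS=0.0011 (p=0.430); 96.2% of variance within individuals
PCA: first three axes explain 4.89%, 3.66%, 3.47%
mean inbreeding by pop: {'admiralty': 0.0899, 'central': 0.0297, 'southern': 0.0321}; max 0.200 (K0003)
```

Reading: the small isolated patch (admiralty) is the most differentiated and
the most inbred; pruning the eleven planted kin pairs lowers every pairwise
F_ST (kin inflate among-patch variance) while leaving diversity essentially
unchanged; almost all molecular variance sits within individuals, i.e.
structure is real but shallow. `analysis/03`–`05` continue the chain:
significant positive spatial autocorrelation in the first 1-km classes and
negative autocorrelation beyond ~7 km; an optimized resistance model whose
distances are strongly collinear with Euclidean distance; kin-filtered LD-Ne
several-fold above the unfiltered estimate; ABC evidence for a recent
contraction; and, in the forward simulations, F_ST rising over 100
generations with the isolated patch diverging fastest while the MEM
partition spuriously reports IBD+IBR in the majority of IBD-only replicates
from generation 20 on — the study's cautionary finding about sampling
design.

## Layout

```
src/landgen/        library: datatypes, io, synthetic, popgen, landscape,
                    spatial, demography, simulate, pipeline
analysis/           numbered drivers reproducing the analysis sequence
tests/              pytest suite (unit, property, and end-to-end checks)
scripts/acceptance.py
docs/methods.md     models, assumptions, parameter choices, limitations
```
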