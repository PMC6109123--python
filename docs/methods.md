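# Methods

This note documents the models, estimators and design choices behind
`landgen`, in the order the analysis uses them, together with the defaults
that matter and the known limitations.

## Data model

Genotypes are biallelic SNP dosages g ∈ {0, 1, 2} (count of the alternate
allele) with no missing entries; matrices that do not satisfy this are
rejected at the I/O boundary. Coordinates are planar kilometres — the study
area is a few tens of kilometres wide, so projection distortion is
negligible. Land cover is a categorical raster with four classes (forest,
managed vegetation, urban, water); a resistance model maps classes to values
on the conventional 1 (no resistance) to 100 (maximum) scale.

## Synthetic data generator

The generator emulates the study conditions so that every estimator can be
exercised against planted truth: 46 individuals in three patches (3 / 27 /
16), 3,849 unlinked SNPs, overall Weir–Cockerham θ ≈ 0.023, spatial
autocorrelation decaying within ~1 km, eleven within-patch kin pairs
(so greedy half-sib pruning removes exactly 11 individuals) and one
individual with inbreeding coefficient F = 0.16.

Per locus, an ancestral frequency p₀ ~ Uniform(0.05, 0.95) is perturbed by
two Gaussian components before binomial genotype draws:

- a **patch-level shift** u ~ N(0, σ_p²), shared by all members of a patch,
  which carries the among-patch differentiation; σ_p is calibrated by
  bisection (12 iterations on a 400-locus pilot draw with its own seed
  stream) so the realized multi-locus θ matches the requested target;
- a **short-range field** with covariance σ_s² exp(−d/κ), κ = 0.7 km and
  σ_s = 0.05, which produces the first-kilometre autocorrelation.

A single short-range field cannot do both jobs: driving patch-level θ
through a field with κ ≪ patch size forces a large per-individual frequency
variance, which shows up as spurious individual inbreeding (apparent
F̂ ≈ 0.26 in pilot runs). Splitting the scales keeps background F̂ at the
few-percent level while hitting the θ target. κ itself is a free fixture
choice consistent with first-bin-only positive autocorrelation at 1-km
classes. Frequencies are clamped to [0.01, 0.99]; loci that come out
monomorphic across the sample are redrawn (up to 100 attempts, then dropped
with a warning).

Kin pairs regenerate one member locus-wise as an offspring of its pair-mate
and a random parent drawn from the *regenerated individual's own local
frequency surface* (the realized field value at its location), giving
expected relatedness 0.5 without making the individual look like an
immigrant. Inbred individuals are regenerated under
P(het) = (1−F)·2pq, P(alt hom) = (1−F)p² + Fp, P(ref hom) = (1−F)q² + Fq,
which reduces exactly to Hardy–Weinberg at F = 0.

The default landscape is a 40 × 24 grid of 0.5-km cells: a large central
patch and a large southern patch bridged by a managed-vegetation
stepping-stone corridor (7 rows, 0.5-km gaps), and a small northern patch
isolated by 2 km of urban matrix — mirroring a minimum ~2.25-km gap in the
study system — with water strips on the east and west edges.

What the generator does **not** emulate: linkage, genotyping error and
missingness, sex-linked loci, continuous (non-patch) population structure,
and temporal sampling; tests passing on these fixtures therefore validate
the estimators' mathematics and calibration, not robustness to those
real-data artefacts.

## Diversity and differentiation

Per-locus observed heterozygosity is the heterozygote fraction; nucleotide
diversity uses the sample-size-corrected π = (2n/(2n−1))·2pq. "Fixed &
polymorphic" rows divide the same locus sums by L × 90 assayed sites,
emulating 90-bp RAD windows. Private alleles count (locus, allele) pairs
present in exactly one population.

Weir & Cockerham's (1984) per-locus components a (among populations),
b (among individuals within populations) and c (within individuals) are
computed from the closed forms in p̄, s², h̄; the multi-locus estimate is
θ̂ = Σa / Σ(a+b+c), with percentile bootstraps over loci (default B = 9,999)
for CIs. Loci monomorphic across the populations compared contribute zeros;
if every locus is monomorphic the estimate is undefined and an error is
raised. The test suite checks the closed forms against an independently
coded allele-level ANOVA (mean-squares) route to 10⁻¹² on random instances.

The AMOVA is the nested allele-dosage ANOVA (population / individual /
gene copy): σ²_c = MSG, σ²_b = (MSI − MSG)/2, σ²_a = (MSP − MSI)/(2n_c),
summed over loci; F_ST = σ²_a/σ²_tot and F_IS = σ²_b/(σ²_b + σ²_c).
F_ST is tested by permuting individuals among populations; F_IS by
re-pairing gene copies within populations, implemented exactly via the
random-pairing heterozygote-count law (sampling the alt-allele slots
uniformly without replacement). A dosage formulation was chosen because the
genotype matrix is biallelic dosage data; the distance-based alternative
gives the same components for this encoding.

## Relatedness, kin filtering, inbreeding

Queller–Goodnight relatedness uses reference allele frequencies computed
from all individuals *excluding the focal pair*, and symmetrizes the two
directional estimates. Kin filtering is greedy: while any pair exceeds the
threshold (0.25, the half-sib criterion), remove the individual in the most
super-threshold pairs, ties broken by lower ID — deterministic, and the
retained set provably contains no residual pair above threshold.

The triadic-likelihood inbreeding estimator of the original study is
replaced by a per-individual ML estimator: each locus likelihood is the
mixture F·P_IBD + (1−F)·P_HWE with P_IBD = q, 0, p for g = 0, 1, 2;
F̂ maximizes the log-likelihood on [0, 1] by golden-section search
(tolerance 10⁻⁶), with frequencies computed excluding the focal individual
and fixed loci skipped. This supports both uses the analysis makes of
inbreeding coefficients — ranking individuals/subpopulations and
cross-checking the realized-inbreeding relation F = 1 − H/H₀ (reported to
two decimals, negative values warned rather than raised).

## Spatial autocorrelation

Squared multilocus genotype distances (g_i − g_j)² summed over loci (0
identical, 1 het–hom, 4 opposite homozygotes) are double-centred to a
covariance matrix; the class statistic is r = Σc_xy / √(Σc_xx·Σc_yy) over
the class's pairs, **plus 1/(n−1)**: double-centring forces the mean
off-diagonal covariance negative, so like Moran's I the raw ratio has null
expectation ≈ −1/(n−1), and recentring makes the permutation envelope
straddle zero. Distance classes are 1 km wide; the null envelope permutes
individual locations (999 by default), CIs bootstrap pairs within class
(1,000), and classes with fewer than 8 pairs are flagged unstable.

## Moran eigenvector maps and IBD/IBR partitioning

dbMEM bases come from Gower-centring −½D*² of a truncated distance matrix
(threshold t = longest minimum-spanning-tree edge; entries beyond t are
replaced by 4t); eigenvectors with positive eigenvalue model positive
spatial autocorrelation and are the candidate predictors.

The response is the PCoA of the proportion-of-shared-alleles distance. The
broken-stick rule picks the leading "signal" axes that drive model
selection, but **all reported R²_adj values are fractions of the total
variance across all positive PCoA axes** — the convention of variance
partitioning on genetic distance matrices, and the scale on which the
original analysis reports values of order 0.03. R²_adj is Ezekiel's
1 − (1−R²)(n−1)/(n−k−1), floored at zero.

Selection is a two-level procedure:

1. a **global permutation gate** — the trace R² of the response on the full
   positive-MEM basis against 999 response permutations; if not significant
   at α the partition is empty. This single pre-test is what keeps the
   pure-noise detection rate at the nominal level.
2. **forward selection** — at each step the candidate with the largest R²
   gain is admitted if its own gain beats a Freedman–Lane permutation
   distribution at α. Testing the *chosen* candidate as if it were
   pre-specified is the classic forward-selection procedure and is
   anticonservative by construction; this is deliberate, because that
   anticonservatism, combined with the strong collinearity between
   resistance and Euclidean distances, is precisely the mechanism that
   produces spurious IBD+IBR detections, the phenomenon the type-I study
   quantifies. The double-stopping rule also halts selection once
   cumulative R²_adj exceeds the global model's.

"IBD+IBR detected" means: after forward selection among the IBD (Euclidean)
MEMs, at least one IBR (resistance-distance) MEM subsequently enters.
The combined R²_adj is computed on the union of the selected sets and
reported as the maximum of {union, IBD-only, IBR-only} so the nested-model
ordering survives the adjustment penalty.

Resistance-model optimization scores each of the 45 candidates (urban and
managed-vegetation resistance from {10, …, 100} with urban > managed,
forest 1, water 100 — the grid reconstructed from the candidate count
45 = C(10, 2)) by the IBR-only R²_adj of its effective-resistance distances,
and also reports the Pearson correlation between the winning model's
distances and Euclidean distances — the IBD/IBR collinearity check.

## Landscape graphs

Rasters become graphs with one node per non-water cell and 8-neighbour
edges; edge conductance is 2/(r_a + r_b), divided by √2 on diagonals (the
average-resistance convention). Effective resistance is solved exactly from
the grounded Laplacian (sparse LU, one factorization per connected
component); disconnected focal pairs get an infinite-resistance flag rather
than an exception. Least-cost distances run Dijkstra over reciprocal
conductances. Sampling coordinates snap to the nearest non-water cell,
ties broken in row-major order; snapped duplicates are disambiguated by an
infinitesimal Euclidean admixture (10⁻⁹·d) when the distances feed MEM
construction, which requires strictly positive off-diagonal distances.

## LD-based Ne

Burrows' composite disequilibrium Δ̂ (with the n/(n−1) correction) over all
pairs of loci passing a minor-allele-count filter (default 3), r² = Δ̂²/
(p_Aq_A·p_Bq_B), and the random-mating sampling expectation E(r²_S) = 1/S +
3.19/S² for S ≥ 30 (0.0018 + 0.907/S + 4.44/S² below). The point estimate is
N̂e = (1/3 + √(1/9 − 2.76 r²'))/(2r²') with r²' = r̄² − E(r²_S); r²' ≤ 0
flags an infinite estimate. CIs are delete-one-locus jackknife. Family
structure in the sample biases r̄² upward and hence N̂e downward — the
package's own analyses show the unfiltered/kin-filtered contrast
(e.g. 78.6 vs 212.3 on the default bundle), the same behaviour the original
study saw between its two arms; aggressive kin purging over-corrects.

## Coalescent ABC

The three demographic scenarios are single-population piecewise-constant
histories: constant (N₁), contraction (N₁ < N_dec, change t generations
ago) and expansion (N₁ > N_dec). Priors: log-uniform sizes on [10, 10⁶],
uniform t on [1, 10⁴], constraint enforced by rejection.

The simulator is a custom vectorized coalescent: level waiting times T_k
are drawn per locus with the two-epoch rate switch handled by memorylessness
(fresh exponential beyond the change time); the single segregating site per
genealogy (fixed-S convention, conditioned polymorphic) is placed by
choosing level k ∝ k·T_k and drawing the derived subtree size from the
classical topology law P(i|k) = C(m−i−1, k−2)/C(m−1, k−1). Derived copies
are assigned to gene copies uniformly and paired into diploids. This needs
no tree construction, so a 15,000-simulation reference table builds in
seconds; tests validate it against an explicit tree-building coalescent
oracle (derived-count law at n = 4) and against E[T_MRCA] = 4N(1 − 1/m).

Six summary statistics per simulated dataset: mean and variance of expected
heterozygosity, mean and variance of minor-allele frequency, fraction of
loci with MAF < 0.05, and mean Burrows r² on a locus-pair subsample. ABC
retains the tolerance fraction (default 1%) of simulations nearest in
MAD-normalized Euclidean distance; scenario posteriors come from both the
retained-set shares (rejection) and a multinomial logistic regression
evaluated at the observed statistics. Parameter posteriors for the winning
scenario use Beaumont local-linear adjustment (on log₁₀ scale for sizes),
clipped back to the prior support, with quantiles at 5/25/50/75/95% and a
kernel-density mode.

## Migrant detection

L_home is the leave-one-out Hardy–Weinberg genotype log-likelihood of an
individual under its sampling population's allele frequencies (floored at
1/(2n)). The Monte-Carlo null is the *conditional* variant of frequency-
based resampling: given the population's pooled allele counts, a resident's
two gene copies are an exchangeable 2-subset of the pool, so null focal
genotypes are hypergeometric draws scored against their own leave-one-out
frequencies. This is exactly calibrated by exchangeability; the naive
plug-in null (simulate from estimated frequencies, score under them)
accumulates an O(L) Jensen bias at thousands of loci and is wildly
anticonservative. An individual is called a migrant at p < α (default
0.01); the putative source is the population maximizing its genotype
likelihood. Within-patch spatial structure makes a few true residents
mildly atypical of their pooled patch frequencies, so the default bundle
yields a handful of migrant-like calls — the same order as the two
first-generation migrants the original analysis reported.

## Forward simulator

CDPOP-style: fixed home sites (one occupant each), non-overlapping
generations. Each generation, females choose a mate among males within the
maximum dispersal distance with probability ∝ (1+d)^−β; offspring
(Poisson fecundity, Mendelian inheritance, equal sex ratio) disperse from
the maternal site to vacant sites under the same truncated kernel; unplaced
offspring die; all adults die. No mutation (neutral loci, ≤ 100-generation
horizon). Total extinction raises a halt signal carrying the generation;
replicates in which a labelled subpopulation is extinct at a snapshot are
flagged and excluded downstream, mirroring the discarding of extinct
replicates in the original simulations.

Defaults: maximum dispersal 1 km (from the first-distance-class
autocorrelation result), β = 1, monogamous pair formation per generation,
fecundity 4. The original study's "relaxed life history parameters" are not
published; these values are the package's own choice, set so that the
small isolated patch (~24 sites at desk scale) is demographically viable
while stochastic extinctions remain possible. The desk-scale default
shrinks the study's 5,761 home sites to 600, preserving patch area ratios;
the full size is configurable. Stepping-stone (managed-vegetation) cells
carry home sites so the southern corridor conducts gene flow, but they are
excluded from the subpopulation-extinction flag.

Three mating modes: `monogamy` (exclusive pairs, realistic sibship
structure), `random` (one sire per female's brood), and `wright_fisher`
(both parents redrawn per offspring — the panmictic null whose effective
size equals the census size; used for the drift-law and Ne-recovery
validations). The simulator records the parentage of placed offspring so
realized offspring-number variance (and hence effective size,
Ne = (4N−2)/(V_k+2)) can be audited.

## Type-I study

The simulator runs with Euclidean distances (IBD-only truth) on the
synthetic landscape; at each sampling generation the 46-point clustered
study design is sampled (nearest occupied site per coordinate, no reuse)
and the MEM partition is offered resistance-distance predictors from the
optimized model. The spurious-detection fraction over non-flagged
replicates reproduces the study's finding: a majority of IBD-only
replicates report IBD+IBR from generation 20 on (0.83 / 0.97 / 1.0 / 1.0
at generations 20–50 over 29 usable of 30 replicates at seed 5), while the
same machinery is calibrated (≈ 5% detection) on spatially unstructured
data. Pairwise F_ST trajectories over generations 10–100 rise
monotonically for all pairs with the isolated patch diverging fastest.

Limitation: the study's further observation that a dense uniform sampling
design should lower the spurious-detection rate does not reproduce under
this detection rule — at n = 200 the per-step forward-selection test has so
much power that detection saturates for any design. Discriminating sampling
designs would require a detection criterion whose power is equalized across
designs, which the original procedure does not define.

## Problem sizes and determinism

Default analysis sizes (46 × 3,849 bundle; 600-site, 99-locus, 100-
generation, 30-replicate simulations; 5,000 ABC simulations per scenario;
999 permutations / 9,999 bootstraps) run the whole chain in minutes on one
CPU; the test suite uses reduced locus counts and permutation numbers where
the check is structural rather than numerical. Every stochastic routine
takes an explicit seed; bundle generation, the workflows and the acceptance
script are bit-reproducible from (config, seed).
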