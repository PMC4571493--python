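# Methods

## Genotype representation

Biallelic SNP genotypes are stored as additive dosage codes: 0 and 2 for the
two homozygotes, 1 for the heterozygote.  Code 2 counts the ALT (VCF) allele
twice; because ALT is not guaranteed to be the minor allele, which homozygote
carries 0 vs 2 is a labelling convention.  The data-driven encodings are
covariant under that relabelling (swapping 0↔2 at a marker swaps E(i,0) and
E(i,2) and leaves the heterozygote value unchanged), so the convention is
documented rather than enforced.  The missing-call sentinel is −9, an
out-of-band integer; −1 is deliberately avoided since it is a legal encoded
value under the {−1, 0, 1} scheme.

Marker QC drops a marker when its missing fraction exceeds
`max_missing_rate`, its minor-allele frequency falls below `min_maf`
(MAF = min(p, 1−p), p = (2·n_hom2 + n_het)/(2·n_called)), or its
heterozygote fraction exceeds `max_heterozygosity`.  All comparisons are
boundary-inclusive for keeping (a marker exactly at the threshold stays).
Defaults: missing ≤ 10 %, MAF ≥ 0.001, heterozygosity unbounded — the values
used for array-genotyped livestock panels.  Missing calls are imputed with
the per-marker modal code, ties broken toward the smaller code; modal rather
than mean imputation keeps codes in {0, 1, 2} so the class-mean encodings
remain well defined.

## Encodings

For marker *i* and genotype class *c*, the pure data-driven encoding is the
class mean of the training trait, E(i, c) = Ave{ y_l : X_li = c }.  The
hybrid variant keeps the class means for the homozygotes and sets
E(i, 1) to the grand training mean, preserving the traditional intuition
that the heterozygote lies between the homozygotes while still letting the
phenotype place the homozygote values.  The pairwise extension assigns each
marker pair a 3×3 grid: the four corner cells are means conditional on both
codes; the edge cell (1, c_j) is the marginal mean over samples with code
c_j at marker *j* (treating the heterozygous marker as unconstrained), and
symmetrically for (c_i, 1); the centre (1, 1) is the grand mean.  Two exact
identities follow and are asserted in the tests: edge cells equal the
single-marker hybrid encodings of the conditioned marker, and the centre
equals the single-marker heterozygote value.

Genotype classes with no training samples take the grand training mean as a
fallback, which is consistent with the hybrid centre-cell logic and keeps
every table total.  Encoding tables are fitted on training samples only and
applied read-only elsewhere; fitting them on test traits would leak the
prediction target, since an encoded test genotype would then carry its own
trait value.  Encoded features are not re-standardized before regression.

## rrBLUP

The mixed model is y = 1β₀ + Xu + e with u ~ iid N(0, σ²_β) and
e ~ N(0, σ²ₑ I).  The BLUP of u coincides with the ridge estimator at
shrinkage λ = σ²ₑ/σ²_β.  The intercept is unpenalized and handled by
centering y and the columns of X, then recovering β₀ = ȳ − x̄ᵀβ.  For
m > n the dual identity β = X_cᵀ(X_cX_cᵀ + λI)⁻¹y_c keeps the cost at
min(n, m)³; XᵀX is never materialized when p > n (relevant for epistasis
designs with thousands of pair features).

λ is estimated by REML.  After one eigendecomposition of the centered
kernel X_cX_cᵀ = U diag(d) Uᵀ, the restricted likelihood profiled over
σ²_β is a one-dimensional function of λ that costs O(n) per evaluation:
with r = Uᵀy_c and n−1 degrees of freedom (one lost to the intercept
direction, whose eigenvalue is 0 and projection exactly 0),

    σ̂²_β(λ) = Σ rᵢ²/(dᵢ+λ) / (n−1)
    −2 l_R(λ) ∝ (n−1)·log σ̂²_β(λ) + Σ log(dᵢ+λ) − log λ + const.

The profile is scanned on a 61-point log grid over λ ∈ [10⁻⁶, 10⁶] and the
bracketing interval refined by bounded scalar minimization to 10⁻⁸ in
log λ.  Hitting a search bound (noiseless data drive λ to the lower bound,
signal-free data to the upper) emits a warning rather than an error, since
the fit is still the correct limiting behaviour.  A fixed-λ ridge solver is
exposed for users who want to bypass REML.

Degenerate inputs: an all-constant design leaves λ unidentifiable and is
rejected; REML requires n ≥ 3.

## Epistasis screening

The interaction feature of a pair under a fixed scheme combination is the
product of the two encoded values, mirroring the multiplicative epistasis
model; the four combinations E1–E4 pair {0,1,2} and its reversal {2,1,0}
across the two markers.  Relevance is the plug-in mutual information (bits)
between the distinct product values and the trait discretized into
equal-frequency bins (default 10; duplicate quantile edges are merged, and a
constant trait is a single bin with MI defined as 0).  Pairs are enumerated
streamed, never materializing an m² feature matrix, and ties are broken by
lexicographic marker order so rankings are deterministic.

Product categories, not the 9-cell joint genotype, are deliberately used:
the collapse of distinct combinations onto one product (0·1 = 0·2 = 0) is
exactly the pathology the data-driven grid encoding addresses, so the
screen reflects the model it feeds.  A consequence worth noting: reversing
both schemes (E1 vs E4) is *not* a bijective relabelling of products — the
(0,0) cell maps to 4 while (0,2) and (2,0) still map to 0 — so E1 and E4
induce different sample partitions and generally different rankings.  The
exact invariances are: MI is unchanged under any bijective relabelling of
categories, and E4 on a genotype matrix equals E1 on its 0↔2-relabelled
copy; both are asserted in the tests.

Ranked lists from different combos are compared by average overlap,
AO(a, b) = (1/K) Σ_{k≤K} |top_k(a) ∩ top_k(b)|/k, a symmetric measure on
possibly non-identical item sets (rank correlations such as Spearman's
require the same items in both lists).  K defaults to the shorter list.

## Cross-validation

Samples are partitioned uniformly at random (seeded) into k folds of sizes
differing by at most one.  Within each fold, encoding tables, the MI pair
ranking, the top-K selection, the pair grids and the regression are all
fitted on the training split only.  The epistasis design is main-effect
features plus the selected pair features.  Re-ranking pairs inside every
fold is slower than ranking once globally but avoids selection leakage; a
`rank_once` flag reproduces the global protocol for users who want it.
The reported summary is the arithmetic mean of per-fold r² values, where
r² is the squared Pearson correlation and is defined as 0 when either
vector is constant (so a degenerate fold cannot poison the mean with NaN).
Several arms can share one fold assignment for paired comparisons, and do
so in the simulation sweep.

## Simulator

One dataset is: per-marker MAF ~ U(0.05, 0.5); genotypes drawn from the
Hardy–Weinberg class probabilities ((1−q)², 2q(1−q), q²); effects
β₁..β_s ~ N(0, σ_β²) on the first s markers, zero elsewhere; residuals
e ~ N(0, σₑ²); trait Y = Xβ + e computed on the raw dosage codes.
Defaults are n = 100 samples, m = 500 markers, σ_β = σₑ = 1.  `s` sets the
architecture: 5–20 oligogenic, 50–200 polygenic.  An optional hook adds
multiplicative pair terms γ·XᵢXⱼ for planted epistasis; it is used by the
MI-screen checks (γ = 1, σₑ = 0.5, n = 500, m = 20) and off by default.

What the simulator does *not* emulate: linkage disequilibrium, population
structure or relatedness, MAF spectra skewed toward rare variants,
genotyping error, and non-Gaussian traits.  Passing tests on simulated data
therefore demonstrate the correctness and the qualitative
oligogenic-vs-polygenic behaviour of the methods, not the absolute
accuracies obtainable on real panels, where LD between markers and
structure typically dominate.  Absolute r² values depend on the
(unconstrained) choice of σ_β/σₑ and are not comparison targets; only the
directional pattern — hybrid over traditional for oligogenic traits,
traditional at least as good for polygenic ones — is asserted, and it is
evaluated over replicate datasets with shared folds.

## Problem sizes and numerical choices

The replicate study uses 10 datasets per architecture and 10-fold CV
(600 REML fits for the two-architecture sweep), which runs in seconds with
the spectral solver.  REML recovery checks use n = 200, m = 50 with 50
replicates.  Eigenvalues of the centered kernel are clipped at 0 to guard
against tiny negative round-off; the TSV writers print 17 significant
digits so encoded matrices and reports round-trip bit-faithfully (readers
use round-trip float parsing).  Fold assignment, simulation and CLI runs
are deterministic given their seeds; rerunning any subcommand with the same
seed reproduces its output files byte for byte.

## Known limitations

* The data-driven encodings assume a reasonably dense sampling of genotype
  classes; with very rare classes the grand-mean fallback flattens markers
  toward no signal.
* The MI screen's plug-in estimator is biased upward at small n; no
  significance testing or bias correction is applied, since only ranks are
  consumed.
* Higher-than-pairwise interaction grids are out of scope.
* VCF input handles biallelic GT calls only; multi-allelic sites are
  skipped with a warning rather than decomposed.
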