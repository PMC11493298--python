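# Methods

## Model and scope

The package works under the additive polygenic model: genetic value
A_i = Σ_l β_l G_il, phenotype Y_i = A_i + E_i, and genetic covariance
Cov(A_i, A_j) accumulated over single loci.  Cross-locus covariance terms
(which arise, e.g., under directional selection on polygenic traits) are
neglected throughout, as are gene–environment covariances, dominance, and
epistasis.  Effect-size distributions are assumed to have finite variance.
The four Σ constructions — genotype GRM, pedigree kinship, gene-tree eGRM,
and phylogenetic Brownian vcv — are all estimates or expectations of this
one quantity under different conditioning: on genotypes, on the pedigree,
on gene trees (random mutations), or on a single species tree.

## Trees

Trees are rooted, with non-negative branch lengths required on every edge
except the root edge.  A tree may carry a *stem* (root-edge) length,
shared by all tips; it is included in shared-path matrices and in the
total tree length, since a Brownian trait started at the origin
accumulates variance along it.  Tip order in all matrices is lexicographic
by label.

The pure-birth simulator starts from a single lineage at the origin;
while k lineages exist the next split arrives after an
Exponential(k·birth-rate) wait, the splitting lineage is chosen uniformly,
and simulation stops the instant the n-th lineage is born.  The wait while
one lineage exists becomes the stem.  Consequences of this stopping rule:
tree depth (stem included) is hypoexponential with rates (k·b, k = 1..n−1),
and the two youngest tips always have zero-length terminal branches, so
the shared-path matrix of a pure-birth tree is singular (two identical
rows).  Simulators that condition on n extant tips at a later sampling
time avoid this; we use the simple stopping rule and handle the
singularity in the estimators (below).  `Tree.without_stem()` strips the
stem when a simulated tree should mimic an inferred phylogeny, which
carries no branch above its root.

## Covariance constructions

*GRM.*  Allele frequencies are sample frequencies (column mean / 2);
monomorphic loci, whose standardization is undefined, are dropped and
counted.  Effect-size weighting follows the α model,
β²(p) ∝ (2p(1−p))^(−α); α = 1 is the canonical GWAS standardization
(derivable from mutation–selection balance under Gaussian stabilizing
selection, scale 2μ/V_s), α = 0 the mean-centered-only convention used in
breeding.  By default the sum over loci is divided by the number of
polymorphic loci so diagonals are O(1); a flag preserves the raw sum.  Two
finite-sample facts worth knowing: sample centering puts the ones-vector
in the GRM's null space (rows sum to zero), so GLS with σ_E² = 0 cannot
estimate an intercept against a GRM and raises a collinearity error (use
the mixed model, whose σ_E² > 0 regularizes it); and the off-diagonal mean
is exactly −mean(diag)/(n−1), approaching zero only as n grows.

*Pedigree kinship.*  The numerator relationship matrix A = 2θ by the
standard tabular recursion in topological order; founders and unknown
parents contribute zero kinship.  Multiply by V_A externally.

*eGRM.*  For gene trees with a common tip set, entries are expected shared
branch length.  Two conventions are provided because the ratio of
expectations (mean_k S_k / mean_k T_k, the coalescent expectation) and the
expectation of ratios (mean_k S_k/T_k, the per-tree Brownian form)
disagree for heterogeneous trees; the default is ratio-of-means.  Shared
branch lengths are uncentered; the PCA-style double-centered variant is
out of scope.

*Phylogenetic vcv.*  rate × shared-path matrix; under the additive model
the rate equals L·E(β²)/T (equivalently U·E(β²) with U the total mutation
rate toward causative alleles).

*Eigendecomposition.*  Eigenvalues are sorted descending; within
numerically repeated eigenvalues LAPACK's orthonormal basis is kept; signs
are fixed deterministically (largest-magnitude entry positive, ties to
the lowest index) so eigenvector covariates are reproducible.  Eigenvalues
in (−1e−9·λ₁, 0) are clipped to zero; anything more negative raises.

## Estimators

All fits happen in the eigenrotated frame of Σ: GLS with residual
covariance σ_G²Σ + σ_E²I becomes weighted least squares with weights
w_j = σ_G²λ_j + σ_E².  When σ_E² = 0 and Σ is singular (identical tips,
GRM null space), dimensions with w_j ≤ 1e−12·max(w) are dropped: the model
places no mass there and data generated under it project to zero on them
almost surely; residual degrees of freedom become rank − p in that case
(otherwise n − p).  Wald t-tests are two-sided with df = residual
dimensions minus fitted columns, for every method including after REML (no
Satterthwaite or small-sample adjustment).  Experiments always include an
intercept; the no-intercept spectral forms are kept exact and verified to
1e−8 in tests.

REML profiles the restricted likelihood down to φ = σ_E²/σ_G²: for fixed φ
the scale σ_G² has the closed form RSS_w/(n−p), and
−2·loglik(φ) = (n−p)·log σ̂_G² + Σ log w_j + log det(X̃ᵀW⁻¹X̃) + const.
φ is scanned on a 61-point log grid over [1e−6, 1e6] and refined by
bounded scalar minimization in the bracketing interval; optima pinned at
either end are flagged `boundary` (σ_E² ≈ 0 below, σ_G² ≈ 0 above).
Σ ∝ I is rejected as unidentifiable (only the sum of components enters the
likelihood).  The phylogenetic case (PGLS) fixes σ_E² = 0 — the
pure-Brownian model — while the GWAS mixed model estimates both.

## Synthetic data: what it emulates, and what it does not

*Brownian traits* are simulated by preorder recursion from value 0 at the
origin.  Clade shifts add one shared N(0, sd²) draw to all members of a
clade — the canonical non-Brownian confounder (a singular evolutionary
event, or a shared environmental exposure).

*Coalescent genotypes* (msprime) use independent single-tree loci with
infinite-sites mutations, pairing haploid genomes sequentially into
diploids within populations.  Independent loci stand in for the
high-recombination regime: they isolate the effect of population structure
from linkage, which is exactly the regime the experiments are about.
Real genomes have LD; nothing here speaks to LD-induced confounding,
LD-aware GRMs, or local ancestry.  Default scale: diploid size N = 10,000
per branch, 1,000 loci at a per-locus mutation rate of 1e−5 per
generation, giving on the order of 2,000 segregating causal variants per
replicate; the GWAS experiment drivers use 500 loci at 1e−4 (≈ 10,000
causal variants) as their scaled-down default.  Heritability defaults to
0.5; environmental noise is iid with variance Var(A)(1−h²)/h².
Environmental-shift grids in the GWAS drivers are expressed in units of
the replicate's pre-shift phenotypic SD, because the absolute trait scale
varies with the random number of causal variants; phylogenetic shift grids
are absolute (the Brownian trait scale is O(1) at rate 1).  The tested
variant is always drawn from an independently simulated region (frequency
> 0.1) and never enters Σ.

*Coevolution fixture.*  Truly coevolving pairs follow a bivariate Brownian
motion with correlation ρ on disjoint gene pairs; a fraction of genes
receive a clade shift (independent draws per gene); entries are knocked
out at random, never leaving a gene below the observation floor.  The
species-tree helper draws pure-birth trees until the root split is
reasonably balanced (smaller clade ≥ 30% of tips) and strips the stem —
a clade shift on a 95%-clade is just a global constant, which the
intercept absorbs, and is not the confounding regime of interest.  Passing
tests on this fixture show that the screen behaves as the theory predicts
when the confounder is a clade-level shift; real expression data violate
Brownian assumptions in richer ways (measurement error, expression-level
dependence, non-Gaussian tails) that the fixture does not emulate.

## Experiments

False-positive rates are fractions of null replicates with p < 0.05.
Replicate rngs derive from (master seed, cell index, replicate index), so
tables are bit-reproducible and independent of execution order.  Default
replicate counts are 1,000 (phylogenetic) and 500 (GWAS); the drivers'
problem sizes (two 100-tip clades; 50–100 diploids per population; 300–500
loci) are the package's desk-scale defaults.  In the two-clade design the
per-replicate p-values of OLS+eig1 and GLS+eig1 coincide (to numerical
precision): the two clade dimensions are spanned by the intercept and the
first eigenvector, and the remaining spectrum is flat, so weighting has
nothing left to reweight.

## Coevolution screen

For each unordered gene pair jointly observed in ≥ min_species species
(default 15), the tree is pruned to the joint species set, the subtree vcv
is eigendecomposed, and the lexicographically smaller gene is regressed on
the larger plus the top-J subtree eigenvectors under PGLS (σ_E² = 0).  The
bivariate-Brownian formulation of coevolution is symmetric; a regression
is not, so the orientation is fixed by gene id and stated here.  BH FDR at
q = 0.05 is applied separately within each J.  Enrichment of an annotated
pair set is defined as f(J)/f(0), where f is the annotated fraction of
discoveries; the definition is isolated in `screen_summary` and
configurable via its inputs.

## Numerical choices and degenerate inputs

Ultrametricity is judged at 1e−9 relative tolerance; Newick round-trips
use `repr` floats (exact); zero-length terminal branches are legal;
negative lengths are not.  Rank deficiency raises with the offending
columns named.  Association tests require J < n − 2.  msprime population
splits at exactly the sampling time (a zero-length terminal branch in a
population tree) are floored at 1e−6 generations.  BH on an empty p-value
vector returns an empty mask; summaries report undefined ratios as NaN
rather than guessing.

## Known limitations

No Ornstein–Uhlenbeck or other non-Brownian Σ; no Pagel's-λ as a separate
parameter (the σ_G²/σ_E² ratio plays its role); no power analyses under
true effects beyond consistency checks; no LD, selection during
simulation, migration, or growth; kinship is additive-only (no dominance
or epistatic relationship matrices); the coevolution screen fits each pair
independently (no joint multivariate likelihood).
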