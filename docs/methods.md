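# Methods

## Model and rationale

Cross-tissue coexpression mixes two sources: common genetic regulation
(donors who are genetically similar have similar expression in *both*
tissues) and non-genetic signal exchange between tissues. `gdttc` removes
the first with a per-gene mixed-model whitening step and calls edges only on
correlations that survive it.

For one gene's expression vector y over n donors (covariate-adjusted,
scaled to unit sample variance) the model is

    y = β₀·1 + u + ε,   u ~ N(0, h·K),   ε ~ N(0, (1−h)·I),

with K the realized relationship matrix from genome-wide SNPs and h the
pseudo-heritability. The assumptions that matter: expression residuals are
approximately Gaussian after covariate adjustment; the genetic component is
polygenic, i.e. its donor-by-donor covariance is proportional to genome-wide
similarity (the model is not meant to condition on individual eQTLs, which
the whitening approach deliberately avoids as over-fitting-prone); and
donors within a tissue pair overlap enough (≥ 10 shared donors enforced) for
rank correlation to be meaningful.

## Kinship

Two centerings are implemented:

- `standard` (default): K(r,s) = (1/L) Σ_l (g_lr − 2p_l)(g_ls − 2p_l) /
  (2 p_l (1−p_l)) — the VanRaden RRM; diagonal ≈ 1 + F, near 1 for
  unrelated donors.
- `as_printed`: centering by p_l and scaling by p_l(1−p_l). This variant is
  provided for fidelity with analyses that state the formula that way; for
  diploid 0/1/2 coding it leaves a nonzero mean and an inflated diagonal, so
  it is not the default.

p_l is the alternate (coded) allele frequency computed from non-missing
entries; missing genotypes are mean-imputed, monomorphic SNPs dropped, and
at least 10 polymorphic SNPs are required. Both Gram forms are positive
semi-definite up to round-off; a diagonal jitter of 1e-8 is applied only if
an eigenvalue falls below −1e-10, and eigenvalues are clipped at zero.
K is eigendecomposed once per donor set and the decomposition is shared by
every gene of the tissue.

## Pseudo-heritability estimation

The likelihood is evaluated in the eigenbasis of K, where the covariance is
diagonal: d_j(h) = h·λ_j + (1−h). The covariance is parameterized as
σ²·(h·K + (1−h)·I) with the scale σ² profiled out analytically and h the
variance *fraction* — the parameterization used by FaST-LMM-style spectral
solvers. Although expression is standardized to unit sample variance, the
free scale matters: pinning σ² = 1 leaks the kinship-inflated part of the
sample variance into the likelihood and biases ĥ downward by ~0.05–0.1 in
family cohorts, which the profiled form avoids.

The criterion is REML by default (ML by flag). The optimizer is a dense grid
over [0, 1−1e−6] at step 0.01 — vectorized across all genes of a tissue —
followed by bounded scalar refinement in the bracketing interval
(tolerance 1e−8). Ties are broken toward h = 0 (within 1e−9 log-likelihood),
so a flat likelihood — e.g. K = I, where h is unidentifiable — yields the
no-transformation solution. The refined optimum is never allowed to fall
below the best grid value.

Identifiability depends on the spread of K's eigenvalue spectrum: with a
flat spectrum (truly unrelated donors, very many independent markers) ĥ has
large variance at n in the low hundreds; family structure and a realistic
effective number of independent loci concentrate it. The recovery
experiments therefore use family cohorts (see study conditions below).

## Whitening transform

Given ĥ, the transform must satisfy D·(ĥK + (1−ĥ)I)·Dᵀ = I. Two forms:

- `symmetric_sqrt` (default): D = U (ĥS + (1−ĥ)I)^(−1/2) Uᵀ. At ĥ = 0 it is
  exactly the identity (unheritable genes untouched) and transformed vectors
  keep their donor coordinates.
- `rotation`: D = (ĥS + (1−ĥ)I)^(−1/2) Uᵀ, the eigenbasis form.

The two differ by the orthonormal factor U, so inner products, norms and
hence uncentered (cosine) correlations between transformed vectors coincide
exactly; *rank*-based correlations do not, because ranks are not preserved
under rotation. The form is therefore a fixed, recorded configuration
choice per run, defaulting to the symmetric square root. Application is
O(n²) per gene via the shared eigenbasis (rotate once, rescale per gene
with its own ĥ, rotate back).

What whitening can and cannot remove: it cancels covariance *structure*
induced by kinship — correlations that exist because genetically similar
donors co-vary — and strongly attenuates cross-tissue correlations carried
by polygenic components aligned with K's leading eigendirections. It cannot
cancel a shared realized factor that lies in the flat part of the spectrum;
with moderate heritability that residue falls below the significance
thresholds, which is exactly the regime the diagnostics test.

## Edge calling, p-values and FDR

Spearman's ρ is the Pearson correlation of average ranks, tested with
t = r√((n−2)/(1−r²)) against t(n−2), two-sided; |r| = 1 maps to p = 0 by
convention, and |r| within 1e−12 of 1 is snapped to ±1 to absorb float
noise on perfectly monotone pairs. The t approximation is mildly
anticonservative in the far tail (measured factor ≈ 1.1 at p ≈ 10⁻³·⁵,
n ≈ 100), which the null-calibration test budgets for within its binomial
band.

A pair is an edge iff p_decorrelated < 10⁻³ **and** p_original < 10⁻³·⁵,
both strict, with 10⁻³·⁵ evaluated exactly. Both tests use the same n — the
shared-donor count of the tissue pair — keeping the two p-values
comparable. Genes with a missing value or constant ranks over the shared
donors are dropped for that pair. Edge calling is symmetric in tissue
order.

Permutation FDR: tissue B's donor labels are permuted (breaking both the
cross-tissue pairing and the genotype alignment, while preserving B's
within-tissue structure), heritabilities and transforms are re-estimated on
the permuted data, edges re-called; with the default five permutations the
FDR is the mean of per-permutation ratios permuted/observed. The mean of
ratios (rather than the ratio of means) was chosen so that each permutation
contributes equally; with the observed count fixed the two differ only in
labeling, and the per-permutation counts are reported alongside. An edge
count of zero makes the FDR undefined (reported as NA/NaN).

## Asymmetric gene-to-module detection

For each source gene i in tissue A with module M (its correlated genes in
B), m = |M| ≥ min_size (default 10 — the back-degree rule AM < m/10 is
unsatisfiable for m < 10 given integer back-degrees ≥ 1, since every member
has at least the edge to i itself):

- check 1: AM < m/10, strict, where AM is the mean back-degree of M's
  members into A (the edge back to i counts). At the boundary (m = 10, all
  back-degrees exactly 1) the strict rule rejects; this is intended.
- check 2 (default `reverse_module`): the same gene id, measured as a
  tissue-B gene, must not anchor a reverse module of size ≥ m/10 toward A;
  vacuously true when the gene is absent from B. This guards against
  apparent asymmetry produced by common regulation within one tissue. The
  source sentence defining this check is ambiguous; an alternative
  `within_degree` variant accepts a caller-supplied within-tissue degree
  table instead (within-tissue networks are outside this package's scope).

Module-size significance: with mean cross-tissue degree d̄ (averaged over
*all* tested source-tissue genes, including degree-zero ones), module size
is compared to Binomial(n_B, d̄/n_B); p = P(X ≥ m) by exact tail summation.
Returned modules pass both checks and are sorted by p ascending, ties
broken by m descending then source gene lexicographically — module p is the
only significance the method defines, so "top k" lists rank by it.

The SVD bipartite co-clustering (Dhillon's spectral co-clustering, via
scikit-learn) is included as the balanced-cluster comparator; it seeks
two-sided clusters and is expected to be uninformative on unidirectional
structures — which is the motivation for the detector above.

## Enrichment

One-sided hypergeometric tail p = P(X ≥ overlap) for each gene set against
a module, with the universe defined as the genes retained in the target
tissue after preprocessing (the population actually eligible to enter a
module). Sets are intersected with the universe first; empty intersections
are not tested and do not count toward the Bonferroni denominator, which is
the number of sets actually tested (after any ontology-level filter).
Ontology level is the number of terms on the shortest is_a path from the
namespace root, root = level 1, minimum over paths for multi-parent terms;
only is_a edges are used (part_of ignored), and annotations are not
propagated up the ontology — supply pre-propagated GMTs if that behavior is
wanted. The same operation serves GO, disease-signature and GWAS-catalog
collections; a "Fisher's exact" one-sided test on a 2×2 overlap table is
the identical hypergeometric tail.

## Synthetic cohorts: what they emulate, and what not

The generator produces: SNP dosages with allele frequencies uniform on
[0.05, 0.5] and family structure (each family has two latent parents; donors
inherit one allele per SNP from each, so realized within-family kinship sits
near 0.5 with Mendelian-sampling noise); per-gene expression u + ε with
variance split h vs 1−h and total variance 1 (u = √h·L·z with L the Cholesky
factor of K + 1e−8·I, computed once and shared); per-tissue donor
subsampling to the overlap fraction; and planted non-genetic cross-tissue
modules — a latent factor added to one source gene in tissue 1 and each
target gene in tissue 2, scaled so the expected pairwise correlation equals
`signal_strength` with total variance restored to 1. Optionally the same
realized polygenic draw is shared across tissues per gene
(`share_genetic_across_tissues`), emulating the cis-like genetic
correlation of the same gene measured in two tissues. All randomness flows
from the single config seed; equal configs are bit-identical.

Deliberately *not* emulated: linkage disequilibrium (SNPs are independent,
so `n_snps` plays the role of the number of effectively independent loci;
300 at n = 200 donors reproduces the kinship eigen-spread under which
per-gene ĥ is estimable), read-count noise and zero-inflation (expression
marginals are Gaussian), and eQTL effect-size spectra. Consequently,
passing tests demonstrate the estimator/transform/detector logic under the
stated covariance model, not robustness to count noise or LD structure.

A practical corollary of Gaussian marginals: the low-variance filter
(remove gene iff sd < 0.2·range, plus zero-variance genes, which the
literal rule cannot catch but which break rank correlation) is calibrated
for skewed, zero-inflated abundance data. On Gaussian data the expected
range grows like ~5σ by n ≈ 120, so the 0.2 default trims roughly half the
genes by chance; simulation configs therefore use 0.15 where the filter is
not itself under test. The fraction is a parameter.

## Study conditions used by the test suite and acceptance script

- Whitening contract and Monte-Carlo check: 30 donors, 6 families; every
  constructed D verified to 1e−6; covariance of 2000 transformed draws
  within 0.1 of I in max-norm.
- Heritability recovery: 200 donors, 2 families, 300 effective loci,
  50 genes per true h ∈ {0, 0.4, 0.8}; mean |ĥ − h| < 0.15.
- Spectral vs dense REML: instances with n ≤ 50; agreement within 0.01
  against a direct slogdet/solve implementation of the same criterion.
- Decorrelation specificity: 150 donors, 30 families; shared polygenic
  signal at h = 0.9 attenuated (|ρ| drops) in ≥ 90 of 100 genes; planted
  non-genetic pairs at signal 0.5 survive the dual rule in ≥ 80% of cases.
- Null calibration: 20 cohorts (10 in the faster acceptance script) of
  150 donors × 120 genes per tissue with h = 0 and no signal; pooled dual
  edge count within 3 binomial SD of n_pairs·10⁻³·⁵; permutation-FDR median
  in [0.5, 2].
- Planted gene-to-module recovery: signal 0.5, n = 150; source detected
  with ≥ 80% member overlap.

These sizes were chosen as the smallest cohorts at which the statistical
claims above are stable across seeds.

## Numerical choices

- Eigen-jitter 1e−8, applied only for eigenvalues below −1e−10; eigenvalues
  clipped at 0; transform scales floored at 1e−12 before the inverse square
  root.
- Heritability grid step 0.01 on [0, 1−1e−6]; bounded refinement with
  xatol 1e−8; tie-break to h = 0 within 1e−9 log-likelihood.
- Standard deviations use ddof = 1 throughout (filtering, standardization).
- Floats are serialized with %.10g (round-trip error < 1e−6); p-values in
  reports use 6 significant digits.
- Seeds: one integer seed per run; per-stage seeds are derived
  arithmetically and recorded in the run report, so re-running a config
  reproduces every TSV/JSON byte for byte.

## Limitations

An asymmetric cross-tissue correlation suggests, but does not establish, a
causal–reactive relationship between tissues. The accuracy of D rests on
the accuracy of ĥ, which degrades for small shared-donor counts and flat
kinship spectra; the dual-threshold rule is deliberately conservative for
exactly that reason. The Spearman t approximation is slightly liberal in
the deep tail; applications needing exact tail control at n < 20 should use
permutation p-values. Multi-component variance models, SNP-level eQTL
conditioning and within-tissue network construction are out of scope.
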