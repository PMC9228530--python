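# Methods

This note documents the statistical procedures implemented in `dysbiome`,
the parameters that matter, what the synthetic generators do and do not
emulate, and the design decisions taken where the methodology was open.

## Data model

The central object is a taxa × samples table of non-negative integer
counts; all compositional machinery treats a sample's counts as a noisy
observation of a composition (relative abundances). Counts stay integral
end-to-end; relative-abundance views are derived on demand and never
written back. Sample and taxon order is preserved from input files and
all set operations are order-stable, so identical inputs and seeds give
byte-identical outputs.

## Filtering and rarefaction

Contaminants are taxa whose lineage contains `mitochondri` or
`chloroplast` (case-insensitive substring match; configurable).
Ultra-rare taxa are removed when **either** prevalence < 5 samples **or**
total count < 20 — the union reading, since the two thresholds name two
separate classes of rarity; both thresholds are strict, and an `and` rule
is available. Order is fixed: contaminants → ultra-rare → rarefaction.

Rarefaction draws, per sample, a multivariate hypergeometric subsample of
exactly `depth` reads (default 10,000) — sampling without replacement, as
QIIME-style pipelines do — so the expected rarefied count of taxon *i* is
`depth·cᵢ/total`. Samples shallower than the depth are excluded and
reported with their totals.

## Diversity

* Shannon entropy is computed in log base 2 ("bits"); Pielou divides by
  log₂ of the observed richness and is therefore base-free.
* Faith's PD includes the path to the root (the minimal rooted subtree).
* Jaccard is computed on presence/absence of the (rarefied) table;
  Bray–Curtis on counts.
* Weighted UniFrac is the **raw** (unnormalised) variant by default, the
  common default in amplicon pipelines; the normalised variant is a flag.
  Both UniFrac variants are validated against an independent per-branch
  enumeration oracle on random trees (≤ 8 leaves) to 1e-9.
* Kruskal–Wallis (alpha) and PERMANOVA (beta, pseudo-F with permutation
  p = (1 + #{F\* ≥ F})/(1 + N), so p is never exactly 0) are each
  BH-corrected within their own four-metric family, mirroring the usual
  reporting of four alpha and four beta metrics.
* PCoA uses Gower double-centering with an `eigh` decomposition; negative
  eigenvalues are reported but excluded from the proportion-explained
  denominator, and no correction is applied by default.

## Differential abundance

All selectors run on the filtered, unrarefied table with pseudocount 1
before log-ratio formation.

**ANCOM.** For taxon *i*, the m−1 additive log-ratios against every other
taxon are tested between groups with two-sided Mann–Whitney; p-values are
BH-adjusted *within taxon i's family*; Wᵢ counts rejections at α = 0.05.
Detection uses the customary heuristic Wᵢ ≥ 0.7·(m−1); the raw W is
always emitted because thresholds vary across practice. Direction of
enrichment is the sign of the between-group CLR mean difference. W is
exactly invariant to scaling any sample's counts when the pseudocount is
scaled along (matched-scale compositional invariance).

**CLR-lasso.** L1-penalised logistic regression on CLR-transformed
abundances. The penalty is the weakest value on a decreasing grid whose
fit keeps ≤ `max_taxa` (default 20) nonzero coefficients — the "at most
20 discriminant taxa" instruction read as a per-method cap.

**Coda-lasso.** The log-contrast formulation: L1-penalised logistic
regression on log abundances under the exact zero-sum constraint on the
coefficient vector. Solved by FISTA where the proximal step — the prox of
λ‖·‖₁ restricted to the zero-sum hyperplane — is computed exactly by
bisection on the soft-threshold shift (the shrunken sum is continuous and
monotone in the shift). Warm starts along the penalty grid.

**Selbal.** Greedy forward search over two-part balances
B = √(k_N·k_D/(k_N+k_D)) · (mean log numerator − mean log denominator),
which is scale-invariant in the counts. The search starts from the best
single pair and adds the taxon (to either side) that most improves the
fold-averaged held-out AUC of the balance (the balance has no fitted
parameters, so cross-validation reduces to evaluating the fixed score on
held-out folds); it stops at `max_taxa` taxa or when no candidate
improves the score by `min_improvement` (0.005). Ties break toward the
lowest taxon index for determinism. Because the greedy search consults
the same score it maximises, the *reported* discrimination score is
computed selection-bias-free: the greedy is re-run on a stratified half
of the samples and the resulting fixed balance scored by AUC on the
other half. On signal-free data this score hovers near 0.5 and the
search terminates early.

**Consensus** tallies which methods selected each taxon, with direction;
taxa can be collapsed by a lineage prefix at a chosen rank (1 = kingdom
… 7 = species) when counting distinct taxonomies per direction.

## Pathway effect sizes

For a feature × sample count table, each Monte-Carlo instance draws every
sample's composition from Dirichlet(counts + 0.5) and CLR-transforms it
(per-sample CLR values sum to zero by construction). Per instance, a
random between-group pairing (min(n₁,n₂) pairs) gives the between-group
CLR difference per feature; within each group a random cyclic pairing of
distinct samples gives within-group differences, and the denominator is
the elementwise maximum of the two groups' absolute within-differences.
The effect is the median of ratio over instances × pairings (default 128
instances), signed group2 − group1 in declared level order; reversing the
level order negates every effect exactly, because pairings are drawn per
sample set rather than per label. Features are classified at the
|effect| ≥ 0.5 / 1 / 1.5 ladder (classes nested by construction). Note
that the effect measures the *observed cohort* difference: in finite
cohorts a null feature has a nonzero effect of order (group-mean
sampling error)/(within-spread), which is why null calibration is stated
as "≥ 95% of null features below 0.5" rather than all.

## Dysbiosis statistics

All three tests share a healthy reference set and Bray–Curtis distances.

**Median-distance test.** A test sample's statistic is its median
distance to all reference samples. The cutoff is the 90% linear-
interpolation quantile of the *reference samples' own leave-one-out
median distances* — the same functional as the test statistic — so by
construction ~10% of reference samples self-flag, giving the test a
built-in calibration check. The pooled-pairwise-distance cutoff (an
alternative reading of "the distance distribution within the reference
set") is available behind a flag.

**Dissimilarity–overlap curve (DOC).** For each sample pair, with S the
taxa present in both: overlap O = ½·Σ_{i∈S}(xᵢ+yᵢ) (shared abundance
mass) and dissimilarity D = the root Jensen–Shannon divergence (natural
log, so D ∈ [0, √log 2]) of the two compositions renormalised over S.
A LOWESS fit summarises the curve; the slope (linear fit) and Spearman
correlation are computed in the high-overlap region, by default pairs
above the median overlap. The region statistic is smoother-free on
purpose, since the choice of smoother is not part of the method's
signature. The bootstrap resamples *samples* (not pairs), preserving the
dependence between pairs sharing a sample; duplicated-sample self-pairs
are dropped.

**CLOUD.** For a random subset of the reference (fraction 0.05/0.15/0.30
of it per draw, 100 draws): the test sample's neighbourhood diameter is
its mean distance to its k nearest subset members (k defaults to
⌈0.05·|reference|⌉, at least 3), and r is that diameter divided by the
subset members' average leave-one-out analogue; reported r is the mean
over draws. The empirical p is the +1-corrected fraction of reference
samples — each scored identically against the remaining reference —
with r at least the test sample's. r = 1 exactly when all distances are
equal, and reference leave-one-out scores average ≈ 1.

## Synthetic cohorts

The generator emulates the statistical structure of a stool 16S cohort,
not its biology:

* **Counts** are Dirichlet-multinomial: a heavy-tailed (log-normal
  ranked-abundance) base composition scaled to a total concentration of
  50 gives the overdispersion and sparsity typical of stool profiles;
  sparsity arises from small per-taxon concentrations rather than
  structural zeros, which keeps log-ratio machinery well defined after
  pseudocounting.
* **Depths** are log-normal with median 16,841 reads and σ = 0.42 chosen
  so the quartile ratio matches an interquartile range of 13,210–23,273;
  ~10% of samples fall below 10,000 reads and exercise rarefaction
  exclusion.
* **Planted effects** multiply a taxon's Dirichlet weight by 2^lfc in one
  group; a 4-fold planting is recovered as a ≈ 4× group mean
  relative-abundance ratio at large n.
* **Planted outliers** redraw a sample from a permuted concentration
  divided by a strength factor, preserving its depth — large strength
  moves the sample far from the cohort in Bray–Curtis space.
* **Universal dynamics** cohorts share one steady-state abundance vector;
  each sample's disturbance level jointly lowers its taxon carriage and
  inflates its multiplicative log-normal noise, which is the mechanism
  that produces the negative dissimilarity–overlap slope at high
  overlap. With `universal=False` each sample draws an independent
  steady state and the curve is flat.
* **Pathway tables** are log-normal abundances (within-group SD 0.5 on
  the log scale) with multinomial sampling; planted effects shift the
  log abundance by a stated number of within-group SDs in one group.

What the generators do **not** emulate: taxon–taxon correlation beyond
the compositional constraint, phylogenetic signal in abundances (the
random tree is independent of the planted effects), batch effects, or
zero-inflation beyond the Dirichlet-multinomial's own sparsity. Passing
tests therefore demonstrate correctness and calibration of the
statistics under a standard microbiome null, not robustness to every
real-data pathology.

## Numerical choices and degenerate inputs

* Quantiles use linear (type-7) interpolation.
* Permutation p-values use the +1 correction.
* Missing Newick branch lengths default to 0 with a logged warning;
  negative lengths are rejected.
* Distance matrices read from disk are symmetrised when asymmetry is
  ≤ 1e-9 and rejected beyond.
* All-zero features are excluded (with a warning) before effect
  computation; samples with zero totals are an error in any
  relative-abundance context.
* The FISTA solver stops at a 1e-7 coefficient change or 400 iterations;
  coefficients below 1e-9 are treated as zero and the zero-sum identity
  is re-imposed exactly on the survivors.

## Problem sizes used in the test suite

The acceptance checks run at cohort scale chosen to keep the whole suite
desk-scale while leaving the statistics meaningful: 500 replicates of
30+30 samples × 50 taxa for type-I calibration (999 permutations), 50
replicates of 30+30 × 20 taxa at fixed depth 10⁴ for planted-taxon power,
200 random trees for the UniFrac oracle, 20 seeds × 50 samples for the
DOC behaviour, and 20 replicates of 200 pathways × 20+20 samples at 128
Monte-Carlo instances for effect recovery.

## Known limitations

* The coda-lasso and CLR-lasso penalty grids are geometric with fixed
  ranges; extremely separable data may select fewer taxa than the cap at
  every grid point.
* selbal's greedy search is a heuristic; it is not guaranteed to find
  the globally best balance, matching the behaviour of the method it
  follows.
* PERMANOVA assumes exchangeability under the null; no strata/covariate
  support.
* The pipeline treats the pathway table as given; no inference of
  functional content from taxa is attempted.
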