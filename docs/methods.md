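# Methods

## Model and score

The object of interest is a massive bicluster: a large gene module *I*
whose members are strongly mutually correlated (positively or negatively)
across a sample subset *J*, against a background where those genes are
unremarkable. Strength is measured by the alpha score — the mean absolute
pairwise Pearson correlation over (*I*, *J*), diagonal included, so
α ∈ (0, 1] and α of a single gene is 1. All correlations and standard
deviations in the package use the sample (n−1) convention. Zero-variance
rows inside a sample subset get correlation 0 to everything (diagonal 1),
so α stays defined; the event is logged.

## Search objective: why sample coherence

The seed search must locate a small sample subset (default 10) for which
the module lights up. The greedy move is a single member/non-member swap,
accepted iff the objective strictly increases, so the trajectory is
monotone and a run is reproducible from its RNG seed.

The objective is the mean absolute correlation *between the seed samples
computed across the gene set* — the transpose reading of the same
restricted correlation matrix that defines α. The two readings agree on
what a perfect bicluster looks like, but their search behavior differs
sharply at small seed sizes. Gene–gene α at |J| = 10 has a null floor of
E|r| ≈ √(2/9π) ≈ 0.27 and saturates once two or three strong-factor
samples are in the seed (the extra factor variance stops moving |r|,
which is scale-invariant), so a hill-climb gains more by overfitting the
~0.27 noise sea of gene pairs than by completing the true sample subset:
in simulation it stalls at 40–60% overlap with a planted block.
Sample-coherence averages over all genes instead, has a null floor of
E|r| ≈ √(2/π(G−1)) (≈ 0.04 at 500 genes), and rewards every additional
true sample quadratically (each new member adds high-|r| pairs with every
member already in). At the package's reference recovery condition it
reaches 100% seed overlap. The gene–gene α of the found seed is still
computed and reported on every `SeedState` (field `alpha`); the trajectory
records the search objective.

## Extension

* **Gene purification.** Average-linkage clustering on 1 − |C| over the
  seed samples; every clade of the dendrogram is a candidate (the root is
  the full set). The winner maximizes `size × (internal α − E|r|₀)`,
  where E|r|₀ is the null mean |correlation| at the seed size. The size
  weighting matters: at 10 samples a ~15-gene cluster of chance-correlated
  noise genes can have internal α near 1 and would hijack PC1 if raw α
  were maximized. Clusters below 10 genes are used only when nothing
  larger exists; if the winner's α falls below the full set's, the full
  set is returned, so purification never reduces α.
* **PC1 and projection.** Loadings are the unit-norm leading left singular
  vector of the seed-centered submatrix (sign fixed so the largest-|loading|
  gene is positive). All samples are scored by projecting their gene-set
  profile centered on the *full-cohort* gene means (zero on a normalized
  matrix). Centering on seed means would shift every score by the seed's
  latent-factor mean and move the fork boundary off the cohort zero,
  costing ~10% fork/factor-sign agreement in simulation.
* **Membership threshold.** Samples sorted by decreasing |PC1|; the
  trailing ⌈background_fraction·n⌉ (default 10%) are assumed outside the
  bicluster, and membership requires |PC1| strictly above the background
  maximum. Ties in |PC1| break by input order; a fraction rounding to zero
  samples is raised to one, logged.
* **CV and alignment.** CV(g) = Pearson r between gene g and the PC1 score
  over member samples, for every gene (constant genes → 0, logged). If
  fewer than 3 members exist the CV falls back to the seed samples with a
  warning. If the largest-|CV| gene is negative, all signs (loadings,
  scores, CV) flip; fork labels (upper ⇔ PC1 > 0; exact 0 → lower) are
  recomputed. Alignment is idempotent and makes sign-flipped input data
  yield identical CV vectors.

## Consensus

Runs are compared by |Pearson r| of their CV vectors (absolute value
because a bicluster and its global sign flip are the same object; a
constant CV gets similarity 0, logged). Average-linkage clustering on
1 − similarity is cut at each K = 2..max_k (default 20); the silhouette
width s(i) = (b−a)/max(a,b) is computed per run with the singleton-cluster
convention s = 0, and the chosen K maximizes the mean width, smallest K on
ties (parsimony). One representative per final cluster is the member run
with the highest α.

## Gene-set statistics

* Over-representation: one-sided hypergeometric upper tail on the overlap
  between a term and the genes with |CV| ≥ 0.5 (threshold configurable —
  the membership rule for "bicluster genes" is a free choice); Bonferroni
  over the terms actually tested; each term carries its average CV, whose
  sign labels the term co- or anti-regulated with the module.
* GSEA: genes ranked by CV descending, weights |CV| (weight exponent 1).
  Hits advance the running sum by weight/Σ(term weights), misses retreat
  by 1/(N − term size); ES is the running-sum value at maximum absolute
  deviation, clipped to [−1, 1] against accumulated rounding. Significance
  by gene-label permutation (the input is a single ranked list, so
  phenotype permutation is unavailable): p is the same-sign tail fraction
  floored at 1/(n_perm+1), NES divides ES by the mean same-sign null |ES|,
  and the single-term FDR q reduces to the tail fraction on the NES scale,
  clipped to [0, 1]. Decoy calibration sits at ~5% rejections at the 0.05
  level with 200 permutations.

## Differential and clinical statistics

Mann–Whitney U, two-sided (the method reports both over- and
under-expressed genes), midrank ties; exact enumeration when both groups
have ≤ 8 tie-free observations, otherwise normal approximation with tie
and continuity corrections (scipy backend). No multiple-testing correction
at the per-cohort stage — robustness comes from requiring p ≤ α in at
least `min_cohorts` cohorts (default 2; genes untested in a cohort never
count). Fork × clinical tables drop unannotated samples (counted),
require ≥ 2 categories, and report per-fork percentages to one decimal.

## Synthetic data

`simulate_matrix` plants rank-1 blocks on the normalized scale:
background N(0, σ²), block entries += λ·w_g·f_j with loadings w ∈ {±1}
(default half negative) and factor f ~ N(0, 1) per block sample. Defaults
follow the reference recovery condition used throughout the tests:
λ = 3–5 in noise-sd units, blocks disjoint in genes and samples. The
raw-scale map x_raw = 10^(x/6 + 4) keeps every value above the expression
filter floor (dynamic range chosen so even λ·|f| excursions of ~20 sd
survive); genes meant to exercise the filter get one value set below it
explicitly. Because correlation statistics are invariant to the per-gene
affine map, filter + log₁₀ + z-score round-trips exactly to the model.
`simulate_clinical` labels block samples by factor sign with a
configurable association probability (background uniform);
`simulate_genesets` emits the block's negative- and positive-loading genes
as planted sets plus uniform decoys, in GMT.

What the generator does *not* emulate: count noise (negative binomial),
library-size and batch effects, overlapping modules (available behind an
explicit flag but untested), and correlated background genes. Passing
recovery tests therefore show the algorithm is correct under its own
model, not that any particular real cohort contains such modules.

## Problem sizes and reproducibility

Tests and the acceptance script use scaled study conditions chosen to
exercise every stage: recovery at 500 genes × 200 samples with one
100 × 40 block (λ/σ = 3, 10-sample seed, 500 iterations, 10 replicates);
consensus at 240 × 160 with two or three 60 × 40 blocks (λ = 4, 30 cycles,
300 iterations/cycle); calibration with 2000 null U tests (n = 20/group)
and 400 decoy GSEA terms at 200 permutations. One integer seeds every
simulation; per-cycle sub-seeds are derived as seed + cycle index (mod
2³¹), so any cycle can be reproduced in isolation.

## Known limitations

* The greedy search can freeze on a noise-local maximum when the initial
  random seed contains no planted-block sample (measured ~3% of replicates
  at the reference condition); the multi-cycle consensus absorbs such
  failed cycles in practice.
* The membership threshold admits background samples whose |PC1| exceeds
  the background maximum by chance whenever the true block covers much
  less than (1 − background_fraction) of the cohort; CV is robust to this
  dilution but membership lists are liberal.
* The gene-screening rule retains a gene when the fraction of block
  partners with |corr| ≥ ρ reaches q; with a module occupying a small
  fraction of a block, q must be set near that fraction (the rule's
  parameters are exposed precisely because the rule's common verbal description is
  ambiguous).
* GSEA FDR is the single-term reduction; with many terms a pooled-null
  implementation would be preferable.
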