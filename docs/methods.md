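# Methods

## The problem being measured

A 16S-based prediction tool and shotgun metagenome sequencing each yield a
genes × samples table of KO relative abundances for the same study. Two
questions are separated deliberately:

1. **Composition accuracy** — does the predicted abundance vector of a
   sample rank genes the way the sequenced one does?
2. **Inference accuracy** — if both tables are used to test which genes
   differ between the study's two groups, do they reach the same
   conclusions?

Microbial functional profiles have low between-sample variance: most of a
KO table is a shared "core" profile. Question 1's metric (per-sample
Spearman rho) is therefore dominated by that shared average and barely
responds when each gene's abundances are independently permuted across
samples. Question 2's metric is built to be destroyed by exactly that
permutation, which gives it a usable null.

## Statistics

**Wilcoxon rank-sum P.** Two-sided. For a combined sample of n₁+n₂ ≤ 20
with no ties, the exact null distribution of the Mann–Whitney U statistic
is computed by the standard counting recursion and the two-sided P is
2·min(P(U ≤ u), P(U ≥ u)) capped at 1 — identical to scipy's and R's exact
convention (verified against `scipy.stats.mannwhitneyu` to 1e-12).
Otherwise the tie-corrected normal approximation with continuity
correction 0.5 is used, again matching scipy to 1e-12. The switch point 20
keeps the exact path cheap while covering the 5-per-group subsampled design
exactly. P values are floored at 1e-300; a gene constant across all
samples gets P = 1. Known limitation: the normal approximation is only
moderately accurate at very small n — its worst-case deviation from the
exact two-sided P over all tie-free splits is 0.088 at n₁=n₂=2, 0.038 at
3, 0.031 at 4, 0.017 at 5 and 0.016 at 6 — so the exact path is always
used where it applies.

**Signed transform.** p_t = log10(P) × sign(mean₁ − mean₂), implemented
verbatim with sign(0) = 0 (a gene with exactly equal group means carries no
direction). Under this convention strongly significant genes that are
higher in group 1 get large *negative* p_t; since the concordance
correlation is invariant to flipping both vectors' signs consistently, the
choice does not affect any result, but it is stated here because plots of
the flipped variant (−log10 P) look more intuitive. Raw P values are used
as statistics, never as discovery thresholds, so no multiple-testing
correction is applied — applying one would only transform both vectors
monotonically anyway.

**Concordance.** Tie-aware (midrank) Spearman rho of (p_t predicted,
p_t observed) over shared genes, with the t-distribution P value. A
constant input vector yields NaN with a warning, never a silent 0. The
scalar entry point wraps `scipy.stats.spearmanr`; the vectorized
column-wise version used inside permutation loops is implemented directly
(midranks + Pearson + t approximation) and is property-tested against
scipy.

**Gene-wise permutation null.** Each gene row of the observed table is
independently assigned a uniform random permutation of its values across
samples; columns are *not* renormalized afterwards, because renormalizing
would change other genes' values and break the per-gene marginal
conservation the control is defined by. Permutations are sampled with
replacement from the permutation group (100 reps by default need not be
distinct). For the composition control the per-sample correlations are
recomputed against the permuted table; for the inference null the whole
observed inference vector is recomputed per permutation.

**Subsampling.** Without replacement, 5 per group by default, 25 repeats
by default (a single draw is reproducible with `n_repeats=1`); both
inference vectors are recomputed on each subsample.

**Category stratification.** One concordance per level-2 functional
category with at least `min_genes` (default 10) shared genes; multi-mapped
genes contribute to every category they map to. Every qualifying category's
rho is computed and stored; a `display` flag marks those positive and with
P < 0.05, mirroring the convention of hiding negative or insignificant
bars in stratified summaries.

**Overlap.** "Detected" means abundance > 0 in at least `min_prevalence`
samples (default 1, the most permissive reading). The missed fraction uses
observed detected genes as denominator; the spurious fraction uses the
predicted gene list — two deliberately different denominators matching how
such percentages are quoted.

**PERMANOVA.** SS_total = Σ_{i<j} d²ᵢⱼ/n, SS_within the analogous sum per
group divided by group size, R² = SS_between/SS_total, pseudo-F with
(1, n−2) degrees of freedom for the two-group case, P by label permutation
(999 by default, seeded; P = (1 + #{F* ≥ F})/(1 + B)). Bray–Curtis
(1 − 2Σmin/Σtotal) is the default distance, Euclidean is available — under
Euclidean the partition reduces to the classical ANOVA identity, which the
tests exploit as a cross-check alongside exhaustive label enumeration at
n = 8 and a pseudo-F comparison against scikit-bio.

## Alignment and normalization choices

`normalize` scales each sample column to sum to one and rejects all-zero
samples. `align_pair` restricts both tables to the shared samples but
records the shared detected-gene list *without* renormalizing either table
over it: each method's composition is compared as that method produced it,
and gene restriction happens at statistic time. Inputs may be raw counts
or proportions; rank-based tests are invariant to per-gene monotone
scaling, but per-sample renormalization over differing gene sets is not
neutral, so the pipeline normalizes by default and exposes
`normalize_inputs=False` for count-scale runs.

## The synthetic generator

`generate_paired_study` emulates the structure the analysis assumes, not
any particular sequencing technology:

- **Baselines**: per-gene lognormal with log-sd `baseline_sigma` = 1.5, a
  heavy right tail so a few KOs dominate composition as in real tables.
- **Between-sample variation**: unit-mean multiplicative lognormal noise
  with coefficient of variation `between_sample_cv` (default 0.3 — low,
  the regime real functional profiles occupy).
- **Group effect**: `n_differential` genes (default 200 of 2000) carry a
  multiplicative `effect_fold` (default 3) in one group; direction ±1 is
  random per gene and recorded in the truth table.
- **Prediction**: starts from the *realized* observed values (both methods
  measure the same samples), removes the effect from the non-mirrored
  share of differential genes — `concordance` (default 0.8) is the
  mirrored fraction, overridable per level-2 category — then applies
  multiplicative lognormal noise of log-sd `noise_sd` (default 0.3),
  deletes a `miss_fraction` (default 0.3) of genes and appends spurious
  genes sized so that `spurious_fraction` (default 0.3) of the final
  predicted list is spurious. The default overlap fractions sit in the
  range reported for real human-gut and animal studies.
- **Hierarchy**: each gene gets exactly one level-2 category, assigned
  round-robin over eight KEGG-style categories spanning three level-1
  groups. Real KOs multi-map; single mapping keeps the truth record
  unambiguous while exercising stratification (multi-mapping is tested
  through `tables_io` directly).
- **Determinism**: one `numpy.random.default_rng` (PCG64) stream, draw
  order documented in the generator docstring; a seed fully determines
  every output file byte-for-byte.

What the generator does *not* emulate — sequencing-depth count noise,
compositional closure artifacts, phylogenetically structured prediction
error, multi-mapped KOs, uneven category sizes — bounds what passing tests
show: they validate the statistical machinery and its documented
sensitivities, not any claim about a specific real tool's accuracy.

## Problem sizes and tolerances

The test and reproduction workloads use 2,000 genes × 40 samples with 100
permutations for the permutation contrasts, five seeds per point on the
concordance-recovery grid {0, 0.25, 0.5, 0.75, 1}, ten seeds for the
category-ordering check (high 0.95 vs low 0.2 around a 0.5 background),
25 subsample draws of 5 per group, and 200 null simulations × 199
permutations for PERMANOVA type-I calibration — sizes at which the checked
contrasts are far larger than their Monte-Carlo error while the whole
suite runs in well under a minute. The composition contrast uses
`between_sample_cv` = 0.02 ("flat", where the real-vs-permuted gap should
vanish) and 2.0 ("variable", where it should exceed 0.2), with prediction
noise 0.1 so the composition signal itself stays strong. Floating
comparisons use absolute tolerance 1e-9 unless a test states otherwise;
frozen oracle values are asserted at 1e-12.

## Degenerate inputs and tie-breaks

All-zero sample columns are rejected by name at normalization; all-zero
genes are simply never "detected". Ties in abundance (ubiquitous zeros)
take midranks everywhere; genes zero in both methods for a sample are
retained in per-sample correlations as tied ranks, since dropping them is
an undocumented filter. Constant vectors yield NaN correlations with a
warning. `sign(0) = 0` resolves directionless genes. The PERMANOVA
pseudo-F is +inf when SS_within = 0; permutation comparisons handle it via
`>=`.
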