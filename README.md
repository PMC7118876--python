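# metaconcord

Inference-based evaluation of predicted metagenome functional profiles.

Tools such as PICRUSt, PICRUSt2 and Tax4Fun predict a microbial community's
functional-gene profile (KO abundances) from its 16S rRNA taxonomic
composition. How good are those predictions? The conventional answer — the
per-sample Spearman correlation between predicted and shotgun-sequenced
gene relative abundances — is misleading: microbial functional profiles
vary so little between samples that the correlation stays high even after
every gene's abundances are independently permuted across samples. It
measures the shared *average* profile, not per-sample accuracy.

`metaconcord` implements an alternative, inference-based evaluation for
anyone comparing a predicted KO table against a shotgun-metagenome KO table
for the same samples. For every gene *g* shared by the two tables, a
two-sided Wilcoxon rank-sum test of the study's two-group contrast gives a
P value, transformed to

```
p_t(g) = log10(P_g) × sign(mean_group1(g) − mean_group2(g))
```

so that magnitude encodes evidence and sign encodes direction. The Spearman
correlation ρ of (p_t predicted, p_t observed) across shared genes — the
**inference concordance** — asks whether both methods support the same
differential-abundance conclusions. Unlike the composition correlation, it
collapses to zero under gene-wise permutation, so it has a usable null.

The package provides:

- `tables_io` — typed KO-table / metadata / KEGG-hierarchy TSV I/O,
  normalization, detection rules, gene-set alignment, category aggregation;
- `composition` — per-sample composition correlations and their gene-wise
  permutation control;
- `inference` — Wilcoxon tests (exact for small tie-free samples, tie-
  corrected normal approximation otherwise), the signed transform, the
  inference concordance, its permutation null, subsampling to equal group
  sizes, and level-2 functional-category stratification;
- `overlap` — genes missed by prediction and genes spuriously predicted,
  overall and per category;
- `effect_size` — one-factor PERMANOVA R² on Bray–Curtis distances;
- `synthetic` — a seeded generator of paired predicted/observed studies
  with known truth (differential genes, per-category concordance, missed
  and spurious genes) so every stage is testable without downloads;
- `pipeline` + a thin `metaconcord` CLI (`simulate`, `run`, `compare`).

## Worked example

```python
import numpy as np
from metaconcord import (
    SyntheticConfig, generate_paired_study, align_pair,
    inference_vector, inference_correlation, inference_permutation_null,
)

study = generate_paired_study(SyntheticConfig(
    n_genes=1500, n_samples_per_group=20, n_differential=150,
    effect_fold=3.0, concordance=0.9, noise_sd=0.3, seed=11,
))
pair = align_pair(study.predicted, study.observed)
v_pred = inference_vector(pair.predicted, study.metadata, pair.shared_genes)
v_obs = inference_vector(pair.observed, study.metadata, pair.shared_genes)

real = inference_correlation(v_pred, v_obs)
null = inference_permutation_null(pair, study.metadata, n_permutations=50, seed=7)
null_rhos = np.array([r.rho for r in null])
print(f"inference concordance (rho over {real.n_genes} shared genes): {real.rho:.3f}")
print(f"permutation null: mean {null_rhos.mean():+.4f}, 95th pct {np.quantile(null_rhos, 0.95):.4f}")
```

prints

```
inference concordance (rho over 1050 shared genes): 0.744
permutation null: mean +0.0015, 95th pct 0.0421
```

Here the generator mirrored 90% of the true differential effects in the
predicted table; the measured concordance of 0.744 sits far above the
permutation null, whose spread shows what "no shared inference" looks
like. The `examples/` directory walks through each capability the same
way: the composition-correlation artifact (`01`), this metric and its null
and subsampling behaviour (`02`), category stratification (`03`), and
overlap plus PERMANOVA effect size (`04`). Each script prints the numbers
it computes and one line on what they mean.

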