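"""The inference-concordance metric and its permutation null.

For every gene shared by the predicted and observed tables, a two-group
Wilcoxon test gives a P value, signed by the direction of the group-mean
difference: p_t = log10(P) x sign(mean_group1 - mean_group2).  The Spearman
correlation of these signed values across genes measures whether both
methods support the same differential-abundance conclusions.  Unlike the
composition correlation, this metric collapses to zero under gene-wise
permutation.
"""

import numpy as np

from metaconcord import (
    SyntheticConfig,
    align_pair,
    generate_paired_study,
    inference_correlation,
    inference_permutation_null,
    inference_vector,
    subsample_and_recompute,
)

study = generate_paired_study(
    SyntheticConfig(
        n_genes=1500,
        n_samples_per_group=20,
        n_differential=150,
        effect_fold=3.0,
        concordance=0.9,  # 90% of true effects survive in the prediction
        noise_sd=0.3,
        seed=11,
    )
)
pair = align_pair(study.predicted, study.observed)
v_pred = inference_vector(pair.predicted, study.metadata, pair.shared_genes)
v_obs = inference_vector(pair.observed, study.metadata, pair.shared_genes)

real = inference_correlation(v_pred, v_obs)
print(f"inference concordance (rho over {real.n_genes} shared genes): {real.rho:.3f}")

null = inference_permutation_null(pair, study.metadata, n_permutations=50, seed=7)
null_rhos = np.array([r.rho for r in null])
print(f"permutation null: mean {null_rhos.mean():+.4f}, 95th pct {np.quantile(null_rhos, 0.95):.4f}")

subs = subsample_and_recompute(pair, study.metadata, per_group=5, n_repeats=25, seed=13)
print(f"subsampled to 5/group (25 draws): mean rho {np.mean([r.rho for r in subs]):.3f}")

print(
    "\nThe real concordance sits far outside its permutation null, and"
    "\nsurvives subsampling to 5 samples per group - so differences between"
    "\nstudies are not mere sample-size artifacts."
)
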