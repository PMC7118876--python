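"""Distance-based effect size: one-factor PERMANOVA R² on Bray-Curtis.

R² = SS_between / SS_total of the distance-based sum-of-squares partition
measures how much of the between-sample dissimilarity the two-level group
factor explains; the permutation P value shuffles group labels.  Euclidean
distance is also supported, under which the partition reduces to the
classical ANOVA identity — a useful cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .tables_io import GeneTable, StudyMetadata

__all__ = ["EffectSizeResult", "bray_curtis_matrix", "permanova_r2"]


@dataclass(frozen=True)
class EffectSizeResult:
    r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "r_squared": self.r_squared,
                    "pseudo_f": self.pseudo_f,
                    "p_value": self.p_value,
                    "n_permutations": self.n_permutations,
                }
            ]
        )


def bray_curtis_matrix(table: GeneTable, metric: str = "braycurtis") -> pd.DataFrame:
    """Symmetric sample × sample distance matrix.

    Bray-Curtis d(i,j) = 1 − 2·Σ_g min(x_gi, x_gj) / Σ_g (x_gi + x_gj) by
    default; ``metric`` accepts any scipy pdist metric (e.g. "euclidean").
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    d = squareform(pdist(table.values.T, metric=metric))
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


def _ss_partition(
    d2: np.ndarray, group_indices: list[np.ndarray]
) -> tuple[float, float, float]:
    """(SS_total, SS_within, SS_between) from a squared-distance matrix."""
    n = d2.shape[0]
    ss_total = d2.sum() / 2.0 / n
    ss_within = 0.0
    for idx in group_indices:
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub.sum() / 2.0 / idx.size
    return ss_total, ss_within, ss_total - ss_within


def permanova_r2(
    distances: pd.DataFrame,
    metadata: StudyMetadata,
    n_permutations: int = 999,
    seed: int | None = None,
) -> EffectSizeResult:
    """One-factor PERMANOVA for a two-level group factor.

    SS_total = Σ_{i<j} d²_ij / n; SS_within sums the analogous term within
    each group; R² = SS_between / SS_total; pseudo-F uses (a−1, n−a)
    degrees of freedom with a = 2 groups.  The P value is the fraction of
    label permutations (plus the observed one) with pseudo-F at least as
    large as observed.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    samples = distances.index.tolist()
    if distances.columns.tolist() != samples:
        raise ValueError("distance matrix index and columns must match")
    d2 = distances.to_numpy(dtype=float) ** 2
    labels = np.array([metadata.group_of(s) for s in samples])
    a = 2
    n = len(samples)
    group_idx = [np.flatnonzero(labels == g) for g in metadata.group_labels]
    for g, idx in zip(metadata.group_labels, group_idx):
        if idx.size < 2:
            raise ValueError(f"group {g!r} needs at least 2 samples")

    def pseudo_f(group_indices) -> tuple[float, float]:
        ss_total, ss_within, ss_between = _ss_partition(d2, group_indices)
        if ss_within == 0.0:
            return np.inf, (1.0 if ss_between > 0 else 0.0)
        f = (ss_between / (a - 1)) / (ss_within / (n - a))
        r2 = ss_between / ss_total if ss_total > 0 else 0.0
        return f, float(np.clip(r2, 0.0, 1.0))

    f_obs, r2_obs = pseudo_f(group_idx)

    rng = np.random.default_rng(seed)
    n1 = group_idx[0].size
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        f_k, _ = pseudo_f([perm[:n1], perm[n1:]])
        if f_k >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return EffectSizeResult(
        r_squared=float(r2_obs),
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )
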