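"""Inference concordance: the signed-log10-P agreement between two methods.

The core statistic: for every gene shared by a predicted and an observed
table, a two-sided Wilcoxon rank-sum test of the two-group contrast gives a
P value, transformed to

    p_t = log10(P) × sign(mean_group1 − mean_group2)

so that magnitude encodes evidence and sign encodes direction.  The Spearman
correlation of (p_t_predicted, p_t_observed) across shared genes is the
inference concordance — a measure of whether the prediction tool supports
the same biological conclusions as shotgun sequencing, not merely the same
average composition.  A gene-wise permutation of the observed table supplies
its null distribution; subsampling and level-2 category stratification probe
sample-size sensitivity and functional heterogeneity.

The Wilcoxon P uses the exact rank-sum distribution when the combined sample
is tie-free with n1+n2 ≤ 20 (covering the 5-per-group subsampled design
exactly), and the tie-corrected normal approximation with continuity
correction otherwise.  Raw P values are used as statistics throughout — no
multiple-testing correction, since they feed a correlation, not a discovery
threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .composition import permute_genes_across_samples, spearman
from .tables_io import AlignedPair, FunctionalHierarchy, GeneTable, StudyMetadata

__all__ = [
    "InferenceVector",
    "ConcordanceResult",
    "wilcoxon_rank_sum",
    "signed_log10_p",
    "inference_vector",
    "inference_correlation",
    "inference_permutation_null",
    "subsample_and_recompute",
    "category_inference_correlations",
    "read_inference_tsv",
]

logger = logging.getLogger(__name__)

#: smallest reportable P value
P_FLOOR = 1e-300

#: exact rank-sum distribution used up to this combined sample size
EXACT_N_MAX = 20


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> np.ndarray:
    """Number of rank assignments per Mann-Whitney U value (tie-free null)."""
    if n1 == 0 or n2 == 0:
        return np.ones(1)
    out = np.zeros(n1 * n2 + 1)
    a = _u_counts(n1 - 1, n2)  # largest rank joins group1: U gains n2
    out[n2 : n2 + a.size] += a
    b = _u_counts(n1, n2 - 1)  # largest rank joins group2
    out[: b.size] += b
    return out


@lru_cache(maxsize=None)
def _exact_two_sided_p(n1: int, n2: int) -> np.ndarray:
    """Two-sided exact P for each U in 0..n1*n2: 2·min(P(U≤u), P(U≥u)), capped at 1."""
    counts = _u_counts(n1, n2)
    total = comb(n1 + n2, n1)
    cdf = np.cumsum(counts) / total
    sf_incl = np.cumsum(counts[::-1])[::-1] / total
    return np.minimum(1.0, 2.0 * np.minimum(cdf, sf_incl))


def _tie_term(values: np.ndarray) -> np.ndarray:
    """Row-wise Σ(t³ − t) over tied groups; 0 marks a tie-free row."""
    m, n = values.shape
    sv = np.sort(values, axis=1)
    new = np.ones((m, n), dtype=bool)
    new[:, 1:] = sv[:, 1:] != sv[:, :-1]
    starts = np.flatnonzero(new.ravel())
    lengths = np.diff(np.append(starts, m * n)).astype(float)
    term = lengths**3 - lengths
    return np.bincount(starts // n, weights=term, minlength=m)


def _rank_sum_p(values: np.ndarray, group1_mask: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Wilcoxon rank-sum P values, one per row.

    Exact path for tie-free rows with n1+n2 ≤ EXACT_N_MAX; tie-corrected
    normal approximation with continuity correction otherwise.  Rows whose
    values are all identical get P = 1.
    """
    values = np.asarray(values, dtype=float)
    group1_mask = np.asarray(group1_mask, dtype=bool)
    n1 = int(group1_mask.sum())
    n2 = int((~group1_mask).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    n = n1 + n2
    if values.shape[1] != n:
        raise ValueError("mask length must match number of columns")

    ranks = stats.rankdata(values, axis=1)
    u1 = ranks[:, group1_mask].sum(axis=1) - n1 * (n1 + 1) / 2.0
    tie = _tie_term(values)

    p = np.empty(values.shape[0])
    exact = (tie == 0) & (n <= EXACT_N_MAX)
    if exact.any():
        table = _exact_two_sided_p(n1, n2)
        p[exact] = table[np.rint(u1[exact]).astype(int)]
    approx = ~exact
    if approx.any():
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie[approx] / (n * (n - 1)))
        sigma = np.sqrt(np.maximum(sigma2, 0.0))
        dev = np.maximum(np.abs(u1[approx] - n1 * n2 / 2.0) - 0.5, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sigma > 0, dev / np.where(sigma > 0, sigma, 1.0), 0.0)
        pa = np.minimum(1.0, 2.0 * stats.norm.sf(z))
        pa[sigma == 0] = 1.0  # every value tied: no evidence either way
        p[approx] = pa
    return np.clip(p, P_FLOOR, 1.0)


def wilcoxon_rank_sum(group1, group2) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) P value for two samples."""
    g1 = np.asarray(group1, dtype=float).ravel()
    g2 = np.asarray(group2, dtype=float).ravel()
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least 2 values")
    values = np.concatenate([g1, g2])[None, :]
    mask = np.zeros(g1.size + g2.size, dtype=bool)
    mask[: g1.size] = True
    return float(_rank_sum_p(values, mask)[0])


def signed_log10_p(p_value: float, mean_group1: float, mean_group2: float) -> float:
    """p_t = log10(P) × sign(mean_group1 − mean_group2), with sign(0) = 0."""
    if not 0.0 < p_value <= 1.0:
        raise ValueError(f"p_value must be in (0, 1], got {p_value}")
    return float(np.log10(p_value) * np.sign(mean_group1 - mean_group2)) + 0.0


# ---------------------------------------------------------------------------
# inference vectors and their concordance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InferenceVector:
    """Per-gene Wilcoxon P values and signed transforms for one table.

    ``group_labels`` records the (group1, group2) ordering the signs refer
    to; P values are two-sided.
    """

    genes: list[str]
    p_value: np.ndarray
    mean_group1: np.ndarray
    mean_group2: np.ndarray
    p_t: np.ndarray
    group_labels: tuple[str, str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.genes,
                "p_value": self.p_value,
                "mean_group1": self.mean_group1,
                "mean_group2": self.mean_group2,
                "p_t": self.p_t,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def subset(self, genes: list[str]) -> "InferenceVector":
        pos = {g: i for i, g in enumerate(self.genes)}
        idx = np.array([pos[g] for g in genes], dtype=int)
        return InferenceVector(
            genes=list(genes),
            p_value=self.p_value[idx],
            mean_group1=self.mean_group1[idx],
            mean_group2=self.mean_group2[idx],
            p_t=self.p_t[idx],
            group_labels=self.group_labels,
        )


def read_inference_tsv(path) -> pd.DataFrame:
    """Read a per-gene inference TSV (gene_id, p_value, ..., p_t) back in."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "p_t"):
        if col not in df.columns:
            raise ValueError(f"inference TSV missing column {col!r}")
    return df


@dataclass(frozen=True)
class ConcordanceResult:
    """A Spearman rho between two inference vectors with its provenance."""

    rho: float
    p_value: float
    n_genes: int
    scope: str = "all"  # "all" or a level-2 category name
    source: str = "real"  # "real", "permutation_<k>", "subsample_<k>"
    #: for category results: whether the value would be displayed under the
    #: convention that negative or insignificant correlations are hidden;
    #: every result is computed and stored regardless
    display: bool | None = None


def inference_vector(
    table: GeneTable,
    metadata: StudyMetadata,
    genes: list[str] | None = None,
) -> InferenceVector:
    """Per-gene Wilcoxon P and signed transform for a two-group contrast.

    Group order (and thus every sign) follows the metadata's declared
    (group1, group2) ordering; swapping it negates every nonzero p_t.
    """
    gene_list = list(genes) if genes is not None else table.gene_ids
    missing = [g for g in gene_list if g not in table.data.index]
    if missing:
        raise KeyError(f"genes not in table: {missing[:5]}")
    mask1 = metadata.group_mask(table.sample_ids)
    if mask1.sum() < 2 or (~mask1).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    values = table.data.loc[gene_list].to_numpy(dtype=float)
    p = _rank_sum_p(values, mask1)
    m1 = values[:, mask1].mean(axis=1)
    m2 = values[:, ~mask1].mean(axis=1)
    p_t = np.log10(p) * np.sign(m1 - m2) + 0.0
    return InferenceVector(
        genes=gene_list,
        p_value=p,
        mean_group1=m1,
        mean_group2=m2,
        p_t=p_t,
        group_labels=metadata.group_labels,
    )


def inference_correlation(
    v_pred: InferenceVector,
    v_obs: InferenceVector,
    scope: str = "all",
    source: str = "real",
) -> ConcordanceResult:
    """Spearman correlation of signed transforms over genes shared by both vectors."""
    obs_set = set(v_obs.genes)
    shared = [g for g in v_pred.genes if g in obs_set]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes")
    a = v_pred.subset(shared).p_t
    b = v_obs.subset(shared).p_t
    rho, p = spearman(a, b)
    return ConcordanceResult(rho=rho, p_value=p, n_genes=len(shared), scope=scope, source=source)


def inference_permutation_null(
    pair: AlignedPair,
    metadata: StudyMetadata,
    n_permutations: int = 100,
    seed: int | None = None,
) -> list[ConcordanceResult]:
    """Null distribution of the inference correlation under gene-wise permutation.

    Each round permutes the observed table's genes across samples,
    recomputes its inference vector, and correlates it against the
    unchanged predicted vector.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    genes = pair.shared_genes
    v_pred = inference_vector(pair.predicted, metadata, genes)
    rng = np.random.default_rng(seed)
    out: list[ConcordanceResult] = []
    for k in range(n_permutations):
        permuted = permute_genes_across_samples(pair.observed, rng)
        v_obs_k = inference_vector(permuted, metadata, genes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = inference_correlation(v_pred, v_obs_k, source=f"permutation_{k}")
        out.append(res)
    return out


def subsample_and_recompute(
    pair: AlignedPair,
    metadata: StudyMetadata,
    per_group: int = 5,
    n_repeats: int = 25,
    seed: int | None = None,
) -> list[ConcordanceResult]:
    """Inference correlation on repeated without-replacement subsamples.

    Each repeat draws ``per_group`` samples from each group, recomputes both
    inference vectors on the subsample, and records the rho — the device for
    checking that concordance differences are not sample-size artifacts.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    g1, g2 = metadata.group_labels
    in_shared = set(pair.shared_samples)
    samples1 = [s for s in metadata.samples_in_group(g1) if s in in_shared]
    samples2 = [s for s in metadata.samples_in_group(g2) if s in in_shared]
    for label, members in ((g1, samples1), (g2, samples2)):
        if len(members) < per_group:
            raise ValueError(
                f"group {label!r} has {len(members)} samples, fewer than per_group={per_group}"
            )
    rng = np.random.default_rng(seed)
    genes = pair.shared_genes
    out: list[ConcordanceResult] = []
    for k in range(n_repeats):
        chosen = list(rng.choice(samples1, size=per_group, replace=False)) + list(
            rng.choice(samples2, size=per_group, replace=False)
        )
        sub_pred = pair.predicted.restrict(samples=chosen)
        sub_obs = pair.observed.restrict(samples=chosen)
        v_pred = inference_vector(sub_pred, metadata, genes)
        v_obs = inference_vector(sub_obs, metadata, genes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = inference_correlation(v_pred, v_obs, source=f"subsample_{k}")
        out.append(res)
    return out


def category_inference_correlations(
    v_pred: InferenceVector,
    v_obs: InferenceVector,
    hierarchy: FunctionalHierarchy,
    min_genes: int = 10,
) -> list[ConcordanceResult]:
    """One concordance per level-2 category with enough shared genes.

    A multi-mapped gene contributes to every category it maps to.  Results
    are computed and stored for every qualifying category; the ``display``
    flag marks those that would conventionally be shown (positive and
    P < 0.05).  Categories below ``min_genes`` shared genes are skipped with
    a log entry.
    """
    if min_genes < 3:
        raise ValueError("min_genes must be >= 3")
    obs_set = set(v_obs.genes)
    shared = [g for g in v_pred.genes if g in obs_set]
    cat_map = hierarchy.category_map(level=2)
    out: list[ConcordanceResult] = []
    for cat in sorted(cat_map):
        members = [g for g in shared if g in cat_map[cat]]
        if len(members) < min_genes:
            logger.info(
                "category %r skipped: %d shared genes < min_genes=%d",
                cat,
                len(members),
                min_genes,
            )
            continue
        a = v_pred.subset(members).p_t
        b = v_obs.subset(members).p_t
        rho, p = spearman(a, b)
        display = bool(np.isfinite(rho) and rho > 0 and p < 0.05)
        out.append(
            ConcordanceResult(
                rho=rho,
                p_value=p,
                n_genes=len(members),
                scope=cat,
                source="real",
                display=display,
            )
        )
    return out


def concordance_frame(results: list[ConcordanceResult]) -> pd.DataFrame:
    """Tabulate concordance results (scope, source, rho, p, n_genes, display)."""
    return pd.DataFrame(
        [
            {
                "scope": r.scope,
                "source": r.source,
                "rho": r.rho,
                "p": r.p_value,
                "n_genes": r.n_genes,
                "display": r.display,
            }
            for r in results
        ]
    )
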