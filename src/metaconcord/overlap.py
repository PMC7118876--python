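"""Gene-overlap accounting between predicted and observed tables.

Counts genes detected by both methods, genes the prediction missed, and
genes it predicted that sequencing never saw, overall and per level-2
functional category.  The two headline fractions use deliberately distinct
denominators: the missed fraction is relative to the observed (sequenced)
detected genes, while the undetected-prediction fraction is relative to the
predicted gene list.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .tables_io import FunctionalHierarchy, GeneTable, detected_genes

__all__ = ["OverlapCounts", "OverlapReport", "overlap_report"]


@dataclass(frozen=True)
class OverlapCounts:
    n_shared: int
    n_pred_only: int
    n_obs_only: int

    @property
    def frac_obs_missed(self) -> float:
        """Fraction of observed detected genes absent from the prediction."""
        denom = self.n_shared + self.n_obs_only
        return self.n_obs_only / denom if denom else 0.0

    @property
    def frac_pred_undetected(self) -> float:
        """Fraction of predicted genes not detected by sequencing."""
        denom = self.n_shared + self.n_pred_only
        return self.n_pred_only / denom if denom else 0.0


@dataclass(frozen=True)
class OverlapReport:
    overall: OverlapCounts
    per_category: dict[str, OverlapCounts]

    def to_frame(self) -> pd.DataFrame:
        def row(scope: str, c: OverlapCounts) -> dict:
            return {
                "scope": scope,
                "n_shared": c.n_shared,
                "n_pred_only": c.n_pred_only,
                "n_obs_only": c.n_obs_only,
                "frac_obs_missed": c.frac_obs_missed,
                "frac_pred_undetected": c.frac_pred_undetected,
            }

        rows = [row("all", self.overall)]
        rows.extend(row(cat, c) for cat, c in sorted(self.per_category.items()))
        return pd.DataFrame(rows)


def _counts(pred: set[str], obs: set[str]) -> OverlapCounts:
    return OverlapCounts(
        n_shared=len(pred & obs),
        n_pred_only=len(pred - obs),
        n_obs_only=len(obs - pred),
    )


def overlap_report(
    predicted: GeneTable,
    observed: GeneTable,
    hierarchy: FunctionalHierarchy | None = None,
    min_prevalence: int = 1,
) -> OverlapReport:
    """Set arithmetic over detected genes, overall and per level-2 category.

    Category rows restrict both detected sets to the category's gene
    universe; a multi-mapped gene counts in every category it maps to, so
    category counts can sum to more than the overall ones.
    """
    pred = detected_genes(predicted, min_prevalence)
    obs = detected_genes(observed, min_prevalence)
    per_category: dict[str, OverlapCounts] = {}
    if hierarchy is not None:
        for cat, members in hierarchy.category_map(level=2).items():
            per_category[cat] = _counts(pred & members, obs & members)
    return OverlapReport(overall=_counts(pred, obs), per_category=per_category)
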