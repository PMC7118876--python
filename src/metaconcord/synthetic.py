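"""Synthetic paired predicted/observed gene tables with known truth.

The generator emulates the statistical structure of paired functional
profiles from a 16S-based prediction tool and shotgun metagenome
sequencing of the same two-group study:

* per-gene lognormal baselines with a heavy right tail, so a handful of
  abundant KOs dominate the composition as in real KO tables;
* low (configurable) between-sample variance of the functional profile,
  the feature that makes naive composition correlations insensitive to
  permutation;
* a subset of truly differential genes carrying a multiplicative group
  effect, of which only a ``concordance`` fraction is mirrored in the
  predicted table (overridable per level-2 category);
* prediction error as multiplicative lognormal noise, plus genes the
  prediction misses entirely and spurious genes it invents.

All randomness flows through one ``numpy.random.default_rng`` (PCG64)
stream in a fixed documented draw order, so a seed fully determines the
output on any platform.
"""

from __future__ import annotations

import os
from collections.abc import Mapping
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .tables_io import (
    FunctionalHierarchy,
    GeneTable,
    StudyMetadata,
    normalize,
    read_gene_table,
    read_hierarchy,
    read_metadata,
    write_gene_table,
    write_hierarchy,
    write_metadata,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticStudy",
    "generate_paired_study",
    "write_fixture",
    "read_fixture",
    "DEFAULT_CATEGORIES",
]

#: level-2 categories (with their level-1 parents) assigned round-robin to
#: synthetic genes; a subset of the KEGG second hierarchy tier, spanning
#: three level-1 groups so stratified analyses have structure to find.
DEFAULT_CATEGORIES: tuple[tuple[str, str], ...] = (
    ("Metabolism", "Amino acid metabolism"),
    ("Metabolism", "Carbohydrate metabolism"),
    ("Metabolism", "Energy metabolism"),
    ("Metabolism", "Nucleotide metabolism"),
    ("Genetic Information Processing", "Translation"),
    ("Genetic Information Processing", "Replication and repair"),
    ("Environmental Information Processing", "Membrane transport"),
    ("Environmental Information Processing", "Signal transduction"),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the paired-study generator.

    Defaults describe a human-gut-like study scaled to desk size: a few
    thousand shared KOs, 20 samples per group, ~10% truly differential
    genes at threefold effect, low between-sample variation of the
    functional profile, partial (0.8) mirroring of differential signal in
    the prediction, and roughly a third of genes missed or invented by the
    prediction tool.
    """

    n_genes: int = 2000
    n_samples_per_group: int = 20
    n_differential: int = 200
    #: multiplicative group effect applied to differential genes (>1 means
    #: the favoured group's abundances are scaled up by this factor)
    effect_fold: float = 3.0
    #: coefficient of variation of a gene's abundance across samples
    between_sample_cv: float = 0.3
    #: fraction of differential genes whose effect survives in the prediction
    concordance: float = 0.8
    #: optional per-level-2-category override of ``concordance``
    category_concordance: Mapping[str, float] | None = None
    #: fraction of observed genes absent from the predicted table
    miss_fraction: float = 0.3
    #: fraction of *predicted* genes that are spurious (absent from observed)
    spurious_fraction: float = 0.3
    #: log-sd of the multiplicative lognormal prediction noise
    noise_sd: float = 0.3
    seed: int = 0
    #: log-sd of the lognormal gene baselines (heavy right tail)
    baseline_sigma: float = 1.5
    categories: tuple[tuple[str, str], ...] = DEFAULT_CATEGORIES
    group_labels: tuple[str, str] = ("group1", "group2")

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples_per_group < 2:
            raise ValueError("need n_genes >= 1 and n_samples_per_group >= 2")
        if not 0 <= self.n_differential <= self.n_genes:
            raise ValueError("n_differential must be in [0, n_genes]")
        if self.effect_fold <= 0:
            raise ValueError("effect_fold must be > 0")
        for name in ("concordance", "miss_fraction", "spurious_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.spurious_fraction >= 1.0:
            raise ValueError("spurious_fraction must be < 1")
        if self.between_sample_cv < 0 or self.noise_sd < 0:
            raise ValueError("dispersion parameters must be >= 0")
        if self.category_concordance:
            level2 = {l2 for _, l2 in self.categories}
            for cat, v in self.category_concordance.items():
                if cat not in level2:
                    raise ValueError(f"unknown level-2 category {cat!r}")
                if not 0.0 <= v <= 1.0:
                    raise ValueError("category concordance must be in [0, 1]")
            object.__setattr__(
                self, "category_concordance", dict(self.category_concordance)
            )


@dataclass(frozen=True)
class SyntheticStudy:
    """Generator output: paired tables, design, hierarchy, and ground truth."""

    observed: GeneTable
    predicted: GeneTable
    metadata: StudyMetadata
    hierarchy: FunctionalHierarchy
    #: per observed gene: category, differential flag, direction (+1 if the
    #: effect favours group1, -1 if group2, 0 for null genes), and whether
    #: the effect is mirrored in the predicted table
    truth: pd.DataFrame
    config: SyntheticConfig


def _lognormal_cv_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(-sigma**2 / 2.0, sigma, shape)


def generate_paired_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate one paired study.

    Draw order from the single RNG stream: (1) gene baselines, (2)
    differential gene indices, (3) effect directions, (4) observed sample
    noise, (5) mirrored-gene selection per category, (6) prediction noise,
    (7) missed-gene indices, (8) spurious baselines, (9) spurious sample
    noise.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, nspg = cfg.n_genes, cfg.n_samples_per_group
    m = 2 * nspg
    samples = [f"S{i + 1:03d}" for i in range(m)]
    g1, g2 = cfg.group_labels
    assignments = {s: (g1 if i < nspg else g2) for i, s in enumerate(samples)}
    metadata = StudyMetadata(assignments, (g1, g2))
    group1_mask = np.arange(m) < nspg

    genes = [f"K{i + 1:05d}" for i in range(n)]

    # (1)-(4): observed table
    baseline = rng.lognormal(0.0, cfg.baseline_sigma, n)
    diff_idx = np.sort(rng.choice(n, size=cfg.n_differential, replace=False))
    direction = rng.choice(np.array([1, -1]), size=cfg.n_differential)
    noise_obs = _lognormal_cv_noise(rng, cfg.between_sample_cv, (n, m))

    effect = np.ones((n, m))
    for gi, d in zip(diff_idx, direction):
        effect[gi, group1_mask if d > 0 else ~group1_mask] = cfg.effect_fold
    observed_raw = baseline[:, None] * noise_obs * effect

    # categories: deterministic round-robin keeps truth unambiguous
    cat_of_gene = [cfg.categories[i % len(cfg.categories)] for i in range(n)]

    # (5): which differential genes keep their effect in the prediction
    overrides = cfg.category_concordance or {}
    is_diff = np.zeros(n, dtype=bool)
    is_diff[diff_idx] = True
    mirrored = np.zeros(n, dtype=bool)
    for _, level2 in cfg.categories:
        cat_diff = np.array(
            [i for i in diff_idx if cat_of_gene[i][1] == level2], dtype=int
        )
        if cat_diff.size == 0:
            continue
        conc = overrides.get(level2, cfg.concordance)
        k = int(round(conc * cat_diff.size))
        mirrored[rng.permutation(cat_diff)[:k]] = True

    pred_effect = np.ones((n, m))
    for gi, d in zip(diff_idx, direction):
        if mirrored[gi]:
            pred_effect[gi, group1_mask if d > 0 else ~group1_mask] = cfg.effect_fold

    # (6): prediction noise on top of the observed realization
    noise_pred = (
        rng.lognormal(-cfg.noise_sd**2 / 2.0, cfg.noise_sd, (n, m))
        if cfg.noise_sd > 0
        else np.ones((n, m))
    )
    predicted_raw = observed_raw / effect * pred_effect * noise_pred

    # (7): genes the prediction misses entirely
    n_miss = int(round(cfg.miss_fraction * n))
    missed_idx = rng.choice(n, size=n_miss, replace=False)
    keep = np.ones(n, dtype=bool)
    keep[missed_idx] = False

    # (8)-(9): spurious predicted genes, sized so that the requested
    # fraction of the final predicted gene list is spurious
    n_kept = n - n_miss
    n_spurious = (
        int(round(cfg.spurious_fraction * n_kept / (1.0 - cfg.spurious_fraction)))
        if cfg.spurious_fraction > 0
        else 0
    )
    spur_genes = [f"K9{i + 1:04d}" for i in range(n_spurious)]
    spur_baseline = rng.lognormal(0.0, cfg.baseline_sigma, n_spurious)
    spur_noise = _lognormal_cv_noise(rng, cfg.between_sample_cv, (n_spurious, m))
    spur_values = spur_baseline[:, None] * spur_noise

    pred_genes = [g for g, k in zip(genes, keep) if k] + spur_genes
    pred_values = np.vstack([predicted_raw[keep], spur_values]) if n_spurious else predicted_raw[keep]

    observed = normalize(GeneTable(pd.DataFrame(observed_raw, index=genes, columns=samples)))
    predicted = normalize(GeneTable(pd.DataFrame(pred_values, index=pred_genes, columns=samples)))

    entries: dict[str, set[tuple[str, str]]] = {
        g: {cat_of_gene[i]} for i, g in enumerate(genes)
    }
    for j, g in enumerate(spur_genes):
        entries[g] = {cfg.categories[(n + j) % len(cfg.categories)]}
    hierarchy = FunctionalHierarchy(entries)

    dir_full = np.zeros(n, dtype=int)
    dir_full[diff_idx] = direction
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "level2": [c[1] for c in cat_of_gene],
            "differential": is_diff,
            "direction": dir_full,
            "mirrored": mirrored,
            "in_predicted": keep,
        }
    )
    return SyntheticStudy(observed, predicted, metadata, hierarchy, truth, cfg)


# ---------------------------------------------------------------------------
# fixture round trip
# ---------------------------------------------------------------------------

_FILES = ("observed.tsv", "predicted.tsv", "metadata.tsv", "hierarchy.tsv", "truth.tsv")


def write_fixture(study: SyntheticStudy, directory: str | os.PathLike) -> list[Path]:
    """Write the five-study TSVs into an existing directory."""
    d = Path(directory)
    if not d.is_dir():
        raise FileNotFoundError(f"fixture directory does not exist: {d}")
    write_gene_table(study.observed, d / "observed.tsv")
    write_gene_table(study.predicted, d / "predicted.tsv")
    write_metadata(study.metadata, d / "metadata.tsv")
    write_hierarchy(study.hierarchy, d / "hierarchy.tsv")
    study.truth.to_csv(d / "truth.tsv", sep="\t", index=False)
    return [d / f for f in _FILES]


def read_fixture(
    directory: str | os.PathLike,
) -> tuple[GeneTable, GeneTable, StudyMetadata, FunctionalHierarchy, pd.DataFrame]:
    """Re-read a fixture directory written by :func:`write_fixture`."""
    d = Path(directory)
    observed = read_gene_table(d / "observed.tsv")
    predicted = read_gene_table(d / "predicted.tsv")
    metadata = read_metadata(d / "metadata.tsv")
    hierarchy = read_hierarchy(d / "hierarchy.tsv")
    truth = pd.read_csv(d / "truth.tsv", sep="\t")
    return observed, predicted, metadata, hierarchy, truth
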