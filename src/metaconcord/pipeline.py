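"""End-to-end evaluation pipeline with a machine-readable summary.

Sequences the whole evaluation over one paired study — normalize, align,
composition correlations with their gene-wise permutation control,
inference vectors, inference concordance with its permutation null,
subsampling, category stratification, gene overlap, and PERMANOVA effect
size — writing one TSV per stage plus a single ``summary.json`` that
mirrors every stage's headline numbers.  Inputs are either four TSV paths
(observed, predicted, metadata, hierarchy) or an inline synthetic
configuration; exactly one of the two.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import composition as comp
from . import effect_size as eff
from . import inference as inf
from . import overlap as ovl
from . import tables_io as tio
from .synthetic import SyntheticConfig, generate_paired_study

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Exactly one of the four file paths block or ``synthetic`` must be
    given.  ``seed`` is mandatory: permutation controls, the inference
    null, and subsampling are all stochastic.
    """

    output_dir: str | Path
    seed: int
    observed_path: str | Path | None = None
    predicted_path: str | Path | None = None
    metadata_path: str | Path | None = None
    hierarchy_path: str | Path | None = None
    synthetic: SyntheticConfig | None = None
    group_order: tuple[str, str] | None = None
    n_permutations_composition: int = 100
    n_permutations_inference: int = 100
    subsample_per_group: int = 5
    subsample_repeats: int = 25
    min_prevalence: int = 1
    min_genes: int = 10
    normalize_inputs: bool = True

    def __post_init__(self) -> None:
        paths = [
            self.observed_path,
            self.predicted_path,
            self.metadata_path,
            self.hierarchy_path,
        ]
        has_files = any(p is not None for p in paths)
        if has_files and self.synthetic is not None:
            raise ValueError("give either file inputs or a synthetic block, not both")
        if not has_files and self.synthetic is None:
            raise ValueError("one of file inputs or a synthetic block is required")
        if has_files and not all(p is not None for p in paths):
            raise ValueError("all four input paths are required for a file run")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "RunConfig":
        doc = dict(doc)
        if "synthetic" in doc and doc["synthetic"] is not None:
            doc["synthetic"] = SyntheticConfig(**doc["synthetic"])
        if "group_order" in doc and doc["group_order"] is not None:
            doc["group_order"] = tuple(doc["group_order"])
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _load_inputs(config: RunConfig):
    if config.synthetic is not None:
        study = generate_paired_study(config.synthetic)
        return study.observed, study.predicted, study.metadata, study.hierarchy
    observed = tio.read_gene_table(config.observed_path)
    predicted = tio.read_gene_table(config.predicted_path)
    metadata = tio.read_metadata(config.metadata_path, config.group_order)
    hierarchy = tio.read_hierarchy(config.hierarchy_path)
    return observed, predicted, metadata, hierarchy


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run every stage, write stage TSVs plus summary.json, return the summary.

    Stage errors are re-raised as :class:`PipelineError` naming the stage;
    partial outputs written during the failed run are removed.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "p_value_sides": "two-sided",
    }
    rng_seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)
    stage = "setup"

    def _write(df, name: str) -> None:
        path = out_dir / name
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    try:
        stage = "load_inputs"
        t0 = time.perf_counter()
        observed, predicted, metadata, hierarchy = _load_inputs(config)
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "normalize"
        if config.normalize_inputs:
            observed = tio.normalize(observed)
            predicted = tio.normalize(predicted)

        stage = "align"
        pair = tio.align_pair(predicted, observed, config.min_prevalence)
        summary["n_shared_genes"] = len(pair.shared_genes)
        summary["n_shared_samples"] = len(pair.shared_samples)

        stage = "composition_with_permutation_control"
        t0 = time.perf_counter()
        comp_res = comp.composition_with_permutation_control(
            pair, config.n_permutations_composition, int(rng_seeds[0])
        )
        _write(comp_res.to_frame(), "composition.tsv")
        perm = comp_res.permuted_rhos()
        summary["composition"] = {
            "per_sample_rho": {
                s: rho for s, (rho, _) in comp_res.per_sample.items()
            },
            "mean_rho_real": float(np.nanmean(comp_res.real_rhos())),
            "mean_rho_permuted": float(np.nanmean(perm)),
            "n_permutations": comp_res.n_permutations,
        }
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "inference_vectors"
        t0 = time.perf_counter()
        v_pred = inf.inference_vector(pair.predicted, metadata, pair.shared_genes)
        v_obs = inf.inference_vector(pair.observed, metadata, pair.shared_genes)
        genes_df = v_pred.to_frame().merge(
            v_obs.to_frame(), on="gene_id", suffixes=("_pred", "_obs")
        )
        level1 = {g: sorted({l1 for l1, _ in hierarchy.annotate(g)}) for g in v_pred.genes}
        level2 = {g: sorted({l2 for _, l2 in hierarchy.annotate(g)}) for g in v_pred.genes}
        genes_df["level1"] = [";".join(level1[g]) for g in genes_df["gene_id"]]
        genes_df["level2"] = [";".join(level2[g]) for g in genes_df["gene_id"]]
        _write(genes_df, "inference_genes.tsv")
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "inference_correlation"
        real = inf.inference_correlation(v_pred, v_obs)
        summary["inference"] = {
            "rho": real.rho,
            "p": real.p_value,
            "n_genes": real.n_genes,
        }

        stage = "inference_permutation_null"
        t0 = time.perf_counter()
        null = inf.inference_permutation_null(
            pair, metadata, config.n_permutations_inference, int(rng_seeds[1])
        )
        null_rhos = np.array([r.rho for r in null])
        summary["inference"]["null_mean_rho"] = float(np.nanmean(null_rhos))
        summary["inference"]["null_q95_rho"] = float(np.nanquantile(null_rhos, 0.95))
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "subsample"
        t0 = time.perf_counter()
        g1, g2 = metadata.group_labels
        sizes = [
            len([s for s in metadata.samples_in_group(g) if s in set(pair.shared_samples)])
            for g in (g1, g2)
        ]
        subs: list[inf.ConcordanceResult] = []
        if min(sizes) >= config.subsample_per_group:
            subs = inf.subsample_and_recompute(
                pair,
                metadata,
                config.subsample_per_group,
                config.subsample_repeats,
                int(rng_seeds[2]),
            )
            summary["subsample"] = {
                "per_group": config.subsample_per_group,
                "n_repeats": config.subsample_repeats,
                "mean_rho": float(np.nanmean([r.rho for r in subs])),
            }
        else:
            logger.info("subsampling skipped: groups smaller than per_group")
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "category_inference_correlations"
        cats = inf.category_inference_correlations(
            v_pred, v_obs, hierarchy, config.min_genes
        )
        summary["categories"] = {
            r.scope: {"rho": r.rho, "p": r.p_value, "n_genes": r.n_genes, "display": r.display}
            for r in cats
        }
        _write(inf.concordance_frame([real, *null, *subs, *cats]), "concordance_summary.tsv")

        stage = "overlap_report"
        report = ovl.overlap_report(
            predicted, observed, hierarchy, config.min_prevalence
        )
        _write(report.to_frame(), "overlap.tsv")
        summary["overlap"] = {
            "n_shared": report.overall.n_shared,
            "n_pred_only": report.overall.n_pred_only,
            "n_obs_only": report.overall.n_obs_only,
            "frac_obs_missed": report.overall.frac_obs_missed,
            "frac_pred_undetected": report.overall.frac_pred_undetected,
        }

        stage = "permanova_r2"
        t0 = time.perf_counter()
        dist = eff.bray_curtis_matrix(observed)
        es = eff.permanova_r2(dist, metadata, seed=int(rng_seeds[3]))
        _write(es.to_frame(), "effect_size.tsv")
        summary["effect_size"] = {
            "r_squared": es.r_squared,
            "pseudo_f": es.pseudo_f,
            "p_value": es.p_value,
            "n_permutations": es.n_permutations,
        }
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "summary"
        path = out_dir / "summary.json"
        with open(path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(path)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return summary
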