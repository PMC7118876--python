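import math

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from _oracles import enumerate_wilcoxon_p, naive_spearman
from conftest import make_table
from metaconcord import (
    FunctionalHierarchy,
    InferenceVector,
    StudyMetadata,
    category_inference_correlations,
    inference_correlation,
    inference_permutation_null,
    inference_vector,
    signed_log10_p,
    subsample_and_recompute,
    wilcoxon_rank_sum,
)
from metaconcord.inference import _exact_two_sided_p, _u_counts


def _vector(p_t, genes=None) -> InferenceVector:
    p_t = np.asarray(p_t, dtype=float)
    genes = genes or [f"K{i + 1:05d}" for i in range(p_t.size)]
    p = 10.0 ** (-np.abs(p_t))
    return InferenceVector(
        genes=genes,
        p_value=p,
        mean_group1=np.sign(p_t),
        mean_group2=np.zeros_like(p_t),
        p_t=p_t,
        group_labels=("g1", "g2"),
    )


class TestWilcoxonRankSum:
    def test_most_extreme_split_of_three(self):
        # one-sided 1/20 of C(6,3) assignments, doubled
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_all_identical_values_give_p_one(self):
        assert wilcoxon_rank_sum([5, 5, 5], [5, 5, 5]) == 1.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([1], [2, 3])

    def test_exact_path_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n1, n2 = rng.integers(2, 7, size=2)
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            g1, g2 = pooled[:n1], pooled[n1:]
            assert wilcoxon_rank_sum(g1, g2) == pytest.approx(
                enumerate_wilcoxon_p(g1, g2), abs=1e-12
            )

    def test_exact_path_matches_scipy_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n1, n2 = rng.integers(2, 10, size=2)
            x, y = rng.normal(size=n1), rng.normal(size=n2)
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert wilcoxon_rank_sum(x, y) == pytest.approx(ref, abs=1e-12)

    def test_tie_corrected_normal_path_matches_scipy(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n1, n2 = rng.integers(11, 16, size=2)
            x = rng.integers(0, 5, size=n1).astype(float)
            y = rng.integers(0, 5, size=n2).astype(float)
            ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            assert wilcoxon_rank_sum(x, y) == pytest.approx(ref, abs=1e-12)

    def test_exact_distribution_sums_to_binomial_count(self):
        assert _u_counts(5, 5).sum() == math.comb(10, 5)
        assert (_exact_two_sided_p(5, 5) <= 1.0).all()


class TestSignedLog10P:
    @pytest.mark.parametrize(
        "p, m1, m2, expected",
        [
            (0.1, 2.0, 5.0, 1.0),  # log10(0.1) = -1 times sign(-3) = -1
            (1.0, 3.0, 1.0, 0.0),
            (0.01, 2.0, 2.0, 0.0),
            (0.01, 5.0, 2.0, -2.0),
        ],
    )
    def test_formula(self, p, m1, m2, expected):
        assert signed_log10_p(p, m1, m2) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_out_of_range_p_rejected(self, bad):
        with pytest.raises(ValueError):
            signed_log10_p(bad, 1.0, 2.0)


class TestInferenceVector:
    def test_extreme_separation_five_per_group(self, two_group_metadata):
        values = np.vstack(
            [
                np.r_[10.0, 11, 12, 13, 14, 1, 2, 3, 4, 5],  # group1 all higher
                np.full(10, 7.0),  # constant gene
            ]
        )
        t = make_table(values, genes=["KUP", "KFLAT"], samples=list(two_group_metadata.assignments))
        v = inference_vector(t, two_group_metadata)
        # exact P = 2 / C(10,5); p_t = log10(P) * (+1) < 0
        assert v.p_value[0] == pytest.approx(2 / 252)
        assert v.p_t[0] == pytest.approx(math.log10(2 / 252))
        assert v.p_value[1] == 1.0 and v.p_t[1] == 0.0

    def test_group_swap_negates_all_signed_values(self, default_study, default_pair):
        genes = default_pair.shared_genes
        v = inference_vector(default_pair.observed, default_study.metadata, genes)
        w = inference_vector(
            default_pair.observed, default_study.metadata.swapped(), genes
        )
        assert np.allclose(w.p_t, -v.p_t, atol=1e-12)
        assert np.allclose(w.p_value, v.p_value, atol=1e-12)

    def test_undersized_group_rejected(self):
        md = StudyMetadata({"S1": "g1", "S2": "g2", "S3": "g2"}, ("g1", "g2"))
        t = make_table([[1.0, 2, 3]], samples=["S1", "S2", "S3"])
        with pytest.raises(ValueError):
            inference_vector(t, md)


class TestInferenceCorrelation:
    def test_self_correlation_is_one(self):
        v = _vector([-2.0, -1.0, 0.5, 1.5, 3.0])
        assert inference_correlation(v, v).rho == pytest.approx(1.0)

    def test_antitone_pair_is_minus_one(self):
        v = _vector([-2.0, -1.0, 0.5, 1.5, 3.0])
        w = _vector([2.0, 1.0, -0.5, -1.5, -3.0])
        assert inference_correlation(v, w).rho == pytest.approx(-1.0)

    def test_six_gene_pair_matches_rank_arithmetic(self):
        a = _vector([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = _vector([2.0, 1.0, 4.0, 3.0, 5.0, 6.0])
        res = inference_correlation(a, b)
        # d^2 = 1+1+1+1+0+0: rho = 1 - 6*4/(6*35)
        assert res.rho == pytest.approx(1 - 24 / 210)
        assert res.n_genes == 6

    def test_restricted_to_shared_genes(self):
        a = _vector([1.0, 2.0, 3.0, 4.0], genes=["A", "B", "C", "D"])
        b = _vector([1.0, 2.0, 3.0, 4.0], genes=["B", "C", "D", "E"])
        assert inference_correlation(a, b).n_genes == 3

    def test_group_swap_leaves_rho_unchanged(self, default_study, default_pair):
        md = default_study.metadata
        genes = default_pair.shared_genes
        r1 = inference_correlation(
            inference_vector(default_pair.predicted, md, genes),
            inference_vector(default_pair.observed, md, genes),
        )
        r2 = inference_correlation(
            inference_vector(default_pair.predicted, md.swapped(), genes),
            inference_vector(default_pair.observed, md.swapped(), genes),
        )
        assert r2.rho == pytest.approx(r1.rho, abs=1e-12)

    def test_agrees_with_naive_oracle(self):
        rng = np.random.default_rng(5)
        a = _vector(rng.normal(size=30))
        b = _vector(rng.normal(size=30))
        assert inference_correlation(a, b).rho == pytest.approx(
            naive_spearman(a.p_t, b.p_t), abs=1e-12
        )


class TestPermutationNull:
    def test_fixed_seed_reproducible(self, default_study, default_pair):
        a = inference_permutation_null(default_pair, default_study.metadata, 5, seed=9)
        b = inference_permutation_null(default_pair, default_study.metadata, 5, seed=9)
        assert [r.rho for r in a] == [r.rho for r in b]

    def test_null_centered_on_zero(self, default_study, default_pair):
        null = inference_permutation_null(
            default_pair, default_study.metadata, 30, seed=9
        )
        rhos = np.array([r.rho for r in null])
        se = rhos.std(ddof=1) / np.sqrt(len(rhos))
        assert abs(rhos.mean()) < 2 * se + 0.02

    def test_sources_are_labelled(self, default_study, default_pair):
        null = inference_permutation_null(default_pair, default_study.metadata, 3, seed=0)
        assert [r.source for r in null] == [
            "permutation_0",
            "permutation_1",
            "permutation_2",
        ]


class TestSubsampling:
    def test_full_size_subsample_reproduces_full_rho(self, default_study, default_pair):
        md = default_study.metadata
        full = inference_correlation(
            inference_vector(default_pair.predicted, md, default_pair.shared_genes),
            inference_vector(default_pair.observed, md, default_pair.shared_genes),
        )
        subs = subsample_and_recompute(default_pair, md, per_group=10, n_repeats=2, seed=1)
        for r in subs:
            assert r.rho == pytest.approx(full.rho, abs=1e-12)

    def test_oversized_subsample_rejected(self, default_study, default_pair):
        with pytest.raises(ValueError, match="per_group"):
            subsample_and_recompute(default_pair, default_study.metadata, per_group=11)


class TestCategoryStratification:
    def test_single_category_equals_global_rho(self, default_study, default_pair):
        md = default_study.metadata
        v_pred = inference_vector(default_pair.predicted, md, default_pair.shared_genes)
        v_obs = inference_vector(default_pair.observed, md, default_pair.shared_genes)
        hier = FunctionalHierarchy(
            {g: {("Meta", "All")} for g in default_pair.shared_genes}
        )
        results = category_inference_correlations(v_pred, v_obs, hier, min_genes=10)
        assert len(results) == 1
        assert results[0].scope == "All"
        assert results[0].rho == pytest.approx(
            inference_correlation(v_pred, v_obs).rho, abs=1e-12
        )

    def test_small_categories_skipped(self):
        v = _vector(np.arange(12.0))
        hier = FunctionalHierarchy(
            {v.genes[0]: {("A", "tiny")}, **{g: {("A", "big")} for g in v.genes[1:]}}
        )
        results = category_inference_correlations(v, v, hier, min_genes=10)
        assert [r.scope for r in results] == ["big"]

    def test_min_genes_validated(self):
        v = _vector(np.arange(5.0))
        with pytest.raises(ValueError):
            category_inference_correlations(v, v, FunctionalHierarchy({}), min_genes=2)

    def test_display_flag_marks_positive_significant_only(self):
        rng = np.random.default_rng(8)
        a = _vector(np.arange(40.0))
        up = np.arange(40.0) + rng.normal(0, 1, 40)  # strongly concordant
        down = -np.arange(40.0) + rng.normal(0, 1, 40)  # anticoncordant
        genes = a.genes
        hier = FunctionalHierarchy(
            {
                **{g: {("A", "good")} for g in genes[:20]},
                **{g: {("A", "bad")} for g in genes[20:]},
            }
        )
        b = _vector(np.r_[up[:20], down[20:]], genes=genes)
        results = {
            r.scope: r for r in category_inference_correlations(a, b, hier, min_genes=10)
        }
        assert results["good"].display is True
        assert results["bad"].display is False
        assert results["bad"].rho < 0  # computed and stored despite the flag
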