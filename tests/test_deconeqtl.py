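import logging

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from _oracles import bh_adjust, projected_gradient_nnls
from conftest import (
    expression_from_array,
    genotypes_from_array,
    proportions_from_array,
    scaled_from_dirichlet,
)
from decon2.deconeqtl import (
    DeconEqtlResults,
    anova_interaction_test,
    choose_encoding,
    deconvolute,
    enumerate_encodings,
    fdr_per_celltype,
    fit_nnls_interaction,
    scale_proportions,
)
from decon2.matrices import ScaledProportions


def random_instance(rng, n=40, k=2, gamma=None, noise=0.5, conc=None):
    """Small random instance of the interaction model."""
    c = rng.dirichlet(conc if conc is not None else np.full(k, 2.0), size=n) * 100
    g = rng.binomial(2, 0.3, size=n).astype(float)
    while np.ptp(g) == 0:
        g = rng.binomial(2, 0.3, size=n).astype(float)
    beta = rng.uniform(1, 3, size=k)
    y = c @ beta
    if gamma is not None:
        for j, gm in enumerate(gamma):
            g_enc = g if gm >= 0 else 2.0 - g
            y = y + abs(gm) * g_enc * c[:, j]
    y = y + rng.normal(0, noise, size=n)
    return np.clip(y, 0, None), g, c


class TestScaleProportions:
    def test_already_scaled_row_unchanged(self):
        props = proportions_from_array([[60, 20, 10, 5, 3, 2]])
        out = scale_proportions(props)
        assert np.allclose(out.data.to_numpy()[0], [60, 20, 10, 5, 3, 2])

    def test_half_sum_row_doubled(self):
        props = proportions_from_array([[30, 10, 5, 2.5, 1.5, 1]])
        out = scale_proportions(props)
        assert np.allclose(out.data.to_numpy()[0], [60, 20, 10, 5, 3, 2])

    def test_collinear_pair_warned(self, caplog):
        rng = np.random.default_rng(0)
        a = rng.uniform(10, 50, 30)
        props = proportions_from_array(
            np.column_stack([a, 2 * a, rng.uniform(10, 50, 30)]),
            cell_types=["x", "y", "z"],
        )
        with caplog.at_level(logging.WARNING):
            scale_proportions(props)
        assert "'x' and 'y'" in caplog.text

    def test_all_zero_sample_rejected(self):
        props = proportions_from_array([[1.0, 2.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="all-zero"):
            scale_proportions(props)

    def test_subset_of_cell_types(self):
        props = proportions_from_array([[50, 30, 20]], cell_types=["a", "b", "c"])
        out = scale_proportions(props, ["a", "b"])
        assert np.allclose(out.data.to_numpy()[0], [62.5, 37.5])


class TestEnumerateEncodings:
    def test_k1_two_distinct(self):
        assert enumerate_encodings(1) == [(False,), (True,)]

    def test_k2_distinct_patterns(self):
        # with two terms every single-term deviation coincides with a
        # deviation from the other majority: only 4 distinct patterns exist
        encs = enumerate_encodings(2)
        assert len(encs) == len(set(encs)) == 4

    @pytest.mark.parametrize("k", [3, 4, 5, 6, 8])
    def test_count_law(self, k):
        encs = enumerate_encodings(k)
        assert len(encs) == len(set(encs)) == 2 * k + 2

    def test_at_most_one_deviation(self):
        for enc in enumerate_encodings(6):
            n_swapped = sum(enc)
            assert n_swapped <= 1 or n_swapped >= 5

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            enumerate_encodings(0)


class TestFitNnlsInteraction:
    def test_exact_reconstruction_k1(self):
        n = 10
        c = np.full((n, 1), 100.0)
        g = np.tile([0.0, 1.0, 2.0], 4)[:n]
        y = 2.0 * c[:, 0] + 1.0 * g * c[:, 0]
        fit = fit_nnls_interaction(y, g, c, (False,))
        assert fit.betas[0] == pytest.approx(2.0, abs=1e-9)
        assert fit.gammas[0] == pytest.approx(1.0, abs=1e-9)
        assert fit.rss < 1e-12

    def test_nested_rss_ordering(self, rng):
        for _ in range(20):
            y, g, c = random_instance(rng, n=40, k=2)
            full = fit_nnls_interaction(y, g, c, (False, False))
            red = fit_nnls_interaction(y, g, c, (False,), drop_term=1)
            assert full.rss <= red.rss + 1e-9

    def test_matches_projected_gradient_oracle(self, rng):
        y, g, c = random_instance(rng, n=40, k=2, gamma=[0.5, 0.0], noise=2.0)
        fit = fit_nnls_interaction(y, g, c, (False, False))
        x = np.column_stack([c, g * c[:, 0], g * c[:, 1]])
        oracle = projected_gradient_nnls(x, y)
        assert np.allclose(np.r_[fit.betas, fit.gammas], oracle, atol=1e-6)

    def test_sample_size_guard(self):
        c = np.full((4, 2), 50.0)
        with pytest.raises(ValueError, match="n > 2k"):
            fit_nnls_interaction(np.ones(4), np.ones(4), c, (False, False))


class TestChooseEncoding:
    def test_swapped_term_recovered(self, rng):
        n = 200
        c = rng.dirichlet([3, 3], size=n) * 100
        g = rng.binomial(2, 0.4, size=n).astype(float)
        # term 1 interacts under as-is coding, term 2 under the swapped coding
        y = 2 * c[:, 0] + 1.5 * c[:, 1] + 0.6 * g * c[:, 0] + 0.8 * (2.0 - g) * c[:, 1]
        y = y + rng.normal(0, 1.0, size=n)
        fits = [fit_nnls_interaction(y, g, c, e) for e in enumerate_encodings(2)]
        best = choose_encoding(fits)
        assert best.encoding == (False, True)
        # exhaustive check: really the minimum rss
        assert best.rss == min(f.rss for f in fits)

    def test_tie_broken_toward_all_as_is(self, rng):
        n = 60
        c = rng.dirichlet([3, 3], size=n) * 100
        g = rng.binomial(2, 0.4, size=n).astype(float)
        y = c @ np.array([2.0, 1.0])  # no interaction: every encoding fits exactly
        fits = [fit_nnls_interaction(y, g, c, e) for e in enumerate_encodings(2)]
        assert choose_encoding(fits).encoding == (False, False)

    def test_single_fit_returned(self, rng):
        y, g, c = random_instance(rng)
        fit = fit_nnls_interaction(y, g, c, (True, False))
        assert choose_encoding([fit]) is fit


class TestAnovaInteractionTest:
    def test_equal_rss_gives_p_one(self):
        f, p = anova_interaction_test(1.5, 1.5, n=50, k=2)
        assert f == 0.0 and p == 1.0

    def test_known_f_value_against_t_distribution(self):
        f, p = anova_interaction_test(1.0, 2.0, n=104, k=2)
        assert f == pytest.approx(100.0)
        # F(1, d) upper tail equals the two-sided t(d) tail at sqrt(F)
        assert p == pytest.approx(2 * scipy.stats.t.sf(10.0, 100), rel=1e-12)

    def test_saturated_fit_gives_p_one(self):
        _, p = anova_interaction_test(0.0, 0.0, n=50, k=2)
        assert p == 1.0

    def test_tiny_negative_numerator_clamped(self):
        f, p = anova_interaction_test(1.0, 1.0 - 1e-12, n=50, k=2)
        assert f == 0.0 and p == 1.0

    def test_sample_guard(self):
        with pytest.raises(ValueError):
            anova_interaction_test(1.0, 2.0, n=4, k=2)


def build_decon_inputs(y_matrix, genos, props_arr, gene_ids=None, snp_ids=None):
    expr = expression_from_array(y_matrix, state="corrected_linear")
    if gene_ids is not None:
        expr.data.index = gene_ids
    geno = genotypes_from_array(genos)
    if snp_ids is not None:
        geno.data.index = snp_ids
    props = ScaledProportions(
        pd.DataFrame(
            props_arr,
            index=[f"sample{j}" for j in range(props_arr.shape[0])],
            columns=[f"ct{j}" for j in range(props_arr.shape[1])],
        )
    )
    return expr, geno, props


class TestDeconvolute:
    def test_single_interacting_cell_type_detected(self, rng):
        n = 500
        c = rng.dirichlet([3, 3], size=n) * 100
        g = rng.binomial(2, 0.3, size=n).astype(float)
        y = 2 * c[:, 0] + 1 * c[:, 1] + 0.5 * g * c[:, 0]
        y = y + rng.normal(0, 0.1 * np.std(0.5 * g * c[:, 0]), size=n)
        expr, geno, props = build_decon_inputs(y[np.newaxis, :], g[np.newaxis, :], c)
        pairs = pd.DataFrame({"snp_id": ["snp0"], "gene_id": ["gene0"]})
        res = deconvolute(pairs, expr, geno, props).results[0]
        assert res.p_values[0] < 0.01
        assert res.p_values[1] > 0.05

    def test_pure_noise_gene_not_significant(self, rng):
        n = 300
        c = rng.dirichlet([3, 3], size=n) * 100
        g = rng.binomial(2, 0.3, size=n).astype(float)
        y = np.clip(rng.normal(100, 10, size=n), 0, None)
        expr, geno, props = build_decon_inputs(y[np.newaxis, :], g[np.newaxis, :], c)
        pairs = pd.DataFrame({"snp_id": ["snp0"], "gene_id": ["gene0"]})
        res = deconvolute(pairs, expr, geno, props).results[0]
        assert min(res.p_values) > 1e-4

    def test_duplicate_pairs_deduplicated(self, rng):
        y, g, c = random_instance(rng, n=30)
        expr, geno, props = build_decon_inputs(y[np.newaxis, :], g[np.newaxis, :], c)
        pairs = pd.DataFrame(
            {"snp_id": ["snp0", "snp0"], "gene_id": ["gene0", "gene0"]}
        )
        out = deconvolute(pairs, expr, geno, props)
        assert len(out) == 1

    def test_unknown_features_skipped_with_summary(self, rng):
        y, g, c = random_instance(rng, n=30)
        expr, geno, props = build_decon_inputs(y[np.newaxis, :], g[np.newaxis, :], c)
        pairs = pd.DataFrame(
            {"snp_id": ["snp0", "snpX", "snp0"], "gene_id": ["gene0", "gene0", "geneX"]}
        )
        out = deconvolute(pairs, expr, geno, props)
        assert len(out) == 1
        assert ("snpX", "gene0", "unknown snp") in out.skipped
        assert ("snp0", "geneX", "unknown gene") in out.skipped

    def test_zero_variance_dosage_skipped(self, rng):
        y, _, c = random_instance(rng, n=30)
        g = np.ones(30)
        expr, geno, props = build_decon_inputs(y[np.newaxis, :], g[np.newaxis, :], c)
        pairs = pd.DataFrame({"snp_id": ["snp0"], "gene_id": ["gene0"]})
        out = deconvolute(pairs, expr, geno, props)
        assert len(out) == 0
        assert out.skipped[0][2] == "zero-variance dosage"

    def test_nonnegative_coefficients_and_nesting(self, rng):
        for _ in range(10):
            y, g, c = random_instance(rng, n=45, k=3)
            expr, geno, props = build_decon_inputs(
                y[np.newaxis, :], g[np.newaxis, :], c
            )
            pairs = pd.DataFrame({"snp_id": ["snp0"], "gene_id": ["gene0"]})
            res = deconvolute(pairs, expr, geno, props).results[0]
            assert all(b >= 0 for b in res.betas)
            assert all(gm >= 0 for gm in res.gammas)
            assert all(res.rss_full <= r + 1e-9 for r in res.rss_reduced)

    def test_global_dosage_swap_leaves_pvalues_invariant(self, rng):
        y, g, c = random_instance(rng, n=80, k=2, gamma=[0.4, -0.2], noise=1.0)
        expr, geno, props = build_decon_inputs(y[np.newaxis, :], g[np.newaxis, :], c)
        geno_sw = genotypes_from_array((2.0 - g)[np.newaxis, :])
        pairs = pd.DataFrame({"snp_id": ["snp0"], "gene_id": ["gene0"]})
        r1 = deconvolute(pairs, expr, geno, props).results[0]
        r2 = deconvolute(pairs, expr, geno_sw, props).results[0]
        assert r1.rss_full == pytest.approx(r2.rss_full, abs=1e-9)
        for p1, p2 in zip(r1.p_values, r2.p_values):
            assert p1 == pytest.approx(p2, abs=1e-9)


class TestFdrPerCellType:
    def _results_from_pvalues(self, pvals_by_ct):
        cts = tuple(pvals_by_ct.keys())
        n = len(next(iter(pvals_by_ct.values())))
        from decon2.deconeqtl import DeconEqtlResult

        results = []
        for i in range(n):
            ps = tuple(pvals_by_ct[ct][i] for ct in cts)
            results.append(
                DeconEqtlResult(
                    snp_id=f"snp{i}",
                    gene_id=f"gene{i}",
                    cell_types=cts,
                    betas=(0.0,) * len(cts),
                    gammas=(0.0,) * len(cts),
                    encoding=(False,) * len(cts),
                    rss_full=1.0,
                    rss_reduced=(1.0,) * len(cts),
                    f_stats=(0.0,) * len(cts),
                    p_values=ps,
                )
            )
        return DeconEqtlResults(results=results, cell_types=cts)

    def test_hand_bh_example(self):
        res = self._results_from_pvalues({"a": [0.01, 0.02, 0.03, 0.04]})
        out = fdr_per_celltype(res)
        assert [r.fdr[0] for r in out] == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_test_fdr_equals_p(self):
        out = fdr_per_celltype(self._results_from_pvalues({"a": [0.123]}))
        assert out.results[0].fdr[0] == pytest.approx(0.123)

    def test_all_ones(self):
        out = fdr_per_celltype(self._results_from_pvalues({"a": [1.0, 1.0, 1.0]}))
        assert all(r.fdr[0] == 1.0 for r in out)

    def test_matches_hand_bh_on_random_vectors(self, rng):
        p = rng.uniform(size=25)
        out = fdr_per_celltype(self._results_from_pvalues({"a": p, "b": p[::-1]}))
        expected = bh_adjust(p)
        got = np.array([r.fdr[0] for r in out])
        assert np.allclose(got, expected, atol=1e-12)
        for r in out:
            assert r.fdr[0] >= r.p_values[0]
            assert r.fdr[1] >= r.p_values[1]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fdr_per_celltype(DeconEqtlResults(results=[], cell_types=("a",)))
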