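"""Moderated-t differential expression: oracles, recovery, consensus."""

import numpy as np
import pytest
from scipy import stats

from tfinertia.data import ComparisonSpec, ExpressionMatrix, enumerate_design
from tfinertia.diffexpr import (
    bh_adjust,
    consensus_gene_list,
    differential_expression,
    estimate_prior,
    fit_two_group,
    moderate,
    significant_genes,
)
from tfinertia.exceptions import DataError

TOY_COMPARISON = ComparisonSpec(
    "toy",
    "L",
    frozenset({("drug", 1.0, 12.0)}),
    frozenset({("vehicle", 0.0, 0.0)}),
)


def _toy_expr(x1, x2):
    """Expression matrix from per-group value arrays (genes x reps)."""
    x1, x2 = np.atleast_2d(x1), np.atleast_2d(x2)
    design = enumerate_design(
        [
            ("L", "drug", 1.0, (12.0,), x1.shape[1]),
            ("L", "vehicle", 0.0, (0.0,), x2.shape[1]),
        ]
    )
    drug = [s for s in design.sample_ids if ".drug." in s]
    veh = [s for s in design.sample_ids if ".vehicle." in s]
    genes = [f"g{i}" for i in range(x1.shape[0])]
    expr = ExpressionMatrix(genes, drug + veh, np.hstack([x1, x2]))
    return expr, design


class TestFitTwoGroup:
    def test_identical_group_means_give_zero_logfc(self):
        expr, design = _toy_expr([[5.0, 5.0]], [[5.0, 5.0]])
        fit = fit_two_group(expr, design, TOY_COMPARISON)
        assert fit["logFC"].iloc[0] == 0.0

    def test_hand_pooled_variance_example(self):
        expr, design = _toy_expr([[2.0, 4.0]], [[1.0, 1.0]])
        fit = fit_two_group(expr, design, TOY_COMPARISON)
        assert fit["logFC"].iloc[0] == pytest.approx(2.0)
        assert fit["s2"].iloc[0] == pytest.approx(1.0)
        assert fit["df"].iloc[0] == 2.0

    def test_doubling_values_doubles_logfc_and_quadruples_variance(self, rng):
        x1 = rng.normal(8, 1, (5, 3))
        x2 = rng.normal(8, 1, (5, 3))
        e1, d1 = _toy_expr(x1, x2)
        e2, d2 = _toy_expr(2 * x1, 2 * x2)
        f1 = fit_two_group(e1, d1, TOY_COMPARISON)
        f2 = fit_two_group(e2, d2, TOY_COMPARISON)
        assert np.allclose(f2["logFC"], 2 * f1["logFC"])
        assert np.allclose(f2["s2"], 4 * f1["s2"])

    def test_group_with_one_sample_raises(self):
        expr, design = _toy_expr([[2.0]], [[1.0, 1.0]])
        with pytest.raises(DataError, match=">= 2 samples"):
            fit_two_group(expr, design, TOY_COMPARISON)


class TestModerate:
    def test_zero_prior_df_reproduces_ordinary_t(self, rng):
        n = 50
        logfc = rng.normal(0, 1, n)
        s2 = rng.chisquare(6, n) / 6 * 0.3
        _, t, p = moderate(logfc, s2, 6.0, 4, 4, d0=0.0)
        # independent ordinary two-sample t
        t_ref = logfc / np.sqrt(s2 * (1 / 4 + 1 / 4))
        p_ref = 2 * stats.t.sf(np.abs(t_ref), 6)
        assert np.max(np.abs(t - t_ref)) < 1e-12
        assert np.max(np.abs(p - p_ref)) < 1e-12

    def test_equal_variances_drive_prior_df_to_infinity(self):
        s2 = np.full(100, 0.25)
        logfc = np.linspace(-1, 1, 100)
        params, t, p = moderate(logfc, s2, 6.0, 4, 4)
        assert np.isinf(params.d0)
        assert params.s02 == pytest.approx(0.25, rel=1e-6)
        assert np.all(np.isfinite(p))

    def test_posterior_variance_lies_between_sample_and_prior(self, rng):
        s2 = rng.chisquare(6, 200) / 6 * 0.1
        params = estimate_prior(s2, 6.0)
        post = params.posterior_variance(s2, np.full(200, 6.0))
        lo = np.minimum(s2, params.s02)
        hi = np.maximum(s2, params.s02)
        assert np.all(post >= lo - 1e-12) and np.all(post <= hi + 1e-12)

    def test_matches_reference_ebayes_implementation(self):
        """Frozen cross-check against the Bioconductor limma eBayes fit.

        The fixture is regenerated deterministically; the expected numbers
        were produced by lmFit/eBayes on the identical matrix.
        """
        rng = np.random.default_rng(20260930)
        n_genes, n1, n2 = 200, 4, 4
        sigma2 = 0.04 * 4.0 / rng.chisquare(4.0, n_genes)
        mu = rng.normal(0, 0.5, n_genes)
        x1 = rng.normal(mu[:, None], np.sqrt(sigma2)[:, None], (n_genes, n1))
        x2 = rng.normal(0, np.sqrt(sigma2)[:, None], (n_genes, n2))
        logfc = x1.mean(1) - x2.mean(1)
        ss = ((x1 - x1.mean(1, keepdims=True)) ** 2).sum(1) + (
            (x2 - x2.mean(1, keepdims=True)) ** 2
        ).sum(1)
        s2 = ss / 6.0
        params, t, p = moderate(logfc, s2, 6.0, n1, n2)
        assert params.d0 == pytest.approx(3.465969934, rel=1e-6)
        assert params.s02 == pytest.approx(0.03941238216, rel=1e-6)
        t_ref = [-2.022615256, 1.741716297, -3.035777781, 2.659624034, 1.242614277]
        p_ref = [
            0.07226363359,
            0.113883478,
            0.01333619836,
            0.02499780969,
            0.2439102946,
        ]
        assert np.allclose(t[:5], t_ref, rtol=1e-6)
        assert np.allclose(p[:5], p_ref, rtol=1e-6)

    def test_prior_recovery_within_25_percent(self):
        errs_d0, errs_s02 = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sigma2 = 0.04 * 4.0 / rng.chisquare(4.0, 5000)
            s2 = sigma2 * rng.chisquare(6.0, 5000) / 6.0
            params = estimate_prior(s2, 6.0)
            errs_d0.append(abs(params.d0 - 4.0) / 4.0)
            errs_s02.append(abs(params.s02 - 0.04) / 0.04)
        assert np.median(errs_d0) < 0.25
        assert np.median(errs_s02) < 0.25

    def test_null_p_values_are_uniform(self):
        ks_stats = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x1 = rng.normal(0, 0.5, (5000, 4))
            x2 = rng.normal(0, 0.5, (5000, 4))
            logfc = x1.mean(1) - x2.mean(1)
            ss = ((x1 - x1.mean(1, keepdims=True)) ** 2).sum(1) + (
                (x2 - x2.mean(1, keepdims=True)) ** 2
            ).sum(1)
            _, _, p = moderate(logfc, ss / 6.0, 6.0, 4, 4)
            ks_stats.append(stats.kstest(p, "uniform").statistic)
        assert np.median(ks_stats) < 0.05

    def test_all_zero_variances_raise(self):
        with pytest.raises(DataError, match="zero"):
            estimate_prior(np.zeros(50), 6.0)


class TestBhAdjust:
    def test_single_p_is_unchanged(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_hand_step_up_example(self):
        adj = bh_adjust(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_adjusted_values_are_monotone_in_raw_order(self, rng):
        p = rng.random(100)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert np.all(adj >= p - 1e-15)

    def test_out_of_range_p_raises(self):
        with pytest.raises(DataError):
            bh_adjust(np.array([0.5, 1.2]))


class TestSignificantGenes:
    def _frame(self, logfc, adj_p):
        import pandas as pd

        return pd.DataFrame(
            {"logFC": logfc, "adj_p": adj_p},
            index=[f"g{i}" for i in range(len(logfc))],
        )

    def test_boundary_values_are_inclusive(self):
        de = self._frame([np.log2(1.3)], [0.05])
        assert significant_genes(de) == {"g0": 1}

    def test_large_fold_change_with_poor_p_is_excluded(self):
        de = self._frame([1.0], [0.2])
        assert significant_genes(de) == {}

    def test_downregulated_genes_are_tagged_negative(self):
        de = self._frame([-1.0], [0.01])
        assert significant_genes(de) == {"g0": -1}

    def test_all_null_simulation_controls_the_fdr(self):
        counts = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x1 = rng.normal(8, 0.25, (2000, 4))
            x2 = rng.normal(8, 0.25, (2000, 4))
            expr, design = _toy_expr(x1, x2)
            de = differential_expression(expr, design, TOY_COMPARISON)
            counts.append(len(significant_genes(de)))
        assert np.mean(counts) <= 0.05 * 2000 * 1.5


class TestConsensusGeneList:
    def test_unanimous_gene_is_included(self):
        sets = [{"g1": 1} for _ in range(6)]
        out = consensus_gene_list(sets)
        assert out["gene"].tolist() == ["g1"]
        assert out["direction"].tolist() == [1]

    def test_direction_conflict_is_always_excluded(self):
        sets = [{"g1": 1}] * 3 + [{"g1": -1}] * 3
        for min_support in (1, 3, 6):
            assert consensus_gene_list(sets, min_support).empty

    def test_five_of_six_support_boundary(self):
        sets = [{"g1": 1}] * 5 + [{}]
        assert not consensus_gene_list(sets, min_support=5).empty
        assert consensus_gene_list(sets, min_support=6).empty


def test_planted_signal_recovery_meets_sensitivity_and_fdr():
    """logFC 1.0, sd 0.25, 4v4, 10% non-null of 2000 genes, 20 seeds."""
    sens, fdr = [], []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        n, n_alt = 2000, 200
        x1 = rng.normal(8, 0.25, (n, 4))
        x2 = rng.normal(8, 0.25, (n, 4))
        x1[:n_alt] += 1.0
        expr, design = _toy_expr(x1, x2)
        de = differential_expression(expr, design, TOY_COMPARISON)
        called = set(significant_genes(de))
        truth = {f"g{i}" for i in range(n_alt)}
        tp = len(called & truth)
        sens.append(tp / n_alt)
        fdr.append((len(called) - tp) / max(1, len(called)))
    assert np.median(sens) >= 0.9
    assert np.median(fdr) <= 0.1
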