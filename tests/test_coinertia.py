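"""Co-inertia coupling: oracles, RV bounds, supervised motif ranking."""

import numpy as np
import pytest
from sklearn.base import clone

from conftest import random_nonneg_table
from tfinertia.coinertia import (
    CoInertiaAnalysis,
    cia,
    supervised_motif_ranking,
    unsupervised_projection,
)
from tfinertia.data import (
    ComparisonSpec,
    ExpressionMatrix,
    MotifIncidenceTable,
    enumerate_design,
)
from tfinertia.exceptions import DataError
from tfinertia.ordination import DualityDiagram, diagonalize, nsc
from tfinertia.simulate import SimulationConfig, simulate_expression, simulate_motif_tables


class TestCia:
    def test_self_coupling_gives_rv_one_and_sigma_equal_lambda(self, rng):
        F = random_nonneg_table(rng, 8, 5)
        dd = nsc(F)
        res = cia(dd, dd)
        assert res.rv == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(res.singular_values, dd.eigenvalues, atol=1e-10)

    def test_sigma_matches_brute_force_svd_of_weighted_cross_matrix(self, rng):
        FA = random_nonneg_table(rng, 5, 4)
        FB = random_nonneg_table(rng, 5, 3)
        ddA = nsc(FA)
        ddB = nsc(FB, row_weights=ddA.row_weights)
        res = cia(ddA, ddB)
        # independent dense route: explicitly materialize the metrics
        W = ddA.Z.T @ np.diag(ddA.row_weights) @ ddB.Z
        M = (
            np.diag(np.sqrt(ddA.col_metric))
            @ W
            @ np.diag(np.sqrt(ddB.col_metric))
        )
        s = np.linalg.svd(M, compute_uv=False)
        assert np.max(np.abs(res.singular_values - s)) < 1e-10

    def test_axis_covariance_of_gene_scores_equals_singular_value(self, rng):
        FA = random_nonneg_table(rng, 9, 5)
        FB = random_nonneg_table(rng, 9, 4)
        ddA = nsc(FA)
        ddB = nsc(FB, row_weights=ddA.row_weights)
        res = cia(ddA, ddB)
        d = ddA.row_weights
        for k in range(len(res.singular_values)):
            cov = np.sum(d * res.gene_scores_A[:, k] * res.gene_scores_B[:, k])
            assert cov == pytest.approx(res.singular_values[k], abs=1e-8)

    def test_rv_lies_in_unit_interval_on_random_pairs(self):
        for seed in range(10):
            r = np.random.default_rng(seed)
            ddA = nsc(random_nonneg_table(r, 7, 4))
            ddB = nsc(random_nonneg_table(r, 7, 5), row_weights=ddA.row_weights)
            res = cia(ddA, ddB)
            assert -1e-10 <= res.rv <= 1 + 1e-10

    def test_row_order_mismatch_raises(self, rng):
        F = random_nonneg_table(rng, 4, 3)
        ddA = nsc(F, row_ids=list("abcd"))
        ddB = nsc(F, row_ids=list("abdc"))
        with pytest.raises(DataError, match="row order"):
            cia(ddA, ddB)

    def test_zero_inertia_table_raises(self, rng):
        flat = np.ones((4, 3))
        ddA = nsc(flat)
        ddB = nsc(random_nonneg_table(rng, 4, 3), row_weights=ddA.row_weights)
        with pytest.raises(DataError, match="zero inertia"):
            cia(ddA, ddB)

    def test_permuting_gene_labels_destroys_co_structure(self):
        cfg = SimulationConfig(seed=11, n_genes=2000, n_motifs=100)
        tables = simulate_motif_tables(cfg)
        expr, _, _ = simulate_expression(cfg, tables)
        ddA = nsc(expr.values)
        ddB = nsc(tables[2].counts, row_weights=ddA.row_weights)
        rng = np.random.default_rng(0)
        small = 0
        for _ in range(50):
            Zp = ddB.Z[rng.permutation(cfg.n_genes)]
            lam, axes, scores = diagonalize(Zp, ddB.row_weights, ddB.col_metric)
            ddp = DualityDiagram(
                Zp, ddB.row_weights, ddB.col_metric, lam, axes, scores,
                ddB.total_inertia,
            )
            small += cia(ddA, ddp).rv < 0.05
        assert small >= 48  # >= 95% of 50 permutations


def _planted_setup(delta=2.0, noise=0.0, seed=1, n_genes=60, n_motifs=8):
    """Noiseless-or-noisy toy study: one driver motif, drug vs vehicle."""
    rng = np.random.default_rng(seed)
    design = enumerate_design(
        [("L", "vehicle", 0.0, (0.0,), 4), ("L", "drug", 1.0, (12.0,), 4)]
    )
    genes = [f"g{i:02d}" for i in range(n_genes)]
    motif_ids = [f"M{j}" for j in range(n_motifs)]
    counts = (rng.random((n_genes, n_motifs)) < 0.25).astype(int)
    counts[:, 3] = 0
    counts[rng.choice(n_genes, n_genes // 5, replace=False), 3] = 1
    motifs = MotifIncidenceTable(genes, motif_ids, counts, "0.8")
    values = np.full((n_genes, design.n_samples), 8.0)
    values += rng.normal(0, noise, values.shape)
    drug = np.array([t == "drug" for t in design.table["treatment"]])
    values[np.ix_(counts[:, 3] > 0, drug)] += delta
    expr = ExpressionMatrix(genes, design.sample_ids, values)
    comp = ComparisonSpec(
        "toy",
        "L",
        frozenset({("drug", 1.0, 12.0)}),
        frozenset({("vehicle", 0.0, 0.0)}),
    )
    return expr, motifs, design, comp


class TestUnsupervised:
    def test_planted_effect_separates_treated_samples_on_axis_one(self):
        cfg = SimulationConfig(seed=5, n_genes=600, n_motifs=50, delta=2.0)
        tables = simulate_motif_tables(cfg)
        expr, design, truth = simulate_expression(cfg, tables)
        line_ids = design.table.loc[
            design.table["cell_line"] == "BT474", "sample_id"
        ].tolist()
        sub = expr.subset_samples(line_ids)
        res = unsupervised_projection(
            sub, next(t for t in tables if t.threshold_label == "0.8")
        )
        responsive = set(truth["responsive_samples"])
        mask = np.array([s in responsive for s in sub.sample_ids])
        axis = res.array_loadings[:, 0]
        dist = abs(axis[mask].mean() - axis[~mask].mean())
        spread = np.sqrt(
            (axis[mask].var(ddof=1) + axis[~mask].var(ddof=1)) / 2.0
        )
        assert dist > 2.0 * spread

    def test_pure_noise_shows_no_comparison_aligned_axis(self):
        hits = 0
        for seed in range(50):
            cfg = SimulationConfig(
                seed=seed, n_genes=300, n_motifs=40, delta=0.0
            )
            tables = simulate_motif_tables(cfg)
            expr, design, truth = simulate_expression(cfg, tables)
            ids = design.table.loc[
                design.table["cell_line"] == "BT474", "sample_id"
            ].tolist()
            sub = expr.subset_samples(ids)
            res = unsupervised_projection(
                sub, next(t for t in tables if t.threshold_label == "0.8")
            )
            responsive = set(truth["responsive_samples"])
            indicator = np.array(
                [s in responsive for s in sub.sample_ids], dtype=float
            )
            corr = np.corrcoef(res.array_loadings[:, 0], indicator)[0, 1]
            hits += abs(corr) < 0.5
        assert hits >= 45  # >= 90% of 50 seeds

    def test_motif_loading_rows_match_motif_count(self, small_sim):
        _, tables, expr, design, _ = small_sim
        ids = design.table.loc[
            design.table["cell_line"] == "SKBR3", "sample_id"
        ].tolist()
        res = unsupervised_projection(expr.subset_samples(ids), tables[2])
        assert res.motif_loadings.shape[0] == len(tables[2].motif_ids)

    def test_unaligned_inputs_raise(self, small_sim):
        _, tables, expr, _, _ = small_sim
        with pytest.raises(DataError, match="align"):
            unsupervised_projection(
                expr.subset_genes(expr.gene_ids[:10]), tables[0]
            )


class TestSupervised:
    def test_two_groups_leave_exactly_one_non_null_axis(self):
        expr, motifs, design, comp = _planted_setup(noise=0.2)
        ranked = supervised_motif_ranking(expr, motifs, design, comp)
        assert ranked.coinertia.n_nonnull_axes == 1

    def test_swapping_groups_negates_scores_and_reverses_ranking(self):
        expr, motifs, design, comp = _planted_setup(noise=0.2)
        swapped = ComparisonSpec(comp.name, comp.cell_line, comp.group2, comp.group1)
        fwd = supervised_motif_ranking(expr, motifs, design, comp)
        rev = supervised_motif_ranking(expr, motifs, design, swapped)
        assert fwd.motif_ids == rev.motif_ids[::-1]
        assert np.allclose(np.sort(fwd.scores), np.sort(-rev.scores), atol=1e-10)

    def test_noiseless_planted_driver_ranks_first(self):
        expr, motifs, design, comp = _planted_setup(noise=0.0)
        ranked = supervised_motif_ranking(expr, motifs, design, comp)
        assert ranked.motif_ids[0] == "M3"
        assert ranked.scores[0] > 0

    def test_all_zero_motif_scores_zero_without_disturbing_others(self):
        expr, motifs, design, comp = _planted_setup(noise=0.1)
        base = supervised_motif_ranking(expr, motifs, design, comp)
        counts = np.column_stack([motifs.counts, np.zeros(len(motifs.gene_ids), int)])
        extended = MotifIncidenceTable(
            motifs.gene_ids, motifs.motif_ids + ["Mzero"], counts, "0.8"
        )
        ranked = supervised_motif_ranking(expr, extended, design, comp)
        idx = ranked.motif_ids.index("Mzero")
        assert ranked.scores[idx] == pytest.approx(0.0, abs=1e-10)
        without = [m for m in ranked.motif_ids if m != "Mzero"]
        assert without == base.motif_ids


def test_coinertia_estimator_matches_functional_route(rng):
    X = random_nonneg_table(rng, 10, 6)
    Y = random_nonneg_table(rng, 10, 4)
    est = CoInertiaAnalysis().fit(X, Y)
    ddA = nsc(X)
    ddB = nsc(Y, row_weights=ddA.row_weights)
    res = cia(ddA, ddB)
    assert np.allclose(est.singular_values_, res.singular_values, atol=1e-12)
    assert est.rv_ == pytest.approx(res.rv, abs=1e-12)
    assert clone(CoInertiaAnalysis(n_components=2)).get_params() == {
        "n_components": 2
    }
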