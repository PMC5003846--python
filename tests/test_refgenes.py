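import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cocount.simulate as sim
from cocount import (
    ExpressionMatrix,
    design_panel,
    expression_logfc,
    expression_screen,
    normalize,
    stability_screen,
)


class TestStabilityScreen:
    def test_constant_gene_has_zero_sd_and_is_stable(self, small_expression):
        report = stability_screen(small_expression)
        assert report.table.loc["CONST", "sd"] == 0.0
        assert report.table.loc["CONST", "stable"]

    def test_alternating_gene_not_stable(self):
        values = pd.DataFrame(
            [[6.0, 7.0, 6.0, 7.0, 6.0, 7.0], [5.0, 5.0, 5.0, 5.0, 5.0, 5.0]],
            index=pd.Index(["ALT6", "FLAT"], name="gene"),
            columns=[f"s{i}" for i in range(6)],
        )
        report = stability_screen(ExpressionMatrix(values=values))
        # sample SD of 6,7,6,7,6,7 is sqrt(0.3) ~ 0.5477
        assert report.table.loc["ALT6", "sd"] == pytest.approx(np.sqrt(0.3))
        assert not report.table.loc["ALT6", "stable"]

    def test_threshold_is_strict(self, small_expression):
        report = stability_screen(small_expression)
        sd_alt = report.table.loc["ALT", "sd"]
        at_boundary = stability_screen(small_expression, sd_threshold=sd_alt)
        assert not at_boundary.table.loc["ALT", "stable"]  # sd == threshold: not stable

    def test_sorted_by_sd_then_mean_then_name(self, small_expression):
        table = stability_screen(small_expression).table
        assert list(table["sd"]) == sorted(table["sd"])

    def test_gene_with_fewer_than_two_observations_excluded(self):
        values = pd.DataFrame(
            [[5.0, np.nan, np.nan], [4.0, 4.5, 4.2]],
            index=pd.Index(["LONELY", "OK"], name="gene"),
            columns=["a", "b", "c"],
        )
        report = stability_screen(ExpressionMatrix(values=values), max_missing=1.0)
        assert "LONELY" in report.excluded.index
        assert "fewer than 2" in report.excluded.loc["LONELY", "reason"]
        assert "LONELY" not in report.table.index

    def test_permuting_samples_changes_nothing(self, small_expression):
        report = stability_screen(small_expression)
        shuffled = ExpressionMatrix(
            values=small_expression.values[["d", "b", "a", "c"]],
            samples=small_expression.samples.loc[["d", "b", "a", "c"]],
        )
        pd.testing.assert_frame_equal(report.table, stability_screen(shuffled).table)

    def test_planted_stable_genes_recovered_among_fixed_noise(self):
        # 100 genes at sigma 0.05 among 900 at sigma 0.6, 12 samples
        design = sim.make_design(conditions=("untreated", "CTL"), replicates=2)
        truth = sim.genomewide_truth(
            design, seed=3, sigma_log_median=0.6, sigma_sdlog=1e-9, n_up=0, n_down=0
        )
        expr = sim.simulate_expression_matrix(truth)
        called = set(stability_screen(expr).stable_genes)
        truly = set(truth.gene_params.index[truth.gene_params["gene_class"] == "stable"])
        recall = len(called & truly) / len(truly)
        precision = len(called & truly) / len(called)
        assert recall >= 0.95
        assert precision >= 0.95


@pytest.fixture(scope="module")
def normalized_sim():
    design = sim.make_design(replicates=3)
    truth = sim.panel_truth(design, seed=9)
    run = sim.simulate_panel(truth)
    return truth, run, normalize(run, list(sim.HK_USABLE))


@pytest.fixture(scope="module")
def genomewide():
    truth = sim.genomewide_truth(seed=21)
    expr = sim.simulate_expression_matrix(truth)
    fc = expression_logfc(expr.values, expr.samples, "CTL", "untreated")
    return truth, expr, fc


class TestExpressionScreen:
    @staticmethod
    def _with_linear(result, gene, values):
        import dataclasses

        linear = result.linear_values.copy()
        linear.loc[gene] = values
        return dataclasses.replace(result, linear_values=linear)

    def test_background_level_candidates_flagged(self, normalized_sim):
        truth, run, result = normalized_sim
        candidates = list(sim.HK_USABLE) + list(sim.HK_LOW)
        usable, too_low = expression_screen(candidates, result)
        assert set(too_low) == set(sim.HK_LOW)
        assert set(usable) == set(sim.HK_USABLE)

    def test_all_missing_candidate_is_too_low(self, normalized_sim):
        _, _, result = normalized_sim
        gene = result.linear_values.index[0]
        modified = self._with_linear(result, gene, np.nan)
        usable, too_low = expression_screen([gene], modified, floor=0.0)
        assert too_low == [gene]

    def test_direct_floor_comparison(self, normalized_sim):
        _, _, result = normalized_sim
        gene = result.linear_values.index[0]
        modified = self._with_linear(result, gene, 500.0)
        usable, too_low = expression_screen([gene], modified, floor=20.0)
        assert usable == [gene]

    def test_absent_candidate_named(self, normalized_sim):
        _, _, result = normalized_sim
        with pytest.raises(ValueError, match="NOPE"):
            expression_screen(["NOPE"], result)

    @settings(derandomize=True, max_examples=25)
    @given(
        floor_lo=st.floats(0, 100),
        floor_hi=st.floats(0, 5000),
    )
    def test_monotone_in_floor(self, normalized_sim, floor_lo, floor_hi):
        """Raising the floor never moves a gene from too_low to usable."""
        _, _, result = normalized_sim
        lo, hi = sorted([floor_lo, floor_hi])
        candidates = list(sim.HK_USABLE) + list(sim.HK_LOW)
        usable_lo, _ = expression_screen(candidates, result, floor=lo)
        usable_hi, _ = expression_screen(candidates, result, floor=hi)
        assert set(usable_hi) <= set(usable_lo)


class TestDesignPanel:
    def test_forced_choice_selects_all_flat_stable_genes(self):
        rng = np.random.default_rng(0)
        flat = [f"FLAT{i}" for i in range(5)]
        noisy = [f"NOISY{i}" for i in range(20)]
        rows = [np.full(6, 4.0 + 2 * i) + rng.normal(0, 0.01, 6) for i in range(5)]
        rows += [rng.normal(8, 1.0, 6) for _ in range(20)]
        values = pd.DataFrame(
            rows, index=pd.Index(flat + noisy, name="gene"),
            columns=[f"s{i}" for i in range(6)],
        )
        samples = pd.DataFrame(
            {"condition": ["untreated", "CTL"] * 3, "cell_line": "Me275"},
            index=values.columns,
        )
        expr = ExpressionMatrix(values=values, samples=samples)
        fc = expression_logfc(expr.values, samples, "CTL", "untreated")
        design = design_panel(expr, fc, n_targets=10, n_norm=5, seed=1)
        assert set(design.normalization_genes) == set(flat)

    def test_every_occupied_stratum_represented(self, genomewide):
        _, expr, fc = genomewide
        design = design_panel(expr, fc, n_targets=185, n_norm=8, seed=4)
        assert len(design.targets) == 185
        assert len(design.normalization_genes) == 8
        targets = design.table[design.table["role"] == "target"]
        pool = expr.values.index.difference(design.normalization_genes)
        mean_expr = expr.values.loc[pool].mean(axis=1)
        mean_fc = fc.mean_logfc.loc[pool]
        from cocount.refgenes import _grid_bins

        occupied = set(
            zip(_grid_bins(mean_expr, design.n_expr_bins), _grid_bins(mean_fc, design.n_fc_bins))
        )
        covered = set(zip(targets["expr_bin"], targets["fc_bin"]))
        assert covered == occupied

    def test_normalization_genes_are_flat(self, genomewide, recwarn):
        _, expr, fc = genomewide
        design = design_panel(expr, fc, n_targets=50, n_norm=5, seed=4)
        assert (design.table.loc[design.normalization_genes, "mean_logfc"].abs() < 0.25).all()

    def test_requesting_too_many_genes_errors(self, genomewide):
        _, expr, fc = genomewide
        with pytest.raises(ValueError):
            design_panel(expr, fc, n_targets=5000, n_norm=8)

    def test_shortfall_of_normalization_genes_warns(self):
        rng = np.random.default_rng(2)
        values = pd.DataFrame(
            rng.normal(8, 1.0, size=(30, 6)),
            index=pd.Index([f"N{i}" for i in range(30)], name="gene"),
            columns=[f"s{i}" for i in range(6)],
        )
        samples = pd.DataFrame(
            {"condition": ["untreated", "CTL"] * 3, "cell_line": "x"},
            index=values.columns,
        )
        expr = ExpressionMatrix(values=values, samples=samples)
        fc = expression_logfc(expr.values, samples, "CTL", "untreated")
        with pytest.warns(UserWarning, match="normalization genes"):
            design = design_panel(expr, fc, n_targets=5, n_norm=5, seed=0)
        assert len(design.normalization_genes) < 5
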