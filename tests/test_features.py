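"""Tests for panel selection and cell-centered scoring."""

import logging

import numpy as np
import pandas as pd
import pytest

import benfordexpr as bx
from benfordexpr.errors import EmptyPanelError
from benfordexpr.features import build_group_panels, check_labels, panel_overlap

E = bx.benford_expected().E


def matrix_from(arr, genes=None, samples=None, kind="normalized"):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return bx.ExpressionMatrix(
        values=pd.DataFrame(arr, index=genes, columns=samples), value_kind=kind
    )


def labels_for(m, groups):
    return pd.Series(groups, index=m.sample_ids, name="group")


def point_mass_mae(d):
    """Independent oracle: MAE of a distribution concentrated on digit d."""
    return (abs(1 - E[d - 1]) + sum(E[i] for i in range(9) if i != d - 1)) / 9


class TestGeneCentered:
    def test_constant_gene_is_point_mass(self):
        m = matrix_from(np.full((1, 50), 7.0))
        lab = labels_for(m, ["grp"] * 50)
        score = bx.gene_centered_mae(m, lab, "grp")
        assert score["g0"] == pytest.approx(point_mass_mae(7), abs=1e-12)
        # frozen from the 9-term oracle: 2 * (1 - log10(8/7)) / 9
        assert score["g0"] == pytest.approx(0.2093351, abs=1e-6)

    def test_uniform_digit_gene(self):
        values = np.tile(np.arange(1.0, 10.0), 1000)[None, :]
        m = matrix_from(values)
        lab = labels_for(m, ["grp"] * values.shape[1])
        score = bx.gene_centered_mae(m, lab, "grp")
        assert score["g0"] == pytest.approx(np.abs(1 / 9 - E).mean(), abs=1e-12)
        assert score["g0"] == pytest.approx(0.059717, abs=1e-6)

    def test_benford_gene_has_near_zero_mae(self):
        rng = np.random.default_rng(0)
        m = matrix_from(10.0 ** rng.uniform(0, 3, size=(1, 100_000)))
        lab = labels_for(m, ["grp"] * m.shape[1])
        assert bx.gene_centered_mae(m, lab, "grp")["g0"] < 0.01

    def test_eligibility_minimum(self):
        arr = np.zeros((2, 20))
        arr[0] = 3.0
        arr[1, :5] = 3.0  # only 5 nonzero values
        m = matrix_from(arr)
        lab = labels_for(m, ["grp"] * 20)
        score = bx.gene_centered_mae(m, lab, "grp", min_nonzero=10)
        assert not np.isnan(score["g0"]) and np.isnan(score["g1"])

    def test_mean_exp_includes_zeros(self):
        m = matrix_from([[0.0, 0.0, 6.0], [5.0, 5.0, 5.0]])
        lab = labels_for(m, ["grp"] * 3)
        means = bx.gene_centered_mean_exp(m, lab, "grp")
        assert means["g0"] == 2.0 and means["g1"] == 5.0

    def test_empty_group_raises(self):
        m = matrix_from(np.ones((2, 3)))
        lab = labels_for(m, ["a", "a", "a"])
        with pytest.raises(ValueError):
            bx.gene_centered_mae(m, lab, "missing")


class TestSelectTopK:
    def test_basic_directions(self):
        scores = pd.Series({"g1": 0.1, "g2": 0.3, "g3": 0.2})
        assert bx.select_top_k(scores, 2, "highest").genes == ("g2", "g3")
        assert bx.select_top_k(scores, 2, "lowest").genes == ("g1", "g3")

    def test_k_larger_than_eligible(self):
        scores = pd.Series({"g1": 0.1, "g2": np.nan})
        panel = bx.select_top_k(scores, 10, "highest")
        assert panel.genes == ("g1",)

    def test_all_missing_raises(self):
        with pytest.raises(EmptyPanelError):
            bx.select_top_k(pd.Series({"g1": np.nan}), 1, "highest")

    def test_matches_sorted_pairs_oracle_with_ties(self):
        rng = np.random.default_rng(1)
        values = rng.integers(0, 50, size=10_000) / 50.0  # many planted ties
        scores = pd.Series(values, index=[f"g{i:05d}" for i in range(10_000)])
        panel = bx.select_top_k(scores, 300, "highest")
        oracle = [g for _, g in sorted(zip(-scores, scores.index))][:300]
        assert list(panel.genes) == oracle

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        scores = pd.Series(rng.random(500), index=[f"g{i}" for i in range(500)])
        a = bx.select_top_k(scores, 50, "lowest")
        b = bx.select_top_k(scores.sample(frac=1, random_state=3), 50, "lowest")
        assert a.genes == b.genes


class TestDeTtest:
    def test_welch_example(self):
        arr = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        m = matrix_from(arr)
        lab = labels_for(m, ["f", "f", "f", "r", "r", "r"])
        de = bx.de_ttest(m, lab, "f")
        assert de.loc["g0", "t_stat"] == pytest.approx(-3.674, abs=1e-3)
        assert de.loc["g0", "p_value"] == pytest.approx(0.0213, abs=1e-3)
        assert de.loc["g0", "sign"] == -1

    def test_null_gene_large_n(self):
        rng = np.random.default_rng(3)
        m = matrix_from(rng.normal(10, 1, size=(1, 2000)).clip(min=0))
        lab = labels_for(m, ["f"] * 1000 + ["r"] * 1000)
        assert bx.de_ttest(m, lab, "f").loc["g0", "p_value"] > 0.01

    def test_shifted_gene_detected(self):
        rng = np.random.default_rng(4)
        vals = np.concatenate([rng.normal(15, 1, 50), rng.normal(10, 1, 200)])
        m = matrix_from(vals[None, :].clip(min=0))
        lab = labels_for(m, ["f"] * 50 + ["r"] * 200)
        de = bx.de_ttest(m, lab, "f")
        assert de.loc["g0", "p_value"] < 1e-6 and de.loc["g0", "sign"] == 1

    def test_small_group_raises_with_name(self):
        m = matrix_from(np.ones((1, 4)))
        lab = labels_for(m, ["f", "r", "r", "r"])
        with pytest.raises(ValueError, match="'f'"):
            bx.de_ttest(m, lab, "f")


class TestSelectDe:
    def test_alpha_and_ranking(self):
        de = pd.DataFrame(
            {"p_value": [0.01, 0.2, 0.04], "t_stat": [3.0, 1.0, -2.0], "sign": [1, 1, -1]},
            index=["gene1", "gene2", "gene3"],
        )
        panel = bx.select_de(de, 2, alpha=0.05)
        assert panel.genes == ("gene1", "gene3")
        assert panel.signs == (1, -1)

    def test_nothing_passes_raises(self):
        de = pd.DataFrame(
            {"p_value": [0.2, 0.9], "t_stat": [1.0, 0.1], "sign": [1, 1]},
            index=["a", "b"],
        )
        with pytest.raises(EmptyPanelError):
            bx.select_de(de, 5, alpha=0.05)

    def test_null_type_one_error_rate(self):
        rng = np.random.default_rng(5)
        m = matrix_from(rng.normal(20, 2, size=(5000, 60)).clip(min=0))
        lab = labels_for(m, ["f"] * 30 + ["r"] * 30)
        de = bx.de_ttest(m, lab, "f")
        n_pass = int((de["p_value"] <= 0.05).sum())
        # Binomial(5000, 0.05): mean 250, sd 15.4; allow +-4 sd
        assert 188 <= n_pass <= 312


class TestCellCentered:
    def test_uniform_digit_cell(self):
        m = matrix_from(np.arange(1.0, 10.0)[:, None])
        panel = bx.GenePanel(
            group="grp", genes=tuple(m.gene_ids), mode="high_mae", k_requested=9
        )
        score = bx.cell_centered_mae(m, panel)
        assert score["s0"] == pytest.approx(0.059717, abs=1e-6)

    def test_all_zero_cell_gets_max_mae(self, caplog):
        arr = np.array([[1.0, 0.0], [2.0, 0.0]])
        m = matrix_from(arr)
        panel = bx.GenePanel(group="grp", genes=("g0", "g1"), mode="high_mae", k_requested=2)
        with caplog.at_level(logging.WARNING):
            score = bx.cell_centered_mae(m, panel)
        assert score["s1"] == pytest.approx(bx.MAX_MAE, abs=1e-12)
        assert "maximum MAE" in caplog.text

    def test_benford_proportional_cell_is_near_zero(self):
        counts = np.round(E * 100_000).astype(int)
        values = np.repeat(np.arange(1.0, 10.0), counts)
        m = matrix_from(values[:, None])
        panel = bx.GenePanel(
            group="grp", genes=tuple(m.gene_ids), mode="high_mae",
            k_requested=len(values),
        )
        assert bx.cell_centered_mae(m, panel)["s0"] < 1e-5

    def test_missing_panel_gene_raises(self):
        m = matrix_from(np.ones((2, 2)))
        panel = bx.GenePanel(group="grp", genes=("g0", "nope"), mode="high_mae", k_requested=2)
        with pytest.raises(KeyError, match="nope"):
            bx.cell_centered_mae(m, panel)

    def test_mean_exp(self):
        m = matrix_from([[2.0, 0.0], [4.0, 0.0]])
        panel = bx.GenePanel(group="grp", genes=("g0", "g1"), mode="low_exp", k_requested=2)
        score = bx.cell_centered_mean_exp(m, panel)
        assert score["s0"] == 3.0 and score["s1"] == 0.0

    def test_full_matrix_mae_matches_core(self):
        rng = np.random.default_rng(6)
        arr = rng.poisson(30, size=(200, 5)).astype(float)
        m = matrix_from(arr)
        panel = bx.GenePanel(
            group="grp", genes=tuple(m.gene_ids), mode="high_mae", k_requested=200
        )
        score = bx.cell_centered_mae(m, panel)
        for j, s in enumerate(m.sample_ids):
            expected = bx.mae(bx.to_distribution(bx.digit_histogram(arr[:, j])))
            assert score[s] == pytest.approx(expected, abs=1e-12)


class TestPolygenicScore:
    def test_signed_sum(self):
        m = matrix_from([[5.0], [2.0], [7.0]])
        panel = bx.GenePanel(
            group="grp", genes=("g0", "g1", "g2"), mode="de",
            k_requested=3, signs=(1, -1, 1),
        )
        assert bx.polygenic_score(m, panel)["s0"] == 10.0

    def test_zero_expression_and_oracle(self):
        rng = np.random.default_rng(7)
        arr = rng.random((200, 10))
        m = matrix_from(arr)
        signs = tuple(int(s) for s in rng.choice([-1, 1], 200))
        panel = bx.GenePanel(
            group="grp", genes=tuple(m.gene_ids), mode="de",
            k_requested=200, signs=signs,
        )
        ps = bx.polygenic_score(m, panel)
        oracle = (np.array(signs)[:, None] * arr).sum(axis=0)
        assert np.allclose(ps.to_numpy(), oracle)

        zero = matrix_from(np.zeros((200, 2)), genes=list(m.gene_ids))
        assert (bx.polygenic_score(zero, panel) == 0).all()

    def test_requires_signs(self):
        m = matrix_from(np.ones((1, 1)))
        panel = bx.GenePanel(group="grp", genes=("g0",), mode="high_mae", k_requested=1)
        with pytest.raises(ValueError):
            bx.polygenic_score(m, panel)


class TestScoreMatrix:
    def test_shape_and_column_order(self, default_normalized):
        m, truth = default_normalized
        panels = build_group_panels(m, truth.labels, "high_mae", k=50)
        scores = bx.build_score_matrix(m, panels)
        assert scores.shape == (1018, 6)
        assert list(scores.columns) == sorted(truth.labels.unique())

    def test_single_group_column_equals_per_cell_score(self):
        rng = np.random.default_rng(8)
        m = matrix_from(rng.random((20, 5)) + 0.1)
        panel = bx.GenePanel(
            group="only", genes=tuple(m.gene_ids[:10]), mode="high_mae", k_requested=10
        )
        scores = bx.build_score_matrix(m, {"only": panel})
        pd.testing.assert_series_equal(
            scores["only"], bx.cell_centered_mae(m, panel), check_names=False
        )

    def test_mixed_modes_rejected(self):
        m = matrix_from(np.ones((2, 2)) * 3)
        pa = bx.GenePanel(group="a", genes=("g0",), mode="high_mae", k_requested=1)
        pb = bx.GenePanel(group="b", genes=("g1",), mode="low_exp", k_requested=1)
        with pytest.raises(ValueError, match="mix"):
            bx.build_score_matrix(m, {"a": pa, "b": pb})

    def test_focus_column_separates_focus_from_rest(self, small_normalized):
        m, truth = small_normalized
        panels = build_group_panels(m, truth.labels, "high_mae", k=30)
        scores = bx.build_score_matrix(m, panels)
        for group in panels:
            p = bx.wilcoxon_focus_vs_rest(scores[group], truth.labels, group)
            assert p < 1e-6


class TestPanelProperties:
    def test_panels_deterministic(self, small_normalized):
        m, truth = small_normalized
        a = build_group_panels(m, truth.labels, "high_mae", k=30)
        b = build_group_panels(m, truth.labels, "high_mae", k=30)
        assert {g: p.genes for g, p in a.items()} == {g: p.genes for g, p in b.items()}

    def test_overlap_report_high_mae_low_exp_dominates(self, default_normalized):
        # Benford-deviant genes are the lowly expressed narrow ones, so the
        # high-MAE and low-mean-expression panels pick largely the same
        # genes, while the DE route finds a different family.
        m, truth = default_normalized
        panels = {
            mode: build_group_panels(m, truth.labels, mode)
            for mode in ("high_mae", "low_exp", "de")
        }
        overlap = panel_overlap(panels)
        pivot = overlap.set_index(["group", "mode_a", "mode_b"])["n_overlap"]
        for group in sorted(truth.labels.unique()):
            winner = pivot[group, "high_mae", "low_exp"]
            assert winner >= 150
            assert winner > pivot[group, "de", "high_mae"]
            assert winner > pivot[group, "de", "low_exp"]

    def test_high_mae_genes_are_narrow_and_low(self, default_normalized):
        # High-MAE genes have narrow, low expression distributions; low-MAE
        # genes are broad and highly expressed.
        m, truth = default_normalized
        group = "hESC"
        scores = bx.gene_centered_mae(m, truth.labels, group).dropna()
        cols = truth.labels.index[truth.labels == group]
        sub = m.values.loc[scores.index, cols]
        high = sub.loc[scores.sort_values(ascending=False).head(200).index]
        low = sub.loc[scores.sort_values().head(200).index]
        assert high.mean(axis=1).median() < low.mean(axis=1).median()
        spread = lambda block: (block.quantile(0.95, axis=1) - block.quantile(0.05, axis=1)).median()
        assert spread(high) < spread(low)

    def test_check_labels_reports_mismatch(self):
        labels = pd.Series({"s1": "a", "s2": "b"})
        with pytest.raises(ValueError, match="s3"):
            check_labels(labels, ["s1", "s2", "s3"])
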