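"""Expression loading, edge correlations, differential expression."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mgnet import (ExpressionMatrix, InteractionNetwork, Module,
                   classify_correlations, collapse_probes, correlate_edges,
                   differential_expression, load_expression,
                   module_expression_report, pearson_pvalue)


def make_matrix(values: np.ndarray, genes, n_disease, n_control) -> ExpressionMatrix:
    samples = [f"D{i:02d}" for i in range(n_disease)] \
        + [f"C{i:02d}" for i in range(n_control)]
    group = {s: ("disease" if s.startswith("D") else "control") for s in samples}
    return ExpressionMatrix(values=pd.DataFrame(values, index=list(genes),
                                                columns=samples), group=group)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

class TestLoadExpression:
    def test_plain_tsv_dimensions(self, tmp_path):
        f = tmp_path / "expr.tsv"
        f.write_text("gene\tS1\tS2\tS3\tS4\n"
                     "A\t1\t2\t3\t4\nB\t5\t6\t7\t8\nC\t9\t8\t7\t6\n")
        labels = {"S1": "disease", "S2": "disease", "S3": "control",
                  "S4": "control"}
        mat = load_expression(f, "plain-tsv", labels=labels)
        assert mat.values.shape == (3, 4)
        assert mat.group_samples("disease") == ["S1", "S2"]

    def test_series_matrix_parses_only_table_block(self, tmp_path):
        f = tmp_path / "series.txt"
        f.write_text(
            '!Series_title\t"synthetic fixture"\n'
            '!Sample_geo_accession\t"GSM1"\t"GSM2"\n'
            "!series_matrix_table_begin\n"
            '"ID_REF"\t"GSM1"\t"GSM2"\n'
            '"A"\t1.5\t2.5\n'
            '"B"\t3.5\t4.5\n'
            "!series_matrix_table_end\n")
        labels = {"GSM1": "disease", "GSM2": "control"}
        mat = load_expression(f, "series-matrix", labels=labels)
        assert list(mat.genes) == ["A", "B"]
        assert mat.values.loc["A", "GSM2"] == 2.5

    def test_na_cell_becomes_missing_and_pairwise_complete_used(self, tmp_path):
        f = tmp_path / "expr.tsv"
        f.write_text("gene\tD1\tD2\tD3\tD4\tD5\n"
                     "A\t1\t2\tNA\t4\t5\nB\t2\t4\t6\t8\t10\n")
        labels = {f"D{i}": "disease" for i in range(1, 6)}
        mat = load_expression(f, "plain-tsv", labels=labels)
        assert math.isnan(mat.values.loc["A", "D3"])
        net = InteractionNetwork.from_edges([("A", "B")])
        rec = correlate_edges(net, mat, group="disease")[0]
        # hand-filtered complete pairs: (1,2),(2,4),(4,8),(5,10) -> r = 1
        assert rec.n == 4
        assert rec.r == pytest.approx(1.0)
        assert rec.degenerate

    def test_non_numeric_cell_reports_coordinates(self, tmp_path):
        f = tmp_path / "expr.tsv"
        f.write_text("gene\tS1\tS2\nA\t1\toops\n")
        with pytest.raises(ValueError, match="S2"):
            load_expression(f, "plain-tsv", labels={"S1": "disease",
                                                    "S2": "control"})

    def test_unlabeled_sample_rejected(self, tmp_path):
        f = tmp_path / "expr.tsv"
        f.write_text("gene\tS1\tS2\nA\t1\t2\n")
        with pytest.raises(ValueError, match="without a group label"):
            load_expression(f, "plain-tsv", labels={"S1": "disease"})


class TestCollapseProbes:
    def setup_method(self):
        self.mat = make_matrix(
            np.array([[5.0, 5, 5, 5], [7.0, 7, 7, 7], [1.0, 3, 5, 7]]),
            genes=["P1", "P2", "P3"], n_disease=2, n_control=2)
        self.mapping = {"P1": "G", "P2": "G", "P3": "H"}

    def test_max_mean_probe_keeps_highest(self):
        out = collapse_probes(self.mat, self.mapping, "max-mean-probe")
        assert list(out.values.loc["G"]) == [7.0, 7, 7, 7]

    def test_mean_averages_elementwise(self):
        out = collapse_probes(self.mat, self.mapping, "mean")
        assert list(out.values.loc["G"]) == [6.0, 6, 6, 6]

    def test_matches_groupby_oracle(self, rng):
        values = rng.normal(size=(10, 4))
        probes = [f"P{i}" for i in range(10)]
        mapping = {p: f"G{i % 4}" for i, p in enumerate(probes)}
        mat = make_matrix(values, probes, 2, 2)
        out = collapse_probes(mat, mapping, "mean")
        for gene in sorted(set(mapping.values())):
            rows = [i for i, p in enumerate(probes) if mapping[p] == gene]
            expected = values[rows].mean(axis=0)
            assert np.allclose(out.values.loc[gene].to_numpy(), expected)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

class TestEdgeCorrelations:
    def test_matches_scipy_pearsonr(self, rng):
        for _ in range(20):
            x = rng.normal(size=21)
            y = rng.normal(size=21)
            r_ref, p_ref = stats.pearsonr(x, y)
            mat = make_matrix(np.vstack([x, y]), ["A", "B"], 21, 0)
            net = InteractionNetwork.from_edges([("A", "B")])
            rec = correlate_edges(net, mat, group="disease")[0]
            assert rec.r == pytest.approx(r_ref, abs=1e-10)
            assert rec.p == pytest.approx(p_ref, rel=1e-8)

    def test_p_symmetric_and_monotone_in_abs_r(self):
        rs = [0.1, 0.3, 0.5, 0.7, 0.9]
        ps = [pearson_pvalue(r, 21) for r in rs]
        assert ps == sorted(ps, reverse=True)
        for r in rs:
            assert pearson_pvalue(r, 21) == pearson_pvalue(-r, 21)

    def test_identical_vectors_degenerate(self):
        x = np.arange(10.0)
        mat = make_matrix(np.vstack([x, x]), ["A", "B"], 10, 0)
        net = InteractionNetwork.from_edges([("A", "B")])
        rec = correlate_edges(net, mat, group="disease")[0]
        assert rec.degenerate and rec.valid
        assert 0 < rec.p <= np.finfo(float).tiny

    def test_zero_variance_gene_flagged_invalid(self):
        mat = make_matrix(np.array([[1.0, 1, 1, 1, 1],
                                    [1.0, 2, 3, 4, 5]]), ["A", "B"], 5, 0)
        net = InteractionNetwork.from_edges([("A", "B")])
        rec = correlate_edges(net, mat, group="disease")[0]
        assert not rec.valid

    def test_missing_gene_reported_uncomputed(self, rng):
        mat = make_matrix(rng.normal(size=(1, 6)), ["A"], 6, 0)
        net = InteractionNetwork.from_edges([("A", "ZZZ")])
        rec = correlate_edges(net, mat, group="disease")[0]
        assert not rec.valid and rec.n == 0

    def test_group_too_small_raises(self, rng):
        mat = make_matrix(rng.normal(size=(2, 5)), ["A", "B"], 3, 2)
        net = InteractionNetwork.from_edges([("A", "B")])
        with pytest.raises(ValueError, match=">= 4"):
            correlate_edges(net, mat, group="disease")


class TestClassifyCorrelations:
    def test_rule_application(self):
        from mgnet import EdgeCorrelation
        recs = [
            EdgeCorrelation(("A", "B"), r=0.6, n=21, p=0.01, significant=True,
                            strong=True),
            EdgeCorrelation(("C", "D"), r=-0.3, n=21, p=0.04, significant=True,
                            strong=False),
            EdgeCorrelation(("E", "F"), r=0.9, n=21, p=0.2, significant=False,
                            strong=True),
        ]
        s = classify_correlations(recs, alpha=0.05, strong_threshold=0.5)
        assert s.significant_count == 2
        assert s.strong_among_significant == 1
        assert s.strong_share == pytest.approx(0.5)
        assert s.positive_significant == 1 and s.negative_significant == 1

    def test_empty_list_all_zero(self):
        s = classify_correlations([])
        assert s.computed_edges == 0 and s.significant_share == 0.0


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

class TestDifferentialExpression:
    def test_identical_groups_not_differential(self):
        row = np.array([1.0, 2, 3, 1, 2, 3])
        mat = make_matrix(row[None, :], ["A"], 3, 3)
        rec = differential_expression(mat)[0]
        assert rec.p == pytest.approx(1.0)
        assert not rec.differential

    def test_hand_computed_t_and_direction(self):
        mat = make_matrix(np.array([[5.0, 6, 7, 1, 2, 3]]), ["A"], 3, 3)
        rec = differential_expression(mat, variant="student")[0]
        # pooled s² = 1, t = (6-2) / sqrt(1*(1/3+1/3)) = 4.898979..., df = 4
        t_hand = 4.0 / math.sqrt(2.0 / 3.0)
        p_hand = 2 * stats.t.sf(t_hand, 4)
        assert rec.t_statistic == pytest.approx(t_hand)
        assert rec.p == pytest.approx(p_hand)
        assert rec.direction == "up" and rec.differential

    def test_label_swap_flips_t_and_direction_keeps_p(self, rng):
        values = rng.normal(size=(5, 10))
        values[2, :5] += 2.0
        mat = make_matrix(values, [f"G{i}" for i in range(5)], 5, 5)
        swapped_group = {s: ("control" if g == "disease" else "disease")
                         for s, g in mat.group.items()}
        mat_sw = ExpressionMatrix(values=mat.values.copy(), group=swapped_group)
        for a, b in zip(differential_expression(mat),
                        differential_expression(mat_sw)):
            assert a.t_statistic == pytest.approx(-b.t_statistic)
            assert a.p == pytest.approx(b.p)
            assert {a.direction, b.direction} == {"up", "down"} or a.p > 0.999

    def test_gene_with_too_few_observations_skipped(self):
        values = np.array([[1.0, np.nan, np.nan, 4, 5, 6],
                           [1.0, 2, 3, 4, 5, 6]])
        mat = make_matrix(values, ["A", "B"], 3, 3)
        recs = differential_expression(mat)
        assert [r.gene for r in recs] == ["B"]

    def test_welch_vs_student_variants_differ_under_unequal_variance(self, rng):
        x = np.concatenate([rng.normal(0, 5, 10), rng.normal(0, 0.5, 10)])
        mat = make_matrix(x[None, :], ["A"], 10, 10)
        p_w = differential_expression(mat, variant="welch")[0].p
        p_s = differential_expression(mat, variant="student")[0].p
        assert p_w != p_s

    def test_bh_q_at_least_p(self, rng):
        values = rng.normal(size=(50, 12))
        mat = make_matrix(values, [f"G{i}" for i in range(50)], 6, 6)
        for rec in differential_expression(mat):
            assert rec.q >= rec.p - 1e-12


class TestModuleExpressionReport:
    def test_counts_restricted_to_module(self):
        from mgnet import DiffExpressionRecord, EdgeCorrelation
        dex = [
            DiffExpressionRecord("A", 2, 1, 3.0, 0.01, 0.02, "up", True),
            DiffExpressionRecord("B", 1, 2, -3.0, 0.01, 0.02, "down", True),
            DiffExpressionRecord("C", 1, 1, 0.1, 0.9, 0.9, "up", False),
            DiffExpressionRecord("D", 3, 1, 4.0, 0.001, 0.01, "up", True),
            DiffExpressionRecord("E", 3, 1, 4.0, 0.001, 0.01, "up", True),
        ]
        cors = [EdgeCorrelation(("A", "B"), 0.8, 21, 0.001, significant=True),
                EdgeCorrelation(("A", "E"), 0.8, 21, 0.001, significant=True)]
        mod = Module(members=frozenset("ABCD"), score=2.0, rank=1)
        rep = module_expression_report(mod, dex, cors)
        assert (rep.gene_count, rep.differential_count, rep.up_count,
                rep.down_count) == (4, 3, 2, 1)
        assert [c.edge for c in rep.correlations] == [("A", "B")]

    def test_module_without_edges_still_tallies(self):
        from mgnet import DiffExpressionRecord
        dex = [DiffExpressionRecord("A", 2, 1, 3.0, 0.01, 0.02, "up", True)]
        mod = Module(members=frozenset("AB"), score=1.0, rank=2)
        rep = module_expression_report(mod, dex, [])
        assert rep.differential_count == 1 and rep.correlations == ()
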