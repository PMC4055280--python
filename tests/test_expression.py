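"""Expression parsing, expressed-gene calling, consolidation, combination."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tisnet import expression as expr
from tisnet.errors import ParseError, UnmappedSubpartError


def quant_panel(rows, dialect="rnaseq"):
    df = pd.DataFrame(rows, columns=expr.QUANT_COLUMNS)
    return expr.ExpressionPanel(dialect, dialect, df)


def ihc_panel(rows):
    df = pd.DataFrame(rows, columns=expr.IHC_COLUMNS)
    return expr.ExpressionPanel("ihc", "ihc", df)


# ---------------------------------------------------------------------------
# parsing


class TestReadExpressionTable:
    def test_empty_file_with_header_gives_zero_records(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("gene_id\ttissue\tsubpart\tvalue\n")
        panel = expr.read_expression_table(p, "rnaseq")
        assert panel.records.empty

    def test_negative_value_is_a_line_numbered_error(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("gene_id\ttissue\tsubpart\tvalue\nA\tbrain\tcortex\t-1\n")
        with pytest.raises(ParseError, match="line 2"):
            expr.read_expression_table(p, "rnaseq")

    def test_non_numeric_value_is_a_line_numbered_error(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("gene_id\ttissue\tsubpart\tvalue\nA\tbrain\tcortex\t1\nB\tbrain\tcortex\thigh\n")
        with pytest.raises(ParseError, match="line 3"):
            expr.read_expression_table(p, "rnaseq")

    def test_well_formed_rows_parse_verbatim(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "gene_id\ttissue\tsubpart\tvalue\n"
            "A\tbrain\tcortex\t1.5\nB\tbrain\tcortex\t0.0\nC\tliver\tliver\t250\n"
        )
        panel = expr.read_expression_table(p, "microarray")
        assert len(panel.records) == 3
        assert panel.records["value"].tolist() == [1.5, 0.0, 250.0]
        assert panel.records["gene_id"].tolist() == ["A", "B", "C"]

    def test_bad_header_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("gene\ttissue\tvalue\n")
        with pytest.raises(ParseError, match="header"):
            expr.read_expression_table(p, "rnaseq")

    def test_unknown_ordinal_token_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "gene_id\ttissue\tsubpart\tlevel\treliability\tvalidity\n"
            "A\tbrain\tcortex\thigh\tgood\t\n"
        )
        with pytest.raises(ParseError, match="line 2"):
            expr.read_expression_table(p, "ihc")

    def test_roundtrip_through_writer(self, tmp_path):
        rows = [("A", "brain", "cortex", 1.5), ("B", "liver", "liver", 101.0)]
        panel = quant_panel(rows, "microarray")
        p = tmp_path / "rt.tsv"
        expr.write_expression_table(panel, p)
        back = expr.read_expression_table(p, "microarray")
        pd.testing.assert_frame_equal(back.records, panel.records)


# ---------------------------------------------------------------------------
# quantitative calling


class TestCallExpressedQuantitative:
    def test_microarray_threshold_is_strict(self):
        panel = quant_panel(
            [("A", "t", "s", 100.0), ("B", "t", "s", 100.5)], "microarray"
        )
        called = expr.call_expressed_quantitative(panel, 100.0)
        assert called["s"] == {"B"}

    def test_rnaseq_threshold_is_at_least(self):
        panel = quant_panel([("A", "t", "s", 1.0), ("B", "t", "s", 0.99)], "rnaseq")
        called = expr.call_expressed_quantitative(panel, 1.0)
        assert called["s"] == {"A"}

    def test_duplicate_measurements_use_highest_value(self):
        panel = quant_panel(
            [("A", "t", "s", 50.0), ("A", "t", "s", 150.0)], "microarray"
        )
        assert expr.call_expressed_quantitative(panel, 100.0)["s"] == {"A"}

    def test_ordinal_panel_is_a_type_error(self):
        panel = ihc_panel([("A", "t", "s", "high", "high", ())])
        with pytest.raises(TypeError):
            expr.call_expressed_quantitative(panel, 1.0)

    @settings(max_examples=50, deadline=None)
    @given(
        values=st.lists(st.floats(0, 1000, allow_nan=False), min_size=1, max_size=30),
        threshold=st.floats(0.1, 500),
    )
    def test_agrees_with_one_line_oracle_and_threshold_monotonicity(self, values, threshold):
        rows = [(f"G{i}", "t", "s", v) for i, v in enumerate(values)]
        panel = quant_panel(rows, "rnaseq")
        called = expr.call_expressed_quantitative(panel, threshold)["s"]
        oracle = {f"G{i}" for i, v in enumerate(values) if v >= threshold}
        assert called == oracle
        relaxed = expr.call_expressed_quantitative(panel, threshold / 2)["s"]
        assert called <= relaxed


# ---------------------------------------------------------------------------
# IHC calling


class TestCallExpressedIhc:
    @pytest.mark.parametrize(
        "level,reliability,validity,expected",
        [
            ("medium", "high", (), True),
            ("medium", "medium", ("negative",), True),    # reliability suffices
            ("high", "absent", ("supportive",), True),
            ("high", "absent", ("supportive", "negative"), False),
            ("low", "low", ("supportive", "uncertain"), True),
            ("low", "low", ("uncertain",), False),
            ("not-detected", "high", (), False),
        ],
    )
    def test_reliability_validity_rule(self, level, reliability, validity, expected):
        panel = ihc_panel([("A", "t", "s", level, reliability, validity)])
        called = expr.call_expressed_ihc(panel)
        assert ("A" in called["s"]) is expected

    def test_any_qualifying_antibody_suffices(self):
        panel = ihc_panel([
            ("A", "t", "s", "high", "absent", ("negative",)),
            ("A", "t", "s", "low", "medium", ()),
        ])
        assert expr.call_expressed_ihc(panel)["s"] == {"A"}

    def test_quantitative_panel_is_a_type_error(self):
        with pytest.raises(TypeError):
            expr.call_expressed_ihc(quant_panel([("A", "t", "s", 1.0)]))


# ---------------------------------------------------------------------------
# consolidation / combination


class TestConsolidate:
    def test_subparts_union_into_tissue_and_are_kept(self):
        scheme = expr.ConsolidationScheme(
            {("ds", "cortex"): "brain", ("ds", "cerebellum"): "brain"}
        )
        ex = expr.consolidate({"cortex": {"A"}, "cerebellum": {"B"}}, scheme, "ds")
        assert ex.tissues == {"brain": {"A", "B"}}
        assert ex.subpart_sets[("ds", "cortex")] == {"A"}
        assert ex.subpart_sets[("ds", "cerebellum")] == {"B"}

    def test_single_subpart_tissue_equals_subpart(self):
        scheme = expr.ConsolidationScheme({("ds", "liver"): "liver"})
        ex = expr.consolidate({"liver": {"A", "B"}}, scheme, "ds")
        assert ex.tissues["liver"] == {"A", "B"}

    def test_unmapped_subpart_named_in_error(self):
        scheme = expr.ConsolidationScheme({("ds", "cortex"): "brain"})
        with pytest.raises(UnmappedSubpartError, match="unmapped subpart: hippocampus"):
            expr.consolidate({"hippocampus": {"A"}}, scheme, "ds")


class TestCombineDatasets:
    def _ex(self, ds, tissues):
        scheme = expr.ConsolidationScheme({(ds, t): t for t in tissues})
        return expr.consolidate(tissues, scheme, ds)

    def test_gene_in_one_dataset_is_in_combined(self):
        a = self._ex("ma", {"brain": {"A"}})
        b = self._ex("rs", {"brain": set()})
        combined = expr.combine_datasets([a, b])
        assert combined.tissues["brain"] == {"A"}

    def test_gene_in_no_dataset_absent(self):
        combined = expr.combine_datasets([self._ex("ma", {"brain": set()})])
        assert combined.tissues["brain"] == set()

    def test_commutative_and_idempotent(self):
        a = self._ex("ma", {"brain": {"A"}, "liver": {"B"}})
        b = self._ex("rs", {"brain": {"C"}})
        ab = expr.combine_datasets([a, b])
        ba = expr.combine_datasets([b, a])
        assert ab.tissues == ba.tissues
        again = expr.combine_datasets([ab])
        assert again.tissues == ab.tissues


class TestBreadthClassify:
    def test_class_boundaries(self):
        tissues = {f"t{i}": set() for i in range(16)}
        for i in range(16):
            tissues[f"t{i}"].add("G16")
        for i in range(2):
            tissues[f"t{i}"].add("G2")
        for i in range(8):
            tissues[f"t{i}"].add("G8")
        ex = expr.Expressome("combined", tissues, {}, {})
        df = expr.breadth_classify(ex).set_index("gene_id")
        assert df.loc["G16", "n_tissues"] == 16
        assert df.loc["G16", "breadth_class"] == "global"
        assert df.loc["G2", "breadth_class"] == "specific"
        assert df.loc["G8", "breadth_class"] == "intermediate"
        hist = expr.breadth_histogram(df.reset_index())
        assert hist.loc[16] == 1 and hist.loc[2] == 1 and hist.loc[8] == 1
        assert hist.sum() == 3


# ---------------------------------------------------------------------------
# compatibility statistics


class TestCompatibilityStats:
    def test_fisher_closed_form_full_overlap(self):
        # C(5,5)*C(15,0)/C(20,5) = 1/15504
        assert expr.fisher_overlap_p(5, 5, 5, 20) == pytest.approx(1 / 15504, rel=1e-9)

    def test_fisher_empty_set_warns_and_returns_one(self):
        with pytest.warns(UserWarning):
            assert expr.fisher_overlap_p(0, 5, 0, 20) == 1.0

    def test_kendall_tau_examples(self):
        assert stats.kendalltau([1, 2, 3], [1, 3, 2]).statistic == pytest.approx(1 / 3)
        assert stats.kendalltau([1, 2, 3], [3, 2, 1]).statistic == pytest.approx(-1.0)

    def test_matching_tissues_rank_first_without_noise(self):
        # two quantitative datasets sharing the same latent per-tissue values
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(40)]
        tissues = ["brain", "liver", "heart"]
        latent = {(g, t): float(rng.lognormal(2, 1)) for g in genes for t in tissues}
        rows_a = [(g, t, t, latent[(g, t)]) for g in genes for t in tissues]
        rows_b = [(g, t, t, latent[(g, t)] * 2) for g in genes for t in tissues]
        pa, pb = quant_panel(rows_a, "rnaseq"), quant_panel(rows_b, "microarray")
        pa.dataset_id, pb.dataset_id = "rs", "ma"
        scheme = expr.ConsolidationScheme(
            {(ds, t): t for ds in ("rs", "ma") for t in tissues}
        )
        exs = [
            expr.consolidate({t: set(genes) for t in tissues}, scheme, "rs"),
            expr.consolidate({t: set(genes) for t in tissues}, scheme, "ma"),
        ]
        report = expr.dataset_compatibility(exs, [pa, pb], scheme, universe_size=100)
        assert (report.match_ranks["match_rank"] == 1).all()
        matching = report.pairs[report.pairs["tissue_a"] == report.pairs["tissue_b"]]
        assert (matching["kendall_tau"] > 0.99).all()
        assert (matching["fisher_p"] < 1e-10).all()


def test_relaxed_thresholds_keep_bimodal_breadth(small_study):
    """Superset + preserved bimodality when thresholds drop to 30 / 0.3."""
    ds = small_study.dataset
    scheme = small_study.scheme
    stringent, relaxed = [], []
    for name, panel in sorted(ds.panels.items()):
        if panel.dialect == "ihc":
            called_s = called_r = expr.call_expressed_ihc(panel)
        else:
            thr_s = expr.DEFAULT_THRESHOLDS[panel.dialect]
            thr_r = {"microarray": 30.0, "rnaseq": 0.3}[panel.dialect]
            called_s = expr.call_expressed_quantitative(panel, thr_s)
            called_r = expr.call_expressed_quantitative(panel, thr_r)
        stringent.append(expr.consolidate(called_s, scheme, name))
        relaxed.append(expr.consolidate(called_r, scheme, name))
    comb_s = expr.combine_datasets(stringent)
    comb_r = expr.combine_datasets(relaxed)
    for t in comb_s.tissues:
        assert comb_s.tissues[t] <= comb_r.tissues[t]
    hist = expr.breadth_histogram(expr.breadth_classify(comb_r))
    mid = hist.loc[6:11].mean()
    assert hist.loc[1:3].mean() > mid
    assert hist.loc[14:16].mean() > mid
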