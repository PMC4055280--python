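"""Disease-gene median contrasts, permutation test, overlaps, reports."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from tisnet import disease as dis
from tisnet import interactome as inter
from tisnet.errors import ConfigError, ExcludedGeneError
from tisnet.expression import Expressome


def gene_record(gene_id, values, disease_tissues, metric="rpkm"):
    expressing = tuple(sorted(values))
    return dis.GeneRecord(
        gene_id, expressing, frozenset(disease_tissues),
        {metric: {t: float(v) for t, v in values.items()}},
    )


def panel_of(*records):
    return dis.DiseasePanel(diseases=[], genes={r.gene_id: r for r in records})


def expressome_of(tissues):
    return Expressome("combined", {t: set(g) for t, g in tissues.items()}, {}, {})


# ---------------------------------------------------------------------------
# panel loading


class TestLoadDiseasePanel:
    def _assoc(self, rows):
        return pd.DataFrame(rows, columns=["disease_id", "gene_id", "tissue"])

    def test_association_dropped_when_gene_not_expressed_in_disease_tissue(self):
        ex = expressome_of({"brain": {"A"}, "liver": {"A"}})
        panel = dis.load_disease_panel(self._assoc([("d1", "A", "heart")]), ex,
                                       tissue_vocab=["brain", "liver", "heart"])
        assert panel.genes == {}
        assert panel.n_dropped_associations == 1

    def test_tissue_specific_gene_retained_but_excluded(self):
        ex = expressome_of({"brain": {"A"}})
        panel = dis.load_disease_panel(self._assoc([("d1", "A", "brain")]), ex)
        assert panel.genes["A"].excluded
        assert panel.included_genes() == []

    def test_unknown_tissue_and_unknown_gene_rows_dropped(self):
        ex = expressome_of({"brain": {"A"}, "liver": {"A"}})
        rows = [("d1", "A", "brain"), ("d1", "A", "marrow"), ("d2", "Z", "brain")]
        panel = dis.load_disease_panel(self._assoc(rows), ex)
        assert panel.n_dropped_rows == 2
        assert set(panel.genes) == {"A"}

    def test_gene_with_multiple_diseases_pools_tissues(self):
        ex = expressome_of({t: {"A"} for t in ("brain", "liver", "heart", "lung")})
        rows = [("d1", "A", "brain"), ("d2", "A", "liver")]
        panel = dis.load_disease_panel(self._assoc(rows), ex)
        assert panel.genes["A"].disease_tissues == {"brain", "liver"}
        assert len(panel.diseases) == 2

    def test_empty_association_table_gives_empty_panel(self):
        ex = expressome_of({"brain": {"A"}})
        panel = dis.load_disease_panel(self._assoc([]), ex)
        assert panel.genes == {} and panel.diseases == []

    def test_metrics_attached_from_graphs_and_tsppis(self):
        ex = expressome_of({"brain": {"A", "B"}, "liver": {"A"}})
        g_brain = nx.Graph([("A", "B")])
        graphs = {"brain": g_brain, "liver": nx.Graph()}
        ts = inter.TSPPISet({"brain": frozenset({("A", "B")})}, k_ts=3)
        rpkm = pd.DataFrame(
            [("A", "brain", 5.0), ("A", "liver", 1.0)],
            columns=["gene_id", "tissue", "value"],
        )
        panel = dis.load_disease_panel(
            self._assoc([("d1", "A", "brain")]), ex, rpkm=rpkm,
            tissue_graphs=graphs, tsppis=ts,
        )
        rec = panel.genes["A"]
        assert rec.metrics["rpkm"] == {"brain": 5.0, "liver": 1.0}
        assert rec.metrics["degree"] == {"brain": 1.0, "liver": 0.0}
        assert rec.metrics["tsppi_count"] == {"brain": 1.0, "liver": 0.0}


# ---------------------------------------------------------------------------
# median contrast


class TestMedianContrast:
    def test_single_disease_tissue(self):
        rec = gene_record("A", {"t1": 5, "t2": 1, "t3": 2, "t4": 3}, {"t1"})
        c = dis.median_contrast(rec, "rpkm")
        assert (c.v_d, c.v_nd) == (5.0, 2.0)
        assert c.success

    def test_even_length_medians_are_midpoints(self):
        rec = gene_record("A", {"t1": 4, "t2": 6, "t3": 1, "t4": 3}, {"t1", "t2"})
        c = dis.median_contrast(rec, "rpkm")
        assert (c.v_d, c.v_nd) == (5.0, 2.0)
        assert c.success

    def test_ties_are_not_successes(self):
        rec = gene_record("A", {"t1": 2, "t2": 2, "t3": 2}, {"t1"})
        assert not dis.median_contrast(rec, "rpkm").success

    def test_excluded_gene_raises(self):
        rec = gene_record("A", {"t1": 1, "t2": 2}, {"t1", "t2"})
        with pytest.raises(ExcludedGeneError):
            dis.median_contrast(rec, "rpkm")


# ---------------------------------------------------------------------------
# permutation test


class TestPermutationTest:
    def one_gene_panel(self):
        return panel_of(gene_record("A", {"t1": 5.0, "t2": 1.0, "t3": 2.0, "t4": 3.0}, {"t1"}))

    def test_one_gene_exact_p_is_half(self):
        # selections give success pattern (1,0,0,1): P(S >= 1) = 0.5
        res = dis.permutation_test(self.one_gene_panel(), "rpkm", mode="exact")
        assert res.observed == 1
        assert res.p_value == pytest.approx(0.5)

    def test_monte_carlo_matches_exact_within_sampling_error(self):
        res = dis.permutation_test(self.one_gene_panel(), "rpkm", n_runs=10_000, seed=4)
        se = math.sqrt(0.5 * 0.5 / 10_000)
        assert abs(res.p_value - 0.5) <= 3 * se

    def test_same_seed_reproduces_null_counts(self):
        a = dis.permutation_test(self.one_gene_panel(), "rpkm", n_runs=500, seed=9)
        b = dis.permutation_test(self.one_gene_panel(), "rpkm", n_runs=500, seed=9)
        assert np.array_equal(a.null_counts, b.null_counts)

    def test_adding_excluded_gene_changes_nothing(self):
        base = self.one_gene_panel()
        res_a = dis.permutation_test(base, "rpkm", n_runs=1000, seed=2)
        extra = gene_record("Z", {"t1": 7.0}, {"t1"})
        augmented = panel_of(*base.genes.values(), extra)
        res_b = dis.permutation_test(augmented, "rpkm", n_runs=1000, seed=2)
        assert res_a.p_value == res_b.p_value
        assert np.array_equal(res_a.null_counts, res_b.null_counts)

    def test_all_genes_excluded_is_an_error(self):
        panel = panel_of(gene_record("A", {"t1": 1.0}, {"t1"}))
        with pytest.raises(ConfigError):
            dis.permutation_test(panel, "rpkm")

    def test_invalid_run_count_is_an_error(self):
        with pytest.raises(ConfigError):
            dis.permutation_test(self.one_gene_panel(), "rpkm", n_runs=0)

    def test_exact_mode_respects_enumeration_bound(self):
        with pytest.raises(ConfigError, match="enumerate"):
            dis.permutation_test(self.one_gene_panel(), "rpkm", mode="exact",
                                 max_enumeration=2)

    def test_add_one_estimator_never_returns_zero(self):
        records = [
            gene_record(f"G{i}", {"t1": 10.0, "t2": 1.0, "t3": 1.0}, {"t1"})
            for i in range(30)
        ]
        res = dis.permutation_test(panel_of(*records), "rpkm", n_runs=200, seed=1,
                                   add_one=True)
        assert res.p_value > 0

    def test_multi_gene_exact_null_is_poisson_binomial(self):
        # gene A: values (5,1,2,3), x=1 -> selections 5 and 3 beat the
        # median of the rest, so p = 1/2; gene B: values (1,2,10), x=1 ->
        # only selecting 10 beats the mean-median of the remaining two,
        # so p = 1/3
        g1 = gene_record("A", {"t1": 5.0, "t2": 1.0, "t3": 2.0, "t4": 3.0}, {"t1"})
        g2 = gene_record("B", {"u1": 1.0, "u2": 2.0, "u3": 10.0}, {"u2"})
        res = dis.permutation_test(panel_of(g1, g2), "rpkm", mode="exact")
        # observed: A succeeds (5 > 2), B fails (2 < 5.5) -> observed = 1
        assert res.observed == 1
        assert res.exact_null_pmf == pytest.approx([1 / 3, 1 / 2, 1 / 6])
        assert res.p_value == pytest.approx(2 / 3)


# ---------------------------------------------------------------------------
# factor overlaps


class TestFactorOverlaps:
    def _panel_and_contrasts(self, n=20, successes_a=5, successes_b=5):
        records = [
            gene_record(f"G{i:02d}", {"t1": 2.0, "t2": 1.0, "t3": 1.5}, {"t1"})
            for i in range(n)
        ]
        for r in records:
            r.metrics["degree"] = dict(r.metrics["rpkm"])
        panel = panel_of(*records)
        ids = sorted(panel.genes)
        contrasts = {
            "rpkm": {
                g: dis.MedianContrast(g, "rpkm", 2.0 if i < successes_a else 0.0, 1.0)
                for i, g in enumerate(ids)
            },
            "degree": {
                g: dis.MedianContrast(g, "degree", 2.0 if i < successes_b else 0.0, 1.0)
                for i, g in enumerate(ids)
            },
        }
        return panel, contrasts

    def test_identical_sets_closed_form(self):
        panel, contrasts = self._panel_and_contrasts()
        report = dis.factor_overlap_tests(panel, contrasts)
        row = report.pairwise.iloc[0]
        assert row["overlap"] == 5
        assert row["fisher_p"] == pytest.approx(1 / 15504, rel=1e-9)

    def test_empty_success_set_warns_p_one(self):
        panel, contrasts = self._panel_and_contrasts(successes_b=0)
        with pytest.warns(UserWarning):
            report = dis.factor_overlap_tests(panel, contrasts)
        assert report.pairwise.iloc[0]["fisher_p"] == 1.0

    def test_tsppi_enrichment_block(self):
        panel, contrasts = self._panel_and_contrasts()
        interactome_genes = set(panel.genes) | {f"X{i}" for i in range(20)}
        with_ts = set(list(sorted(panel.genes))[:10])
        report = dis.factor_overlap_tests(
            panel, contrasts, interactome_genes=interactome_genes,
            genes_with_tsppi=with_ts,
        )
        enr = report.tsppi_enrichment
        assert enr["n_interactome"] == 40
        assert enr["n_causal_with_tsppi"] == 10
        assert 0 < enr["fisher_p"] < 1


# ---------------------------------------------------------------------------
# candidate report and disease summary


class TestCandidateReport:
    def _setup(self, total, ts):
        partners = [f"P{i}" for i in range(total)]
        g = nx.Graph([("A", p) for p in partners])
        graphs = {"brain": g}
        ts_edges = frozenset(inter.edge_key("A", p) for p in partners[:ts])
        tsppis = inter.TSPPISet({"brain": ts_edges} if ts else {}, k_ts=3)
        rec = gene_record("A", {"brain": 1.0, "liver": 0.5}, {"brain"})
        panel = dis.DiseasePanel(
            diseases=[dis.DiseaseEntry("d1", frozenset({"brain"}), ("A",))],
            genes={"A": rec},
        )
        return dis.tsppi_candidate_report(panel, tsppis, graphs)

    def test_eightfold_reduction(self):
        df = self._setup(total=16, ts=2)
        row = df.iloc[0]
        assert row["total_ppis"] == 16 and row["n_tsppi"] == 2
        assert row["reduction_factor"] == pytest.approx(8.0)

    def test_no_tsppi_gives_null_factor(self):
        df = self._setup(total=4, ts=0)
        assert df.iloc[0]["n_tsppi"] == 0
        assert df.iloc[0]["reduction_factor"] is None or math.isnan(df.iloc[0]["reduction_factor"])

    def test_single_ppi_that_is_ts(self):
        df = self._setup(total=1, ts=1)
        assert df.iloc[0]["reduction_factor"] == pytest.approx(1.0)


class TestDiseaseFactorSummary:
    def _summary(self, labels):
        diseases, genes, contrasts = [], {}, {"rpkm": {}, "tsppi_count": {}}
        for i, (elev, ts) in enumerate(labels):
            gid = f"G{i}"
            rec = gene_record(gid, {"t1": 2.0, "t2": 1.0, "t3": 1.0}, {"t1"})
            rec.metrics["tsppi_count"] = dict(rec.metrics["rpkm"])
            genes[gid] = rec
            diseases.append(dis.DiseaseEntry(f"d{i}", frozenset({"t1"}), (gid,)))
            contrasts["rpkm"][gid] = dis.MedianContrast(gid, "rpkm", 2.0 if elev else 0.0, 1.0)
            contrasts["tsppi_count"][gid] = dis.MedianContrast(gid, "tsppi_count", 2.0 if ts else 0.0, 1.0)
        panel = dis.DiseasePanel(diseases=diseases, genes=genes)
        return dis.disease_factor_summary(panel, contrasts)

    def test_mixed_panel_fractions(self):
        df, fr = self._summary([(1, 0), (1, 0), (0, 1), (0, 0)])
        assert fr["elevated-only"] == pytest.approx(0.5)
        assert fr["tsppi-only"] == pytest.approx(0.25)
        assert fr["elevated_or_tsppi"] == pytest.approx(0.75)

    def test_all_neither(self):
        _, fr = self._summary([(0, 0), (0, 0)])
        assert fr["elevated_or_tsppi"] == 0.0

    def test_single_disease_both(self):
        df, fr = self._summary([(1, 1)])
        assert df.iloc[0]["label"] == "both"
        assert fr["elevated_or_tsppi"] == 1.0
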