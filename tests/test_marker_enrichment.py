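import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucsort import (
    ExpressionTable,
    NucsortError,
    QcRules,
    SimConfig,
    count_table,
    enrichment_correlation,
    filter_sam,
    gene_enrichment,
    iter_alignments,
    make_annotation,
    panel_summary,
    refine_markers,
    reference_expression,
    sample_qc,
    simulate_reads,
    to_tpm,
)


def series(values: dict) -> pd.Series:
    return pd.Series(values, dtype=float)


class TestGeneEnrichment:
    def test_eight_over_one_is_three(self):
        enr = gene_enrichment(series({"g": 8.0}), series({"g": 1.0}), pseudocount=0.0)
        assert enr.at["g", "log2_enrichment"] == pytest.approx(3.0)

    def test_identity_zero(self):
        enr = gene_enrichment(series({"g": 5.5}), series({"g": 5.5}), pseudocount=0.0)
        assert enr.at["g", "log2_enrichment"] == pytest.approx(0.0)

    def test_antisymmetry(self):
        x = series({"a": 4.0, "b": 0.5, "c": 12.0})
        y = series({"a": 1.0, "b": 8.0, "c": 12.0})
        fwd = gene_enrichment(x, y, pseudocount=0.0)["log2_enrichment"]
        rev = gene_enrichment(y, x, pseudocount=0.0)["log2_enrichment"]
        np.testing.assert_allclose(fwd.to_numpy(), -rev.to_numpy())

    def test_zero_denominator_flagged_infinite(self):
        enr = gene_enrichment(series({"g": 2.0}), series({"g": 0.0}), pseudocount=0.0)
        assert np.isinf(enr.at["g", "log2_enrichment"])
        assert not enr.at["g", "finite"]

    def test_empty_intersection_errors(self):
        with pytest.raises(NucsortError):
            gene_enrichment(series({"a": 1.0}), series({"b": 1.0}))

    def test_rescale_makes_ratio_scale_free(self):
        x = series({"a": 10.0, "b": 30.0})
        with pytest.warns(UserWarning, match="rescal"):
            e1 = gene_enrichment(x, x * 1000.0, pseudocount=0.0, rescale=True)
        np.testing.assert_allclose(e1["log2_enrichment"].to_numpy(), 0.0, atol=1e-12)

    @given(
        x=st.floats(min_value=0.0, max_value=1e4),
        y=st.floats(min_value=0.0, max_value=1e4),
        eps1=st.floats(min_value=1e-6, max_value=10.0),
        eps2=st.floats(min_value=1e-6, max_value=10.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_pseudocount_monotonicity(self, x, y, eps1, eps2):
        # larger pseudocount shrinks |log2 ratio| toward 0, never flips sign
        lo, hi = sorted((eps1, eps2))
        num, den = series({"g": x}), series({"g": y})
        v_lo = gene_enrichment(num, den, pseudocount=lo).at["g", "log2_enrichment"]
        v_hi = gene_enrichment(num, den, pseudocount=hi).at["g", "log2_enrichment"]
        assert abs(v_hi) <= abs(v_lo) + 1e-9
        assert v_lo * v_hi >= -1e-12


class TestPanelSummary:
    panels = {"endothelial": ("e1", "e2", "e3"), "neuron": ("n1", "n2", "n3")}

    def test_constant_panels(self):
        enr = series({"e1": 3, "e2": 3, "e3": 3, "n1": 0, "n2": 0, "n3": 0})
        summary = panel_summary(enr, self.panels, "endothelial")
        assert summary.relative_enrichment == pytest.approx(3.0)
        assert summary.medians["endothelial"] == pytest.approx(3.0)

    def test_identical_distributions_zero(self):
        enr = series({g: v for g, v in zip(
            ("e1", "e2", "e3", "n1", "n2", "n3"), (1, 2, 3, 1, 2, 3))})
        summary = panel_summary(enr, self.panels, "endothelial")
        assert summary.relative_enrichment == pytest.approx(0.0)

    def test_empty_panel_flagged_and_excluded(self):
        panels = {**self.panels, "microglia": ("m1",)}
        enr = series({"e1": 1, "e2": 1, "e3": 1, "n1": 0, "n2": 0, "n3": 0})
        summary = panel_summary(enr, panels, "endothelial")
        assert "microglia" in summary.excluded_panels
        assert "microglia" not in summary.medians

    def test_nonfinite_values_excluded_from_medians(self):
        enr = series({"e1": np.inf, "e2": 2, "e3": 4, "n1": 0, "n2": 0, "n3": 0})
        summary = panel_summary(enr, self.panels, "endothelial")
        assert summary.medians["endothelial"] == pytest.approx(3.0)
        assert summary.n_genes["endothelial"] == 2

    def test_median_of_medians_option(self):
        panels = {
            "endothelial": ("e1",), "neuron": ("n1", "n2", "n3"), "microglia": ("m1",)
        }
        enr = series({"e1": 5, "n1": 1, "n2": 1, "n3": 1, "m1": 3})
        pooled = panel_summary(enr, panels, "endothelial")
        mom = panel_summary(enr, panels, "endothelial",
                            other_aggregation="median-of-medians")
        assert pooled.relative_enrichment == pytest.approx(5 - 1)  # pooled median=1
        assert mom.relative_enrichment == pytest.approx(5 - 2)  # median of {1,3}

    def test_missing_target_errors(self):
        with pytest.raises(Exception):
            panel_summary(series({"e1": 1}), self.panels, "astrocyte")


class TestRefineMarkers:
    def test_min_log2_minus_inf_only_removes_duplicates(self):
        panels = {"endothelial": ("a", "b", "dup"), "neuron": ("c", "dup")}
        ref = series({"a": -5, "b": -5, "dup": -5, "c": -5})
        refined, report = refine_markers(panels, [ref], min_log2=-math.inf)
        assert refined["endothelial"] == ("a", "b")
        assert refined["neuron"] == ("c",)
        assert set(report["gene_id"]) == {"dup"}

    def test_threshold_inclusive(self):
        panels = {"endothelial": ("a", "b"), "neuron": ()}
        ref = series({"a": 1.0, "b": 0.999})
        refined, report = refine_markers(panels, [ref], min_log2=1.0)
        assert refined["endothelial"] == ("a",)
        assert list(report["gene_id"]) == ["b"]

    def test_gene_must_pass_every_reference(self):
        panels = {"endothelial": ("a",), "neuron": ()}
        good = series({"a": 3.0})
        bad = series({"a": 0.0})
        with pytest.warns(UserWarning, match="empty"):
            refined, _ = refine_markers(panels, [good, bad], min_log2=1.0)
        assert refined["endothelial"] == ()

    def test_empty_result_warns_not_errors(self):
        panels = {"endothelial": ("a",), "neuron": ()}
        with pytest.warns(UserWarning, match="empty"):
            refined, _ = refine_markers(panels, [series({"a": -9.0})], min_log2=1.0)
        assert refined["endothelial"] == ()

    def test_planted_nonspecific_markers_removed(self):
        # 10% of the endothelial panel replaced by shared (non-specific)
        # genes; two noisy references at min_log2=1 must remove them while
        # keeping true markers.
        removed_planted = kept_true = n_planted = n_true = 0
        for seed in range(5):
            cfg = SimConfig(seed=seed)
            ann = make_annotation(cfg)
            panel = list(ann.panels["endothelial"])
            shared = [g for g in ann.gene_ids if g.startswith("shared")][:2]
            planted_panel = panel[:-2] + shared
            panels = {"endothelial": tuple(planted_panel), "neuron": ann.panels["neuron"]}
            refs = [
                gene_enrichment(
                    reference_expression(ann, {"endothelial": 1.0}, noise_sd=0.2,
                                         seed=[seed, i]),
                    reference_expression(ann, {"endothelial": 0.02, "other": 0.98},
                                         noise_sd=0.2, seed=[seed, i + 50]),
                    pseudocount=0.5,
                )
                for i in range(2)
            ]
            refined, _ = refine_markers(panels, refs, min_log2=1.0)
            n_planted += len(shared)
            n_true += len(panel) - 2
            removed_planted += sum(g not in refined["endothelial"] for g in shared)
            kept_true += sum(g in refined["endothelial"] for g in panel[:-2])
        assert removed_planted / n_planted >= 0.95
        assert kept_true / n_true >= 0.95


class TestEnrichmentCorrelation:
    def test_identity_gives_one(self):
        a = series({"a": 1, "b": 2, "c": 3, "d": -1})
        res = enrichment_correlation(a, a)
        assert res.pearson == pytest.approx(1.0)
        assert res.spearman == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        a = series({"a": 1, "b": 2, "c": 3})
        res = enrichment_correlation(a, -a)
        assert res.pearson == pytest.approx(-1.0)
        assert res.spearman == pytest.approx(-1.0)

    def test_too_few_pairs_errors(self):
        with pytest.raises(NucsortError):
            enrichment_correlation(series({"a": 1, "b": 2}), series({"a": 1, "b": 2}))

    def test_replicate_sorts_correlate(self):
        # two independent simulations of the same sorted composition must
        # rank panel genes consistently (spearman > 0.8)
        cfg = SimConfig(seed=40, read_depth=60_000)
        ann = make_annotation(cfg)
        comp_sorted = {"endothelial": 0.95, "microglia": 0.04, "other": 0.01}
        comp_unsorted = {"endothelial": 0.02, "microglia": 0.05, "neuron": 0.30,
                         "astrocyte": 0.20, "oligodendrocyte": 0.20, "OPC": 0.03,
                         "other": 0.20}
        enrs = []
        for rep in range(2):
            rows = {}
            for si, (name, comp) in enumerate(
                    (("sorted", comp_sorted), ("unsorted", comp_unsorted))):
                lines, _ = filter_sam(
                    simulate_reads(comp, ann, cfg, seed=[40, rep, si])
                )
                cr = count_table(iter_alignments(lines), ann, name)
                rows[name] = to_tpm(cr.table, ann).data.loc[name]
            enrs.append(gene_enrichment(rows["sorted"], rows["unsorted"], 0.5))
        panel_genes = [g for p in ann.panels.values() for g in p]
        a = enrs[0].loc[enrs[0].index.intersection(panel_genes)]
        b = enrs[1].loc[enrs[1].index.intersection(panel_genes)]
        res = enrichment_correlation(a, b)
        assert res.spearman > 0.8


class TestSampleQc:
    def tpm_table(self, data):
        return ExpressionTable(pd.DataFrame(data).T, "TPM")

    def test_zero_erg_fraction_flagged(self):
        table = self.tpm_table({"s1": {"Ptprc": 10.0}})
        qc = sample_qc({"s1": 0.0}, table)
        assert not qc["passed"].iloc[0]
        assert qc["reasons"].iloc[0].startswith("A:")

    def test_contamination_gene_above_ceiling_flagged(self):
        table = self.tpm_table({"s1": {"Ptprc": 5000.0}})
        qc = sample_qc({"s1": 0.02}, table)
        assert not qc["passed"].iloc[0]
        assert "B:" in qc["reasons"].iloc[0]

    def test_missing_contamination_gene_warns_and_skips(self):
        table = self.tpm_table({"s1": {"Cldn5": 5.0}})
        with pytest.warns(UserWarning, match="Ptprc"):
            qc = sample_qc({"s1": 0.02}, table)
        assert qc["passed"].iloc[0]

    def test_contaminated_sort_flagged_clean_sort_passes(self):
        cfg = SimConfig(seed=41, read_depth=25_000)
        ann = make_annotation(cfg)
        samples = {
            "clean": {"endothelial": 0.98, "other": 0.02},
            "contaminated": {"endothelial": 0.70, "microglia": 0.30},
        }
        rows = []
        for si, (name, comp) in enumerate(sorted(samples.items())):
            lines, _ = filter_sam(simulate_reads(comp, ann, cfg, seed=[41, si]))
            cr = count_table(iter_alignments(lines), ann, name)
            rows.append(to_tpm(cr.table, ann).data)
        table = ExpressionTable(pd.concat(rows), "TPM")
        qc = sample_qc({"clean": 0.02, "contaminated": 0.02}, table,
                       QcRules(contamination_tpm_max=1000.0))
        by_sample = qc.set_index("sample")
        assert by_sample.at["clean", "passed"]
        assert not by_sample.at["contaminated", "passed"]


class TestEstimatorConsistency:
    def test_bias_shrinks_with_depth(self):
        # panel-median enrichment bias decreases from shallow to deep
        comp_sorted = {"endothelial": 0.95, "other": 0.05}
        comp_unsorted = {"endothelial": 0.02, "other": 0.98}
        biases = []
        for depth in (2_000, 8_000, 64_000):
            errs = []
            for seed in range(3):
                cfg = SimConfig(seed=seed, read_depth=depth)
                ann = make_annotation(cfg)
                rows = {}
                for si, (name, comp) in enumerate(
                        (("s", comp_sorted), ("u", comp_unsorted))):
                    lines, _ = filter_sam(
                        simulate_reads(comp, ann, cfg, seed=[seed, depth, si])
                    )
                    cr = count_table(iter_alignments(lines), ann, name)
                    rows[name] = to_tpm(cr.table, ann).data.loc[name]
                enr = gene_enrichment(rows["s"], rows["u"], 0.5)
                summary = panel_summary(enr, ann.panels, "endothelial")
                # analytic truth from the noiseless expression model
                expr = ann.expr
                w_s = expr.mul(pd.Series(comp_sorted), axis=1).sum(axis=1).fillna(0)
                w_u = expr.mul(pd.Series(comp_unsorted), axis=1).sum(axis=1).fillna(0)
                truth = np.log2(w_s / w_u).loc[list(ann.panels["endothelial"])].median()
                errs.append(abs(summary.medians["endothelial"] - truth))
            biases.append(np.mean(errs))
        assert biases[2] < biases[0]
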