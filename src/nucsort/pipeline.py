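"""End-to-end desk-scale experiment: simulate -> gate -> sort -> reads ->
filter -> quantify -> enrich -> qPCR -> QC, with a machine-readable
manifest.

A run is reproducible from its config alone: all outputs, including the
manifest, are bit-identical across re-runs with the same config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import io as nio
from .errors import NucsortError
from .flow_gating import LABEL_TO_CLASS, GateSet, apply_gates, in_silico_sort
from .junction_filter import filter_sam, iter_alignments
from .junction_quant import (
    ExpressionTable,
    combine_counts,
    count_table,
    detected_genes,
    to_tpm,
)
from .marker_enrichment import (
    QcRules,
    enrichment_correlation,
    gene_enrichment,
    panel_summary,
    refine_markers,
    sample_qc,
)
from .qpcr_analysis import delta_ct, fold_table
from .synthetic_cohort import (
    SimConfig,
    default_profiles,
    make_annotation,
    reference_expression,
    simulate_events,
    simulate_qpcr,
    simulate_reads,
    write_sam,
)

log = logging.getLogger("nucsort")

DEFAULT_MIXTURE: Mapping[str, float] = {
    "endothelial": 0.02,
    "microglia": 0.05,
    "neuron": 0.30,
    "astrocyte": 0.20,
    "oligodendrocyte": 0.20,
    "OPC": 0.03,
    "other": 0.20,
}


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one experiment."""

    sim: SimConfig = SimConfig()
    gates: GateSet = GateSet()
    mixture: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    sort_labels: tuple[str, ...] = ("ErgHi", "NeuN")
    n_sort: int = 300
    stranded: bool = False
    min_count: int = 1
    pseudocount: float = 0.5
    min_log2: float = 1.0
    qc: QcRules = QcRules()
    qpcr_targets: tuple[str, ...] = ("Cldn5", "Map2")
    qpcr_housekeeping: str = "Ubc"
    reference_noise_sd: float = 0.25

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mixture"] = dict(self.mixture)
        d["sort_labels"] = list(self.sort_labels)
        d["qpcr_targets"] = list(self.qpcr_targets)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimConfig(**d["sim"])
        if "gates" in d:
            d["gates"] = GateSet(**d["gates"])
        if "qc" in d:
            d["qc"] = QcRules(**d["qc"])
        if "sort_labels" in d:
            d["sort_labels"] = tuple(d["sort_labels"])
        if "qpcr_targets" in d:
            d["qpcr_targets"] = tuple(d["qpcr_targets"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def _stage(name: str, **counts) -> None:
    log.info("%s %s", name, " ".join(f"{k}={v}" for k, v in counts.items()))


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage and write all outputs under ``outdir``.

    Returns the manifest (also written as manifest.json).  Errors propagate
    with the failing stage named.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.sim.seed,
        "counts": {},
        "warnings": [],
        "outputs": [],
    }

    def emit(name: str, writer, *args) -> None:
        writer(*args, out / name)
        manifest["outputs"].append(name)

    stage = "annotation"
    try:
        annotation = make_annotation(config.sim)
        nio.write_annotation(annotation, out / "annotation.bed", out / "abundance.tsv")
        manifest["outputs"] += ["annotation.bed", "abundance.tsv"]
        nio.write_panels(annotation.panels, out / "panels.tsv")
        manifest["outputs"].append("panels.tsv")
        manifest["counts"]["genes"] = len(annotation.genes)
        _stage(stage, genes=len(annotation.genes))

        stage = "events"
        profiles = default_profiles(config.mixture)
        events = simulate_events(profiles, config.sim, min_separation=3.0)
        nio.write_events(events, out / "events.tsv")
        manifest["outputs"].append("events.tsv")
        manifest["counts"]["events"] = len(events)

        stage = "gating"
        gating = apply_gates(events, config.gates)
        gating.fraction_table().to_csv(out / "fractions.tsv", sep="\t", index=False)
        manifest["outputs"].append("fractions.tsv")
        manifest["counts"]["parent_gate"] = gating.parent_count
        manifest["counts"]["populations"] = dict(gating.counts)
        _stage(stage, parent=gating.parent_count, **gating.counts)

        stage = "sorting"
        compositions: dict[str, Mapping[str, float]] = {}
        purities: dict[str, float] = {}
        parent = gating.events[gating.events["label"] != "non-nucleus"]
        unsorted_pool = parent.iloc[: config.n_sort]
        compositions["unsorted"] = {
            k: int(v) for k, v in Counter(unsorted_pool["true_class"]).items()
        }
        for label in config.sort_labels:
            sr = in_silico_sort(gating.events, label, config.n_sort)
            if sr.n_selected == 0:
                raise NucsortError(f"no events available for sort gate {label}")
            if sr.shortfall:
                manifest["warnings"].append(
                    f"sort {label}: only {sr.n_selected}/{config.n_sort} events"
                )
            compositions[label] = sr.composition
            purities[label] = sr.purity
        manifest["counts"]["sorted"] = {
            s: int(sum(c.values())) for s, c in compositions.items()
        }
        manifest["purity"] = purities

        stage = "reads"
        count_results = []
        read_counts: dict[str, dict[str, int]] = {}
        for i, (sample, comp) in enumerate(sorted(compositions.items())):
            lines = simulate_reads(
                comp, annotation, config.sim, seed=[config.sim.seed, 101, i]
            )
            write_sam(lines, out / f"raw_{sample}.sam")
            manifest["outputs"].append(f"raw_{sample}.sam")
            kept_lines, stats = filter_sam(lines)
            write_sam(kept_lines, out / f"filtered_{sample}.sam")
            manifest["outputs"].append(f"filtered_{sample}.sam")
            reads = list(iter_alignments(kept_lines))
            cr = count_table(reads, annotation, sample, stranded=config.stranded)
            count_results.append(cr)
            read_counts[sample] = {
                "total": stats.total,
                "kept": stats.kept,
                "dropped": stats.dropped,
                "assigned": cr.assigned,
                "unassigned": cr.unassigned,
            }
            _stage(stage, sample=sample, **read_counts[sample])
        manifest["counts"]["reads"] = read_counts

        stage = "quantification"
        counts = combine_counts(count_results)
        tpm = to_tpm(counts, annotation)
        nio.write_expression(counts, out / "counts.tsv")
        nio.write_expression(tpm, out / "tpm.tsv")
        manifest["outputs"] += ["counts.tsv", "tpm.tsv"]
        detected = detected_genes(counts, config.min_count)
        detected.rename("n_detected").to_frame().to_csv(
            out / "detected_genes.tsv", sep="\t"
        )
        manifest["outputs"].append("detected_genes.tsv")
        manifest["counts"]["detected_genes"] = {
            s: int(v) for s, v in detected.items()
        }

        all_filtered = counts.data.to_numpy().sum() == 0
        if all_filtered:
            manifest["warnings"].append(
                "all alignment records were removed by the junction filter; "
                "count table is empty and enrichment/QC stages were skipped"
            )
            log.warning("all reads filtered; skipping enrichment stages")

        stage = "enrichment"
        summaries = []
        enr_by_label = {}
        if not all_filtered:
            for label in config.sort_labels:
                enr = gene_enrichment(
                    tpm.row(label),
                    tpm.row("unsorted"),
                    config.pseudocount,
                    comparison_label=f"{label}-vs-unsorted",
                )
                enr_by_label[label] = enr
                enr.to_csv(out / f"enrichment_{label}.tsv", sep="\t")
                manifest["outputs"].append(f"enrichment_{label}.tsv")
                target = LABEL_TO_CLASS.get(label, "endothelial")
                summary = panel_summary(enr, annotation.panels, target)
                frame = summary.to_frame()
                frame.insert(0, "comparison", f"{label}-vs-unsorted")
                frame["relative_enrichment_of_target"] = summary.relative_enrichment
                summaries.append(frame)
            pd.concat(summaries).to_csv(out / "panel_summary.tsv", sep="\t", index=False)
            manifest["outputs"].append("panel_summary.tsv")

            stage = "reference-comparison"
            ref_endo = reference_expression(
                annotation,
                {"endothelial": 1.0},
                noise_sd=config.reference_noise_sd,
                seed=[config.sim.seed, 211],
            )
            ref_brain = reference_expression(
                annotation,
                dict(config.mixture),
                noise_sd=config.reference_noise_sd,
                seed=[config.sim.seed, 212],
            )
            ref_enr = gene_enrichment(
                ref_endo, ref_brain, config.pseudocount,
                comparison_label="reference-endothelial-vs-brain",
            )
            ref_enr.to_csv(out / "enrichment_reference.tsv", sep="\t")
            manifest["outputs"].append("enrichment_reference.tsv")
            if "ErgHi" in enr_by_label:
                corr = enrichment_correlation(enr_by_label["ErgHi"], ref_enr)
                pd.DataFrame(
                    [{"n": corr.n, "pearson": corr.pearson, "spearman": corr.spearman}]
                ).to_csv(out / "correlation.tsv", sep="\t", index=False)
                manifest["outputs"].append("correlation.tsv")
                manifest["counts"]["correlation_n"] = corr.n

            stage = "marker-refinement"
            refined, removals = refine_markers(
                annotation.panels, [ref_enr], config.min_log2
            )
            nio.write_panels(refined, out / "refined_panels.tsv")
            removals.to_csv(out / "removed_markers.tsv", sep="\t", index=False)
            manifest["outputs"] += ["refined_panels.tsv", "removed_markers.tsv"]
            manifest["counts"]["refined_target_panel"] = len(
                refined.get("endothelial", ())
            )

            stage = "sample-qc"
            erg_fracs = {
                s: float(gating.fractions.get("ErgHi", 0)) if gating.defined else 0.0
                for s in config.sort_labels
            }
            sorted_tpm = ExpressionTable(
                tpm.data.loc[list(config.sort_labels)], "TPM"
            )
            qc = sample_qc(erg_fracs, sorted_tpm, config.qc)
            qc.to_csv(out / "qc.tsv", sep="\t", index=False)
            manifest["outputs"].append("qc.tsv")
            manifest["counts"]["qc_flagged"] = int((~qc["passed"]).sum())

        stage = "qpcr"
        wells = simulate_qpcr(
            compositions,
            list(config.qpcr_targets),
            config.qpcr_housekeeping,
            annotation,
            config.sim,
            seed=[config.sim.seed, 131],
        )
        wells.to_csv(out / "qpcr_ct.tsv", sep="\t", index=False)
        dct = delta_ct(wells, config.qpcr_housekeeping)
        folds = fold_table(dct, "unsorted")
        folds.to_csv(out / "qpcr_results.tsv", sep="\t", index=False)
        manifest["outputs"] += ["qpcr_ct.tsv", "qpcr_results.tsv"]
    except Exception as exc:
        raise NucsortError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest["outputs"].append("manifest.json")
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n"
    )
    return manifest
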