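# nucsort

Desk-scale re-implementation of an endothelial **nuclei-sorting RNA
analysis** workflow: flow-cytometry gating of nucleus events, in-silico
sorting, splice-junction-only RNA quantification from SAM alignments,
cell-type marker-panel enrichment statistics, and ΔΔCt qPCR fold
enrichment. Everything runs on a bundled synthetic-cohort simulator with
known ground truth, so the whole pipeline is testable offline — no
downloads, no binary files.

## What it does

1. **synthetic_cohort** — generates every input: a small genome with
   multi-exon gene models and disjoint marker panels (endothelial, neuron,
   microglia, astrocyte, oligodendrocyte, OPC, other), log-normal
   fluorescence event mixtures (distinct ErgHi / ErgLo / NeuN populations),
   SAM read streams with junction / intronic / intergenic (genomic-DNA)
   classes, reference expression tables and qPCR CT plates. One seed
   determines all output bit-for-bit.
2. **flow_gating** — axis-aligned log10 gates (DAPI+/SSC-low parent, then
   ErgHi / ErgLo / NeuN / rest), exact rational population fractions, and
   in-silico sorting producing true-class compositions plus purity.
3. **junction_filter** — keeps only alignments whose CIGAR contains an N
   op (splice junction); equivalent to the classic "column 6 contains N"
   text filter, with headers preserved and secondary alignments dropped.
4. **junction_quant** — assigns each junction to the unique gene span
   containing it (ambiguity is never double-counted) and builds
   count / TPM / RPM tables plus detected-gene counts.
5. **marker_enrichment** — per-gene log2 sorted-vs-reference ratios with
   pseudocount, per-panel medians, target-vs-pooled-others relative
   enrichment, marker stringency refinement against reference
   enrichments, Pearson/Spearman enrichment correlation, and rule-based
   outlier-sample QC (low Erg+ staining, Ptprc contamination).
6. **qpcr_analysis** — replicate-mean ΔCT against a housekeeping gene and
   fold enrichment `efficiency**(ΔCT_ref − ΔCT_sorted)`.
7. **pipeline_cli** — the `nucsort` command orchestrating the full run
   with a reproducible manifest (config hash, per-stage counts).

## CLI

```bash
# full experiment into one directory (events, SAM, tables, manifest):
nucsort run --config run.yaml --out results/run1 --seed 7

# per-stage commands, chainable on plain-text files:
nucsort simulate --out sim/                 # annotation, panels, events
nucsort gate --events sim/events.tsv --gates sim/gates.yaml --out fractions.tsv
nucsort filter raw.sam -o spliced.sam       # also: filter-junctions raw.sam -o ...
nucsort quant --sam spliced.sam --annotation sim/annotation.bed --out quant/
nucsort enrich --tpm quant/tpm.tsv --sorted-sample ErgHi --panels sim/panels.tsv --out enr/
nucsort qpcr --wells qpcr_ct.tsv --housekeeping Ubc --out folds.tsv
```

`run.yaml` mirrors `nucsort.RunConfig` (see `RunConfig.to_yaml`); omitting
it uses defaults. Two runs with the same config+seed produce bit-identical
outputs.

## Python API sketch

```python
import nucsort as ns

cfg = ns.SimConfig(seed=7)
ann = ns.make_annotation(cfg)
events = ns.simulate_events(ns.default_profiles({"endothelial": 0.02, "neuron": 0.3, "other": 0.68}), cfg)
gated = ns.apply_gates(events, ns.GateSet())
sort = ns.in_silico_sort(gated.events, "ErgHi", 300)
lines = ns.simulate_reads(sort.composition, ann, cfg)
kept, stats = ns.filter_sam(lines)
counts = ns.count_table(ns.iter_alignments(kept), ann, "ErgHi")
tpm = ns.to_tpm(counts.table, ann)
```
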