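"""Marker-panel enrichment statistics for sorted-vs-reference comparisons.

Per-gene log2 ratios with pseudocount handling, per-panel medians and the
target panel's enrichment relative to pooled other-panel genes, panel
stringency refinement against reference enrichments, cross-comparison
correlation, and rule-based sample QC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NucsortError, ParameterError
from .junction_quant import ExpressionTable


def gene_enrichment(
    numerator: pd.Series,
    denominator: pd.Series,
    pseudocount: float = 0.5,
    *,
    rescale: bool = False,
    comparison_label: str = "",
) -> pd.DataFrame:
    """log2((x + eps) / (y + eps)) on the shared gene universe.

    With ``pseudocount == 0`` zero-denominator (or numerator) genes yield
    +/-inf and are flagged non-finite (excluded from medians downstream).
    ``rescale`` renormalises both inputs to sum 1e6 first; use it whenever
    the two inputs are on different unit scales (e.g., TPM vs FPKM) — the
    ratio then becomes scale-free.  Returns a frame indexed by gene with
    columns log2_enrichment and finite.
    """
    if pseudocount < 0:
        raise ParameterError("pseudocount must be >= 0")
    shared = numerator.index.intersection(denominator.index)
    if len(shared) == 0:
        raise NucsortError("empty gene intersection between expression inputs")
    x = numerator.loc[shared].astype(float)
    y = denominator.loc[shared].astype(float)
    if rescale:
        warnings.warn(
            "rescaling both expression inputs to a common 1e6 total "
            "(mixed-unit comparison)",
            stacklevel=2,
        )
        if x.sum() <= 0 or y.sum() <= 0:
            raise NucsortError("cannot rescale an all-zero expression input")
        x = x / x.sum() * 1e6
        y = y / y.sum() * 1e6
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.log2(x.to_numpy() + pseudocount) - np.log2(
            y.to_numpy() + pseudocount
        )
    frame = pd.DataFrame(
        {
            "log2_enrichment": values,
            "finite": np.isfinite(values),
        },
        index=shared,
    )
    frame.index.name = "gene_id"
    if comparison_label:
        frame.attrs["comparison_label"] = comparison_label
    return frame


def _enrichment_series(enrichment) -> pd.Series:
    if isinstance(enrichment, pd.DataFrame):
        return enrichment["log2_enrichment"]
    return enrichment


@dataclass
class PanelSummary:
    """Per-panel medians and the target panel's pooled-relative enrichment."""

    target: str
    medians: Mapping[str, float]
    n_genes: Mapping[str, int]
    relative_enrichment: float
    excluded_panels: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "panel": p,
                "median_log2_enrichment": self.medians[p],
                "n_genes": self.n_genes[p],
                "is_target": p == self.target,
            }
            for p in self.medians
        ]
        frame = pd.DataFrame(rows)
        frame.attrs["relative_enrichment"] = self.relative_enrichment
        return frame


def panel_summary(
    enrichment,
    panels: Mapping[str, Sequence[str]],
    target: str,
    *,
    other_aggregation: str = "pooled",
) -> PanelSummary:
    """Median log2 enrichment per panel plus target-vs-others enrichment.

    ``relative_enrichment`` is the target-panel median minus the median over
    all non-target panel genes pooled (``other_aggregation="pooled"``), or
    minus the median of the other panels' medians
    (``other_aggregation="median-of-medians"``).
    """
    if target not in panels:
        raise ParameterError(f"target panel {target!r} not among panels")
    series = _enrichment_series(enrichment)
    finite = series[np.isfinite(series)]
    medians: dict[str, float] = {}
    n_genes: dict[str, int] = {}
    excluded: list[str] = []
    for panel, genes in panels.items():
        vals = finite.loc[finite.index.intersection(pd.Index(genes))]
        if len(vals) == 0:
            excluded.append(panel)
            continue
        medians[panel] = float(vals.median())
        n_genes[panel] = int(len(vals))
    if target not in medians:
        raise NucsortError(f"target panel {target!r} has no finite enrichment values")
    if other_aggregation == "pooled":
        pooled_genes: list[str] = []
        for panel, genes in panels.items():
            if panel != target:
                pooled_genes.extend(genes)
        others = finite.loc[finite.index.intersection(pd.Index(pooled_genes))]
        if len(others) == 0:
            raise NucsortError("no finite values in any non-target panel")
        other_median = float(others.median())
    elif other_aggregation == "median-of-medians":
        vals = [m for p, m in medians.items() if p != target]
        if not vals:
            raise NucsortError("no non-target panel medians available")
        other_median = float(np.median(vals))
    else:
        raise ParameterError(f"unknown other_aggregation {other_aggregation!r}")
    return PanelSummary(
        target=target,
        medians=medians,
        n_genes=n_genes,
        relative_enrichment=medians[target] - other_median,
        excluded_panels=tuple(excluded),
    )


def refine_markers(
    panels: Mapping[str, Sequence[str]],
    reference_enrichments: Sequence,
    min_log2: float,
    *,
    target: str = "endothelial",
) -> tuple[dict[str, tuple[str, ...]], pd.DataFrame]:
    """Stringency-refine the target panel and de-duplicate across panels.

    A target-panel gene is retained iff its log2 enrichment is >= min_log2
    (inclusive) in *every* provided reference; genes appearing in more than
    one panel are removed from all panels.  Returns the refined panels and a
    removal report (gene, panel, reason).
    """
    refs = [_enrichment_series(r) for r in reference_enrichments]
    removals: list[dict] = []

    seen: dict[str, list[str]] = {}
    for panel, genes in panels.items():
        for g in genes:
            seen.setdefault(g, []).append(panel)
    duplicated = {g for g, ps in seen.items() if len(ps) > 1}
    for g in sorted(duplicated):
        for panel in seen[g]:
            removals.append(
                {"gene_id": g, "panel": panel, "reason": "duplicated-across-panels"}
            )

    refined: dict[str, tuple[str, ...]] = {}
    for panel, genes in panels.items():
        kept = [g for g in genes if g not in duplicated]
        if panel == target:
            survivors = []
            for g in kept:
                failed = None
                for i, ref in enumerate(refs):
                    if g not in ref.index or not np.isfinite(ref.loc[g]):
                        failed = f"missing-in-reference-{i}"
                        break
                    if ref.loc[g] < min_log2:
                        failed = f"below-threshold-in-reference-{i}"
                        break
                if failed is None:
                    survivors.append(g)
                else:
                    removals.append({"gene_id": g, "panel": panel, "reason": failed})
            kept = survivors
        refined[panel] = tuple(kept)

    if not refined.get(target):
        warnings.warn(f"refined target panel {target!r} is empty", stacklevel=2)
    report = pd.DataFrame(removals, columns=["gene_id", "panel", "reason"])
    return refined, report


@dataclass
class CorrelationResult:
    n: int
    pearson: float
    spearman: float
    pairs: pd.DataFrame = field(repr=False, default=None)


def enrichment_correlation(enr_a, enr_b) -> CorrelationResult:
    """Pearson and Spearman correlation of two enrichment tables.

    Computed on the gene intersection restricted to finite pairs; fewer than
    3 pairs is an error.
    """
    a = _enrichment_series(enr_a)
    b = _enrichment_series(enr_b)
    shared = a.index.intersection(b.index)
    pairs = pd.DataFrame({"a": a.loc[shared], "b": b.loc[shared]})
    pairs = pairs[np.isfinite(pairs["a"]) & np.isfinite(pairs["b"])]
    if len(pairs) < 3:
        raise NucsortError(
            f"need >= 3 shared finite gene pairs for correlation, got {len(pairs)}"
        )
    pearson = float(stats.pearsonr(pairs["a"], pairs["b"]).statistic)
    spearman = float(stats.spearmanr(pairs["a"], pairs["b"]).statistic)
    return CorrelationResult(n=len(pairs), pearson=pearson, spearman=spearman, pairs=pairs)


@dataclass(frozen=True)
class QcRules:
    """Outlier-sample rules: minimum Erg+ staining and a contamination gene."""

    erg_fraction_min: float = 0.005
    contamination_gene: str = "Ptprc"
    contamination_tpm_max: float = 1000.0


def sample_qc(
    erg_fractions: Mapping[str, float],
    expression: ExpressionTable,
    rules: QcRules = QcRules(),
) -> pd.DataFrame:
    """Flag outlier samples; never drops rows (exclusion is a config action).

    Rule A: the sample's Erg+ gating fraction is below ``erg_fraction_min``.
    Rule B: the contamination gene's expression exceeds
    ``contamination_tpm_max``.  A missing contamination gene skips rule B
    with a warning.
    """
    has_gene = rules.contamination_gene in expression.data.columns
    if not has_gene:
        warnings.warn(
            f"contamination gene {rules.contamination_gene!r} absent from "
            "expression table; rule B skipped",
            stacklevel=2,
        )
    rows = []
    for sample in expression.samples:
        reasons = []
        frac = erg_fractions.get(sample)
        if frac is not None and frac < rules.erg_fraction_min:
            reasons.append(f"A:erg_fraction {frac:.4g} < {rules.erg_fraction_min}")
        if has_gene:
            val = float(expression.data.at[sample, rules.contamination_gene])
            if val > rules.contamination_tpm_max:
                reasons.append(
                    f"B:{rules.contamination_gene} {val:.4g} > "
                    f"{rules.contamination_tpm_max}"
                )
        rows.append(
            {
                "sample": sample,
                "passed": not reasons,
                "reasons": ";".join(reasons),
            }
        )
    return pd.DataFrame(rows)
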