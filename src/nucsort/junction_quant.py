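"""Gene-level quantification of junction-spanning reads.

A read is assigned to a gene iff the reference interval skipped by its N op
lies entirely within exactly one gene's span (overlap ambiguity is never
silently double-counted).  Count tables normalise to TPM using exonic
length, or to RPM (depth only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .junction_filter import AlignedRead, is_junction_spanning
from .synthetic_cohort import Annotation, GeneModel

UNITS = ("count", "TPM", "RPM")


@dataclass
class ExpressionTable:
    """samples x genes matrix with a unit tag ("count", "TPM" or "RPM")."""

    data: pd.DataFrame
    unit: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ParameterError(f"unknown unit {self.unit!r}")
        if self.unit == "count":
            vals = self.data.to_numpy()
            if vals.size and not np.allclose(vals, np.round(vals)):
                raise ParameterError("count table contains non-integers")
        if self.data.size and (self.data.to_numpy() < 0).any():
            raise ParameterError("expression values must be non-negative")

    def row(self, sample: str) -> pd.Series:
        return self.data.loc[sample]

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)


class GeneIndex:
    """Junction-containment lookup over gene spans (per chromosome)."""

    def __init__(self, genes: Sequence[GeneModel]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[GeneModel]]] = {}
        for chrom in {g.chrom for g in genes}:
            sub = sorted((g for g in genes if g.chrom == chrom), key=lambda g: g.start)
            starts = np.array([g.start for g in sub], dtype=np.int64)
            ends = np.array([g.end for g in sub], dtype=np.int64)
            self._by_chrom[chrom] = (starts, ends, sub)

    def containing(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        """Genes whose span fully contains [start, end)."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        starts, ends, sub = entry
        mask = (starts <= start) & (ends >= end)
        return [sub[i] for i in np.nonzero(mask)[0]]


def junction_interval(read: AlignedRead) -> tuple[int, int] | None:
    """0-based half-open reference interval skipped by the first N op."""
    cur = read.pos - 1
    for n, op in read.cigar:
        if op == "N":
            return cur, cur + n
        if op in "MD=X":
            cur += n
    return None


def assign_read_to_gene(
    read: AlignedRead,
    index: GeneIndex,
    *,
    stranded: bool = False,
) -> str | None:
    """Gene id the read's junction belongs to, or None if unassigned.

    Unassigned cases: no junction, junction extending past every gene span,
    or containment in more than one gene (ambiguous).
    """
    interval = junction_interval(read)
    if interval is None:
        return None
    hits = index.containing(read.chrom, *interval)
    if stranded:
        hits = [g for g in hits if g.strand == read.strand]
    if len(hits) != 1:
        return None
    return hits[0].gene_id


@dataclass
class CountResult:
    table: "ExpressionTable"
    assigned: int
    unassigned: int


def count_table(
    reads: Iterable[AlignedRead],
    annotation: Annotation,
    sample_label: str,
    *,
    stranded: bool = False,
) -> CountResult:
    """Per-gene junction-read counts for one sample.

    Input reads must already be junction-filtered; junctionless reads are
    counted as unassigned rather than erroring, so conservation
    (assigned + unassigned = inputs) always holds.
    """
    index = GeneIndex(annotation.genes)
    counts: dict[str, int] = {gid: 0 for gid in annotation.gene_ids}
    assigned = unassigned = 0
    for read in reads:
        gid = assign_read_to_gene(read, index, stranded=stranded)
        if gid is None:
            unassigned += 1
        else:
            counts[gid] += 1
            assigned += 1
    frame = pd.DataFrame([counts], index=[sample_label]).astype(np.int64)
    frame = frame[list(annotation.gene_ids)]
    return CountResult(
        table=ExpressionTable(frame, "count", meta={"unassigned": {sample_label: unassigned}}),
        assigned=assigned,
        unassigned=unassigned,
    )


def combine_counts(results: Sequence[CountResult]) -> ExpressionTable:
    """Stack single-sample count tables into one samples x genes table."""
    frames = [r.table.data for r in results]
    meta: dict = {"unassigned": {}}
    for r in results:
        meta["unassigned"].update(r.table.meta.get("unassigned", {}))
    return ExpressionTable(pd.concat(frames), "count", meta=meta)


def _exonic_lengths(annotation: Annotation, genes: Sequence[str]) -> np.ndarray:
    by_id = {g.gene_id: g for g in annotation.genes}
    lengths = []
    for gid in genes:
        if gid not in by_id:
            raise ParameterError(f"gene {gid} missing from annotation")
        length = by_id[gid].exonic_length
        if length <= 0:
            raise ParameterError(f"gene {gid} has zero exonic length")
        lengths.append(length)
    return np.array(lengths, dtype=float)


def to_tpm(counts: ExpressionTable, annotation: Annotation) -> ExpressionTable:
    """Length-normalised TPM: 1e6 * (count/kb) / sum(count/kb) per sample.

    All-zero samples stay all-zero and are listed in meta["zero_samples"].
    """
    if counts.unit != "count":
        raise ParameterError("to_tpm expects a count table")
    lengths_kb = _exonic_lengths(annotation, counts.genes) / 1000.0
    rates = counts.data.to_numpy(dtype=float) / lengths_kb
    totals = rates.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    safe = np.where(totals == 0, 1.0, totals)
    tpm = rates / safe * 1e6
    frame = pd.DataFrame(tpm, index=counts.data.index, columns=counts.data.columns)
    zero_samples = [s for s, z in zip(counts.samples, zero) if z]
    return ExpressionTable(frame, "TPM", meta={"zero_samples": zero_samples})


def to_rpm(counts: ExpressionTable) -> ExpressionTable:
    """Depth-only normalisation: reads per million mapped junction reads."""
    if counts.unit != "count":
        raise ParameterError("to_rpm expects a count table")
    vals = counts.data.to_numpy(dtype=float)
    totals = vals.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    safe = np.where(totals == 0, 1.0, totals)
    frame = pd.DataFrame(
        vals / safe * 1e6, index=counts.data.index, columns=counts.data.columns
    )
    zero_samples = [s for s, z in zip(counts.samples, zero) if z]
    return ExpressionTable(frame, "RPM", meta={"zero_samples": zero_samples})


def detected_genes(table: ExpressionTable, min_count: int = 1) -> pd.Series:
    """Per-sample number of genes with count >= min_count."""
    if table.unit != "count":
        raise ParameterError("detected_genes expects a count table")
    return (table.data >= min_count).sum(axis=1)
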