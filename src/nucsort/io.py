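"""Plain-text readers and writers for every stage boundary.

Formats: BED12-like annotation TSV + abundance TSV, 2-column panel TSV,
event TSV, expression TSV (genes x samples), gates YAML/JSON blocks.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .errors import ParameterError
from .flow_gating import GateSet
from .junction_quant import ExpressionTable
from .synthetic_cohort import CELL_TYPES, Annotation, GeneModel

_BED_COLUMNS = [
    "chrom",
    "start",
    "end",
    "gene_id",
    "score",
    "strand",
    "blockCount",
    "blockSizes",
    "blockStarts",
]


def write_annotation(annotation: Annotation, bed_path, abundance_path) -> None:
    rows = []
    for g in annotation.genes:
        sizes = ",".join(str(e - s) for s, e in g.exons)
        starts = ",".join(str(s - g.start) for s, e in g.exons)
        rows.append(
            [g.chrom, g.start, g.end, g.gene_id, 0, g.strand, len(g.exons), sizes, starts]
        )
    pd.DataFrame(rows, columns=_BED_COLUMNS).to_csv(bed_path, sep="\t", index=False)
    expr = annotation.expr
    expr.index.name = "gene_id"
    expr.to_csv(abundance_path, sep="\t")


def read_annotation(
    bed_path, abundance_path=None, panels: Mapping[str, tuple[str, ...]] | None = None
) -> Annotation:
    bed = pd.read_csv(bed_path, sep="\t")
    missing = [c for c in _BED_COLUMNS if c not in bed.columns]
    if missing:
        raise ParameterError(f"annotation lacks column(s): {', '.join(missing)}")
    expr = (
        pd.read_csv(abundance_path, sep="\t", index_col="gene_id")
        if abundance_path is not None
        else None
    )
    genes = []
    for _, row in bed.iterrows():
        sizes = [int(v) for v in str(row["blockSizes"]).split(",") if v]
        starts = [int(v) for v in str(row["blockStarts"]).split(",") if v]
        if len(sizes) != int(row["blockCount"]) or len(starts) != len(sizes):
            raise ParameterError(f"gene {row['gene_id']}: inconsistent block fields")
        exons = tuple(
            (int(row["start"]) + s, int(row["start"]) + s + sz)
            for s, sz in zip(starts, sizes)
        )
        expr_map = (
            {ct: float(expr.at[row["gene_id"], ct]) for ct in expr.columns}
            if expr is not None and row["gene_id"] in expr.index
            else {}
        )
        genes.append(
            GeneModel(
                gene_id=str(row["gene_id"]),
                chrom=str(row["chrom"]),
                strand=str(row["strand"]),
                exons=exons,
                expr_by_celltype=expr_map,
            )
        )
    chrom_lengths = {
        chrom: int(bed[bed["chrom"] == chrom]["end"].max()) + 210_000
        for chrom in bed["chrom"].unique()
    }
    return Annotation(
        genes=tuple(genes),
        panels=panels or {},
        chrom_lengths=chrom_lengths,
        intergenic_region=None,
    )


def write_panels(panels: Mapping[str, tuple[str, ...]], path) -> None:
    rows = [
        {"cell_type": ct, "gene_id": g} for ct in panels for g in panels[ct]
    ]
    pd.DataFrame(rows, columns=["cell_type", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_panels(path) -> dict[str, tuple[str, ...]]:
    frame = pd.read_csv(path, sep="\t")
    panels: dict[str, list[str]] = {}
    for _, row in frame.iterrows():
        panels.setdefault(str(row["cell_type"]), []).append(str(row["gene_id"]))
    return {ct: tuple(genes) for ct, genes in panels.items()}


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression(table: ExpressionTable, path) -> None:
    """Genes as rows, samples as columns; unit recorded in the index name."""
    out = table.data.T.rename_axis(f"gene_id[{table.unit}]")
    out.to_csv(path, sep="\t")


def read_expression(path) -> ExpressionTable:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    name = frame.index.name or ""
    unit = name[name.find("[") + 1 : name.find("]")] if "[" in name else "count"
    frame.index.name = "gene_id"
    data = frame.T.rename_axis(None, axis=0).rename_axis(None, axis=1)
    if unit == "count":
        data = data.round().astype(int)
    return ExpressionTable(data, unit)


def write_gates(gates: GateSet, path) -> None:
    Path(path).write_text(yaml.safe_dump(gates.to_dict(), sort_keys=True))


def read_gates(path) -> GateSet:
    return GateSet.from_dict(yaml.safe_load(Path(path).read_text()))
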