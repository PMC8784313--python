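"""Housekeeping-normalised qPCR fold enrichment (delta-delta-Ct).

Replicate wells are aggregated by mean CT; the fold change of a sorted
population against the unsorted reference is efficiency**(dCT_ref - dCT_s),
with amplification efficiency fixed at perfect doubling by default.
"""

from __future__ import annotations

import pandas as pd

from .errors import NucsortError, ParameterError

REQUIRED_COLUMNS = ("sample", "gene", "ct")


def _validate_wells(wells: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in wells.columns]
    if missing:
        raise ParameterError(f"wells table lacks column(s): {', '.join(missing)}")
    if len(wells) and not wells["ct"].map(lambda v: v == v and abs(v) != float("inf")).all():
        raise ParameterError("CT values must be finite")


def delta_ct(wells: pd.DataFrame, housekeeping_gene: str) -> pd.DataFrame:
    """Per-(sample, target) dCT = mean(ct_target) - mean(ct_housekeeping).

    Replicate SDs of both the target and housekeeping wells are reported.
    A sample without housekeeping wells is an error naming the sample.
    """
    _validate_wells(wells)
    rows = []
    for sample, group in wells.groupby("sample", sort=False):
        hk = group[group["gene"] == housekeeping_gene]["ct"]
        if hk.empty:
            raise NucsortError(
                f"housekeeping gene {housekeeping_gene!r} not measured in "
                f"sample {sample!r}"
            )
        hk_mean = hk.mean()
        for gene, tg in group[group["gene"] != housekeeping_gene].groupby(
            "gene", sort=False
        ):
            rows.append(
                {
                    "sample": sample,
                    "gene": gene,
                    "delta_ct": float(tg["ct"].mean() - hk_mean),
                    "ct_sd_target": float(tg["ct"].std(ddof=1)) if len(tg) > 1 else 0.0,
                    "ct_sd_housekeeping": float(hk.std(ddof=1)) if len(hk) > 1 else 0.0,
                    "n_replicates": int(len(tg)),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample",
            "gene",
            "delta_ct",
            "ct_sd_target",
            "ct_sd_housekeeping",
            "n_replicates",
        ],
    )


def fold_enrichment(
    delta_sorted: float, delta_unsorted: float, efficiency: float = 2.0
) -> float:
    """Fold change of sorted vs unsorted: efficiency**(dCT_un - dCT_sorted).

    > 1 means enriched in the sorted population, < 1 depleted.
    """
    if efficiency <= 1.0:
        raise ParameterError("amplification efficiency must exceed 1")
    return efficiency ** (delta_unsorted - delta_sorted)


def fold_table(
    delta_table: pd.DataFrame,
    reference_sample: str,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Fold enrichment of every non-reference sample against the reference."""
    ref = delta_table[delta_table["sample"] == reference_sample]
    if ref.empty:
        raise NucsortError(f"reference sample {reference_sample!r} not in dCT table")
    ref_by_gene = dict(zip(ref["gene"], ref["delta_ct"]))
    rows = []
    for _, row in delta_table.iterrows():
        if row["sample"] == reference_sample:
            continue
        if row["gene"] not in ref_by_gene:
            continue
        rows.append(
            {
                "sample": row["sample"],
                "gene": row["gene"],
                "delta_ct": row["delta_ct"],
                "fold_vs_reference": fold_enrichment(
                    row["delta_ct"], ref_by_gene[row["gene"]], efficiency
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["sample", "gene", "delta_ct", "fold_vs_reference"]
    )
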