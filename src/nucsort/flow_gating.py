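"""Gating of nucleus-event tables and in-silico sorting.

Gates are axis-aligned thresholds on log10 intensities.  Lower bounds are
inclusive, upper bounds exclusive.  Populations within the DAPI+/SSC-low
parent gate are mutually exclusive: ErgHi takes precedence over ErgLo, and
Erg positivity takes precedence over NeuN (double positives counted once,
as ErgHi).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParameterError

POPULATIONS = ("ErgHi", "ErgLo", "NeuN", "rest")
NON_NUCLEUS = "non-nucleus"

#: default mapping from sort gate to the class it is intended to capture
LABEL_TO_CLASS: Mapping[str, str] = {
    "ErgHi": "endothelial",
    "ErgLo": "microglia",
    "NeuN": "neuron",
}


@dataclass(frozen=True)
class GateSet:
    """Thresholds (log10 intensity units) defining the four populations."""

    dapi_min: float = 2.5
    ssc_max: float = 3.0
    erg_hi_min: float = 3.1
    erg_lo_min: float = 1.9
    erg_lo_max: float = 3.1
    neun_min: float = 2.3
    erg_precedence: bool = True

    def __post_init__(self) -> None:
        if not self.erg_lo_min < self.erg_lo_max <= self.erg_hi_min:
            raise ParameterError(
                "require erg_lo_min < erg_lo_max <= erg_hi_min "
                f"(got {self.erg_lo_min}, {self.erg_lo_max}, {self.erg_hi_min})"
            )

    def to_dict(self) -> dict:
        return {
            "dapi_min": self.dapi_min,
            "ssc_max": self.ssc_max,
            "erg_hi_min": self.erg_hi_min,
            "erg_lo_min": self.erg_lo_min,
            "erg_lo_max": self.erg_lo_max,
            "neun_min": self.neun_min,
            "erg_precedence": self.erg_precedence,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GateSet":
        return cls(**dict(d))


@dataclass
class GatingResult:
    """Labelled events plus exact population fractions over the parent gate."""

    events: pd.DataFrame  # input columns + "label"
    counts: Mapping[str, int]
    fractions: Mapping[str, Fraction]
    parent_count: int
    total: int
    defined: bool  # False when the parent population is empty

    def fraction_table(self) -> pd.DataFrame:
        rows = [
            {
                "population": pop,
                "count": self.counts[pop],
                "fraction_of_parent": float(self.fractions[pop]) if self.defined else float("nan"),
            }
            for pop in POPULATIONS
        ]
        rows.append(
            {
                "population": NON_NUCLEUS,
                "count": self.counts[NON_NUCLEUS],
                "fraction_of_parent": float("nan"),
            }
        )
        return pd.DataFrame(rows)


def apply_gates(events: pd.DataFrame, gates: GateSet) -> GatingResult:
    """Assign each event exactly one population label and tally fractions.

    Fractions are computed over the DAPI+/SSC-low parent population with
    rational arithmetic, so they sum to 1 exactly whenever the parent is
    non-empty.
    """
    n = len(events)
    if n == 0:
        counts = {pop: 0 for pop in (*POPULATIONS, NON_NUCLEUS)}
        out = events.copy()
        out["label"] = pd.Series([], dtype=object)
        return GatingResult(out, counts, {}, 0, 0, defined=False)

    log = {
        ch: np.log10(events[ch].to_numpy(dtype=float))
        for ch in ("dapi", "ssc", "erg_af647", "neun_pe")
    }
    parent = (log["dapi"] >= gates.dapi_min) & (log["ssc"] < gates.ssc_max)
    erg_hi = log["erg_af647"] >= gates.erg_hi_min
    erg_lo = (log["erg_af647"] >= gates.erg_lo_min) & (
        log["erg_af647"] < gates.erg_lo_max
    )
    neun = log["neun_pe"] >= gates.neun_min

    if gates.erg_precedence:
        conds = [~parent, erg_hi, erg_lo, neun]
        labels = [NON_NUCLEUS, "ErgHi", "ErgLo", "NeuN"]
    else:
        conds = [~parent, neun, erg_hi, erg_lo]
        labels = [NON_NUCLEUS, "NeuN", "ErgHi", "ErgLo"]
    label = np.select(conds, labels, default="rest")

    out = events.copy()
    out["label"] = label
    tally = Counter(label)
    counts = {pop: int(tally.get(pop, 0)) for pop in (*POPULATIONS, NON_NUCLEUS)}
    parent_count = n - counts[NON_NUCLEUS]
    defined = parent_count > 0
    fractions = (
        {pop: Fraction(counts[pop], parent_count) for pop in POPULATIONS}
        if defined
        else {}
    )
    return GatingResult(out, counts, fractions, parent_count, n, defined=defined)


@dataclass
class SortResult:
    """Outcome of selecting up to n_target events with one gate label."""

    label: str
    composition: Mapping[str, int]  # true class -> count
    n_selected: int
    purity: float
    shortfall: bool
    selected_index: pd.Index


def in_silico_sort(
    gated_events: pd.DataFrame,
    label: str,
    n_target: int,
    *,
    intended_class: str | None = None,
) -> SortResult:
    """Select the first ``n_target`` events carrying ``label`` (stream order).

    Requires a ``label`` column (from :func:`apply_gates`) and a
    ``true_class`` column (simulation ground truth).  Purity is the fraction
    of selected events whose true class is the gate's intended class.
    """
    if n_target < 1:
        raise ParameterError("n_target must be >= 1")
    for col in ("label", "true_class"):
        if col not in gated_events.columns:
            raise ParameterError(f"events table lacks required column '{col}'")
    pool = gated_events[gated_events["label"] == label]
    selected = pool.iloc[:n_target]
    shortfall = len(pool) < n_target
    comp = Counter(selected["true_class"])
    intended = intended_class or LABEL_TO_CLASS.get(label)
    n_sel = len(selected)
    purity = comp.get(intended, 0) / n_sel if n_sel and intended else float("nan")
    return SortResult(
        label=label,
        composition={k: int(v) for k, v in comp.items()},
        n_selected=n_sel,
        purity=purity,
        shortfall=shortfall,
        selected_index=selected.index,
    )
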