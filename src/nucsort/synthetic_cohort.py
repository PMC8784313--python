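"""Synthetic cohort simulator: annotation, flow events, SAM reads, qPCR plates.

Everything downstream of the wet lab is exercisable on the outputs of this
module: a small genome with multi-exon gene models, per-cell-type expression
with panel structure, log-normal fluorescence mixtures, aligned-read streams
containing junction / intronic / intergenic classes, and CT tables.

All randomness flows from a single integer seed; independent operations use
fixed integer stream tags so that calling one simulator does not perturb
another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError

# All simulated classes.  "other" is the catch-all non-endothelial,
# non-neuronal, non-glial background population.
CELL_TYPES: tuple[str, ...] = (
    "endothelial",
    "neuron",
    "microglia",
    "astrocyte",
    "oligodendrocyte",
    "OPC",
    "other",
)

CHANNELS: tuple[str, ...] = ("dapi", "ssc", "erg_af647", "neun_pe")

# Well-known marker names are assigned to the first genes of each panel so
# that configs can refer to familiar symbols (qPCR targets, QC genes).
_ALIASES: Mapping[str, Sequence[str]] = {
    "endothelial": ("Cldn5", "Cdh5", "Vwf", "Erg", "Pecam1", "Icam2"),
    "neuron": ("Map2", "Rbfox3", "Meg3"),
    "microglia": ("Ptprc", "Aif1"),
    "astrocyte": ("Aqp4",),
    "oligodendrocyte": ("Mbp",),
    "OPC": ("Pdgfra",),
}
_HOUSEKEEPING: Sequence[str] = ("Ubc", "Actb")

# RNG stream tags (arbitrary fixed integers, one per stochastic operation).
_TAG_ANNOTATION = 11
_TAG_EVENTS = 23
_TAG_READS = 37
_TAG_QPCR = 53
_TAG_REFERENCE = 71


def _rng(seed, tag: int) -> np.random.Generator:
    if isinstance(seed, (list, tuple)):
        return np.random.default_rng([*seed, tag])
    return np.random.default_rng([int(seed), tag])


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """One gene: coordinates, strand, exons, per-cell-type true abundance.

    Coordinates are 0-based half-open throughout; SAM emission converts to
    1-based.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    expr_by_celltype: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ParameterError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ParameterError(f"{self.gene_id}: at least one exon required")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ParameterError(f"{self.gene_id}: empty exon [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise ParameterError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e
        if any(v < 0 for v in self.expr_by_celltype.values()):
            raise ParameterError(f"{self.gene_id}: negative abundance")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )


@dataclass(frozen=True)
class CellTypeProfile:
    """Mixture component: a class fraction plus per-channel log10 params.

    ``channels`` maps channel name -> (location, scale) of the base-10
    log-normal: log10(intensity) ~ Normal(location, scale).
    """

    name: str
    mixture_fraction: float
    channels: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if not 0.0 <= self.mixture_fraction <= 1.0:
            raise ParameterError(f"{self.name}: mixture_fraction outside [0,1]")
        for ch in CHANNELS:
            if ch not in self.channels:
                raise ParameterError(f"{self.name}: missing channel {ch}")
            loc, scale = self.channels[ch]
            if not (np.isfinite(loc) and np.isfinite(scale)) or scale <= 0:
                raise ParameterError(
                    f"{self.name}: channel {ch} scale must be positive and finite"
                )


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic cohort; the seed fully determines output."""

    n_genes: int = 300
    n_marker_genes_per_type: int = 20
    n_events: int = 20_000
    read_depth: int = 30_000
    dna_contamination_fraction: float = 0.15
    intronic_read_fraction: float = 0.35
    fixation: str = "fixed"
    rna_recovery_factor_unfixed: float = 0.25
    read_length: int = 150
    marker_exclusivity: float = 0.95
    marker_abundance: float = 10.0
    shared_abundance: float = 1.0
    abundance_log2_sd: float = 0.75
    qpcr_ct_ref: float = 30.0
    qpcr_noise_sd: float = 0.15
    qpcr_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dna_contamination_fraction", "intronic_read_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0,1]")
        if not 0.0 < self.rna_recovery_factor_unfixed <= 1.0:
            raise ParameterError("rna_recovery_factor_unfixed outside (0,1]")
        if self.fixation not in ("fixed", "unfixed"):
            raise ParameterError("fixation must be 'fixed' or 'unfixed'")
        if not 0.0 <= self.marker_exclusivity <= 1.0:
            raise ParameterError("marker_exclusivity outside [0,1]")
        if self.qpcr_noise_sd < 0:
            raise ParameterError("qpcr_noise_sd must be >= 0")
        if self.n_genes < 1 or self.n_events < 0 or self.read_depth < 0:
            raise ParameterError("n_genes/n_events/read_depth out of range")
        if self.read_length < 20:
            raise ParameterError("read_length must be >= 20")


@dataclass(frozen=True)
class Annotation:
    """Gene models plus marker-panel bookkeeping for one simulated genome."""

    genes: tuple[GeneModel, ...]
    panels: Mapping[str, tuple[str, ...]]
    chrom_lengths: Mapping[str, int]
    intergenic_region: tuple[str, int, int] | None = None

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g.gene_id for g in self.genes)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def expr(self) -> pd.DataFrame:
        """Gene x cell-type abundance matrix (column order = CELL_TYPES)."""
        data = {
            g.gene_id: [g.expr_by_celltype.get(ct, 0.0) for ct in CELL_TYPES]
            for g in self.genes
        }
        return pd.DataFrame(data, index=list(CELL_TYPES)).T


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def make_annotation(config: SimConfig) -> Annotation:
    """Build a deterministic gene annotation with disjoint marker panels.

    Each of the 7 cell types gets ``n_marker_genes_per_type`` own genes whose
    abundance share in the owning type is ``marker_exclusivity`` (>= 0.9 by
    default); remaining genes are expressed equally everywhere.  Per-type
    abundance columns are normalised to a common total so that mixture-
    weighted library sizes are composition-invariant.
    """
    k = config.n_marker_genes_per_type
    n_types = len(CELL_TYPES)
    if config.n_genes < n_types * k:
        raise ParameterError(
            f"n_genes={config.n_genes} cannot host {n_types} panels of {k} markers"
        )
    rng = _rng(config.seed, _TAG_ANNOTATION)

    ids: list[str] = []
    owners: list[str | None] = []
    for ct in CELL_TYPES:
        aliases = _ALIASES.get(ct, ())
        for i in range(k):
            ids.append(aliases[i] if i < len(aliases) else f"{ct}_m{i:03d}")
            owners.append(ct)
    n_shared = config.n_genes - n_types * k
    for i in range(n_shared):
        ids.append(_HOUSEKEEPING[i] if i < len(_HOUSEKEEPING) else f"shared_{i:04d}")
        owners.append(None)

    # Raw abundance matrix, columns = cell types.  Marker genes vary both in
    # overall abundance (log-normal) and in how concentrated they are in the
    # owning type (uniform on [marker_exclusivity, 1]).
    a, x_min, s = config.marker_abundance, config.marker_exclusivity, config.shared_abundance
    mat = np.zeros((config.n_genes, n_types))
    jitter = np.power(2.0, rng.normal(0.0, config.abundance_log2_sd, config.n_genes))
    exclusivity = rng.uniform(x_min, 1.0, config.n_genes)
    for gi, owner in enumerate(owners):
        if owner is None:
            mat[gi, :] = s * jitter[gi]
        else:
            oi = CELL_TYPES.index(owner)
            x = exclusivity[gi]
            mat[gi, :] = a * jitter[gi] * (1.0 - x) / (n_types - 1)
            mat[gi, oi] = a * jitter[gi] * x
    # Normalise each type column to a fixed total (keeps TPM denominators
    # composition-invariant).
    totals = mat.sum(axis=0)
    if np.any(totals <= 0):
        raise ParameterError("a cell type has zero total abundance")
    mat = mat / totals * 1000.0

    min_intron = 2 * config.read_length
    chrom = "chr1"
    cursor = 10_000
    genes: list[GeneModel] = []
    for gi, gid in enumerate(ids):
        n_exons = int(rng.integers(2, 5))
        exon_lens = rng.integers(max(200, config.read_length + 50), 401, n_exons)
        intron_lens = rng.integers(min_intron, max(min_intron + 1, 1501), n_exons - 1)
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = cursor
        for j in range(n_exons):
            exons.append((pos, pos + int(exon_lens[j])))
            pos += int(exon_lens[j])
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        cursor = pos + 5_000
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exons=tuple(exons),
                expr_by_celltype={ct: float(mat[gi, ti]) for ti, ct in enumerate(CELL_TYPES)},
            )
        )

    intergenic_start = cursor + 10_000
    chrom_len = intergenic_start + 200_000
    panels = {
        ct: tuple(ids[ti * k : (ti + 1) * k]) for ti, ct in enumerate(CELL_TYPES)
    }
    return Annotation(
        genes=tuple(genes),
        panels=panels,
        chrom_lengths={chrom: chrom_len},
        intergenic_region=(chrom, intergenic_start, chrom_len - 1_000),
    )


# ---------------------------------------------------------------------------
# Flow events
# ---------------------------------------------------------------------------

# log10 (location, scale) per channel; non-listed types fall back to "other".
_DEFAULT_CHANNELS: Mapping[str, Mapping[str, tuple[float, float]]] = {
    "dapi": {"*": (3.5, 0.15)},
    "ssc": {"*": (2.0, 0.20)},
    "erg_af647": {"endothelial": (3.6, 0.15), "microglia": (2.4, 0.15), "*": (1.0, 0.20)},
    "neun_pe": {"neuron": (3.0, 0.15), "*": (1.0, 0.20)},
}


def default_profiles(fractions: Mapping[str, float]) -> list[CellTypeProfile]:
    """Profiles with cleanly separated ErgHi / ErgLo / NeuN clouds."""
    unknown = sorted(set(fractions) - set(CELL_TYPES))
    if unknown:
        raise ParameterError(f"unknown cell type(s): {', '.join(unknown)}")
    profiles = []
    for ct, frac in fractions.items():
        channels = {
            ch: spec.get(ct, spec["*"]) for ch, spec in _DEFAULT_CHANNELS.items()
        }
        profiles.append(CellTypeProfile(name=ct, mixture_fraction=frac, channels=channels))
    return profiles


def profile_separation(a: CellTypeProfile, b: CellTypeProfile, channel: str) -> float:
    """Separation between two profiles on one channel, in scale units."""
    la, sa = a.channels[channel]
    lb, sb = b.channels[channel]
    return abs(la - lb) / max(sa, sb)


def simulate_events(
    profiles: Sequence[CellTypeProfile],
    config: SimConfig,
    *,
    seed=None,
    n_events: int | None = None,
    min_separation: float | None = None,
) -> pd.DataFrame:
    """Draw nucleus events from the mixture of profiles.

    Returns a DataFrame with columns dapi, ssc, erg_af647, neun_pe,
    true_class.  ``min_separation`` optionally enforces the selection-channel
    separation (scale units) between the endothelial/neuronal profiles and
    the "other" profile.
    """
    if not profiles:
        raise ParameterError("at least one profile required")
    fracs = np.array([p.mixture_fraction for p in profiles], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ParameterError(f"mixture fractions sum to {fracs.sum()}, not 1")
    if min_separation is not None:
        by_name = {p.name: p for p in profiles}
        other = by_name.get("other")
        if other is not None:
            for name, ch in (("endothelial", "erg_af647"), ("neuron", "neun_pe")):
                p = by_name.get(name)
                if p is not None and profile_separation(p, other, ch) < min_separation:
                    raise ParameterError(
                        f"{name} vs other separation on {ch} below {min_separation}"
                    )

    n = config.n_events if n_events is None else int(n_events)
    rng = _rng(config.seed if seed is None else seed, _TAG_EVENTS)
    cols = {ch: np.empty(n, dtype=float) for ch in CHANNELS}
    if n == 0:
        frame = pd.DataFrame(cols)
        frame["true_class"] = pd.Series([], dtype=str)
        return frame
    idx = rng.choice(len(profiles), size=n, p=fracs)
    for ch in CHANNELS:
        locs = np.array([p.channels[ch][0] for p in profiles])
        scales = np.array([p.channels[ch][1] for p in profiles])
        cols[ch] = np.power(10.0, rng.normal(locs[idx], scales[idx]))
    frame = pd.DataFrame(cols)
    frame["true_class"] = np.array([profiles[i].name for i in idx], dtype=object)
    return frame


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


def _gene_weights(
    composition: Mapping[str, float], annotation: Annotation
) -> np.ndarray:
    unknown = sorted(set(composition) - set(CELL_TYPES))
    if unknown:
        raise ParameterError(f"unknown cell type(s) in composition: {', '.join(unknown)}")
    if not composition:
        raise ParameterError("composition is empty")
    expr = annotation.expr  # genes x cell types
    w = np.zeros(len(annotation.genes))
    for ct, count in composition.items():
        if count < 0:
            raise ParameterError(f"negative count for {ct}")
        w += float(count) * expr[ct].to_numpy()
    if w.sum() <= 0:
        raise ParameterError("composition-weighted abundance is zero everywhere")
    return w


def simulate_reads(
    composition: Mapping[str, float],
    annotation: Annotation,
    config: SimConfig,
    *,
    seed=None,
) -> list[str]:
    """Emit a SAM text stream (header lines + alignment records).

    Read classes: a ``dna_contamination_fraction`` of reads are junctionless
    intergenic placements; of the gene-derived remainder,
    ``intronic_read_fraction`` are junctionless intronic reads and the rest
    span one exon-exon junction (CIGAR ``uM<intron>N(L-u)M``).  QNAMEs encode
    the read class and generating gene for ground-truth checks.
    """
    weights = _gene_weights(composition, annotation)
    p_gene = weights / weights.sum()
    rng = _rng(config.seed if seed is None else seed, _TAG_READS)
    L = config.read_length

    factor = config.rna_recovery_factor_unfixed if config.fixation == "unfixed" else 1.0
    n_total = int(round(config.read_depth * factor))

    header = [
        "@HD\tVN:1.6\tSO:unsorted",
        *(
            f"@SQ\tSN:{chrom}\tLN:{length}"
            for chrom, length in annotation.chrom_lengths.items()
        ),
    ]
    if n_total == 0:
        return header

    is_dna = rng.random(n_total) < config.dna_contamination_fraction
    n_gene_reads = int((~is_dna).sum())
    gene_idx = (
        rng.choice(len(annotation.genes), size=n_gene_reads, p=p_gene)
        if n_gene_reads
        else np.empty(0, dtype=int)
    )
    is_intronic = rng.random(n_gene_reads) < config.intronic_read_fraction

    ig_chrom, ig_start, ig_end = annotation.intergenic_region
    records: list[str] = []
    gi = 0  # cursor into gene_idx / is_intronic
    for i in range(n_total):
        if is_dna[i]:
            pos0 = int(rng.integers(ig_start, ig_end - L))
            records.append(
                f"r{i:07d}|intergenic|*\t0\t{ig_chrom}\t{pos0 + 1}\t255\t{L}M"
                "\t*\t0\t0\t*\t*"
            )
            continue
        gene = annotation.genes[gene_idx[gi]]
        flag = 0 if gene.strand == "+" else 16
        if is_intronic[gi]:
            introns = gene.introns
            s, e = introns[int(rng.integers(len(introns)))]
            off = int(rng.integers(0, e - s - L + 1))
            pos0 = s + off
            cigar = f"{L}M"
            cls = "intronic"
        else:
            exons = gene.exons
            j = int(rng.integers(len(exons) - 1))
            left_end = exons[j][1]
            intron_len = exons[j + 1][0] - left_end
            u = int(rng.integers(10, L - 9))
            pos0 = left_end - u
            cigar = f"{u}M{intron_len}N{L - u}M"
            cls = "junction"
        records.append(
            f"r{i:07d}|{cls}|{gene.gene_id}\t{flag}\t{gene.chrom}\t{pos0 + 1}\t255\t"
            f"{cigar}\t*\t0\t0\t*\t*"
        )
        gi += 1
    return header + records


def write_sam(lines: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line)
            fh.write("\n")


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def simulate_qpcr(
    compositions: Mapping[str, Mapping[str, float]],
    targets: Sequence[str],
    housekeeping: str,
    annotation: Annotation | None,
    config: SimConfig,
    *,
    seed=None,
    abundances: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Simulate CT values: CT = ct_ref - log2(weighted abundance) + noise.

    ``compositions`` maps sample label -> {cell type: nucleus count}; gene
    abundance per sample is the composition-weighted mean of the annotation's
    per-type abundances.  Supplying ``abundances`` ({sample: {gene: value}})
    bypasses the composition weighting (direct control for tests).
    Returns a tidy frame (sample, gene, replicate, ct).
    """
    rng = _rng(config.seed if seed is None else seed, _TAG_QPCR)
    genes = [*targets, housekeeping]
    rows = []
    samples = list(abundances) if abundances is not None else list(compositions)
    for sample in samples:
        if abundances is not None:
            gene_abund = abundances[sample]
        else:
            comp = compositions[sample]
            total = sum(comp.values())
            if total <= 0:
                raise ParameterError(f"sample {sample}: empty composition")
            expr = annotation.expr
            gene_abund = {}
            for g in genes:
                if g not in expr.index:
                    raise ParameterError(f"gene {g} not in annotation")
                gene_abund[g] = float(
                    sum(comp[ct] * expr.at[g, ct] for ct in comp) / total
                )
        for g in genes:
            a = gene_abund.get(g, 0.0)
            if a <= 0:
                kind = "housekeeping" if g == housekeeping else "target"
                raise ParameterError(
                    f"sample {sample}: zero abundance for {kind} gene {g}; CT undefined"
                )
            base = config.qpcr_ct_ref - math.log2(a)
            noise = (
                rng.normal(0.0, config.qpcr_noise_sd, config.qpcr_replicates)
                if config.qpcr_noise_sd > 0
                else np.zeros(config.qpcr_replicates)
            )
            for r in range(config.qpcr_replicates):
                rows.append((sample, g, r + 1, base + float(noise[r])))
    return pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"])


# ---------------------------------------------------------------------------
# Reference expression (gold-standard style tables)
# ---------------------------------------------------------------------------


def reference_expression(
    annotation: Annotation,
    weights: Mapping[str, float],
    *,
    noise_sd: float = 0.0,
    seed=0,
) -> pd.Series:
    """A reference expression vector (RPM-scaled) for a weighted cell mix.

    Emulates externally published per-gene tables (whole-cell sorted
    populations, nuclei cluster averages): composition-weighted true
    abundance with optional per-gene multiplicative log2-normal noise.
    """
    w = _gene_weights(weights, annotation)
    if noise_sd > 0:
        rng = _rng(seed, _TAG_REFERENCE)
        w = w * np.power(2.0, rng.normal(0.0, noise_sd, len(w)))
    w = w / w.sum() * 1e6
    return pd.Series(w, index=list(annotation.gene_ids), name="rpm")


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Convenience: a copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
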