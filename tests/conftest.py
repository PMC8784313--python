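import pytest

from nucsort import Annotation, GeneModel, SimConfig, make_annotation


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=1234)


@pytest.fixture(scope="session")
def annotation(sim_config) -> Annotation:
    return make_annotation(sim_config)


@pytest.fixture()
def two_gene_annotation() -> Annotation:
    """Tiny hand-built annotation: two 2-exon genes on one chromosome."""
    gene_a = GeneModel(
        gene_id="A",
        chrom="chr1",
        strand="+",
        exons=((1000, 1400), (1800, 2200)),
        expr_by_celltype={"endothelial": 1.0, "other": 1.0},
    )
    gene_b = GeneModel(
        gene_id="B",
        chrom="chr1",
        strand="-",
        exons=((5000, 5400), (5900, 6300)),
        expr_by_celltype={"endothelial": 1.0, "other": 1.0},
    )
    return Annotation(
        genes=(gene_a, gene_b),
        panels={},
        chrom_lengths={"chr1": 50_000},
        intergenic_region=("chr1", 10_000, 40_000),
    )


def sam_line(
    qname="r1",
    flag=0,
    chrom="chr1",
    pos=100,
    mapq=255,
    cigar="150M",
) -> str:
    return f"{qname}\t{flag}\t{chrom}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t*\t*"
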