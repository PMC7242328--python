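import pytest

from memvar import make_bundle
from memvar.reference_store import (
    AnnotationBundle,
    GeneModel,
    GenomeSequence,
    ProteinRecord,
    TopologyFeature,
    reverse_complement,
    translate,
)


def build_toy_bundle(sense_cds: str, strand: str = "+", pad: int = 30,
                     intron_at: int | None = None,
                     topology: tuple = ()) -> AnnotationBundle:
    """Single-gene bundle around an explicit sense-orientation CDS.

    ``intron_at`` splits the CDS after that many bases and inserts a short
    intron.  For '-' strand genes the genomic region carries the reverse
    complement of the (possibly intron-containing) pre-mRNA.
    """
    if intron_at is not None:
        intron = "GT" + "ACGT" * 5 + "AG"
        region = sense_cds[:intron_at] + intron + sense_cds[intron_at:]
        sense_exons = [(1, intron_at), (intron_at + len(intron) + 1, len(region))]
    else:
        region = sense_cds
        sense_exons = [(1, len(region))]
    left = "C" * pad
    right = "G" * pad
    if strand == "+":
        genome_seq = left + region + right
    else:
        genome_seq = left + reverse_complement(region) + right
    region_start = pad + 1
    R = len(region)
    if strand == "+":
        exons = [(region_start + a - 1, region_start + b - 1) for a, b in sense_exons]
    else:
        exons = sorted(
            (region_start + (R - b), region_start + (R - a)) for a, b in sense_exons
        )
    protein, _ = translate(sense_cds)
    model = GeneModel("G1", "chr_t", strand, tuple(exons), "P1", "toy37")
    record = ProteinRecord("P1", protein, tuple(topology))
    return AnnotationBundle(
        genome={"chr_t": GenomeSequence("chr_t", genome_seq)},
        models={"G1": model},
        proteins={"P1": record},
    )


@pytest.fixture(scope="session")
def fixture_bundle():
    """A 9-gene synthetic bundle shared by read-only tests."""
    return make_bundle(11, n_genes=9)


def tm_protein(length: int = 993, tm=(540, 563)) -> ProteinRecord:
    """Type-I record with an adjustable TM span and cytoplasmic tail."""
    feats = (
        TopologyFeature("signal_peptide", 1, 20),
        TopologyFeature("extracellular", 21, tm[0] - 1),
        TopologyFeature("transmembrane", tm[0], tm[1]),
        TopologyFeature("cytoplasmic", tm[1] + 1, length),
    )
    return ProteinRecord("PTM", "A" * length, feats)
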