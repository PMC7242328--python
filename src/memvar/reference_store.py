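"""Reference bundle: genome sequences, gene models, protein topology, lookups.

A bundle is the local stand-in for the genome build / protein knowledgebase
pair a full-scale annotator would query: chromosome sequences (FASTA),
strand-aware CDS exon structures tying each gene to a protein, protein
records carrying curated topology features (signal peptide, extracellular,
transmembrane, cytoplasmic spans), and optional exact-key lookup tables for
rsIDs and drug-target agents.

Coordinates are 1-based inclusive throughout, matching VCF convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

VALID_DNA = set("ACGTN")
VALID_STRANDS = {"+", "-"}
TOPOLOGY_KINDS = ("signal_peptide", "extracellular", "transmembrane", "cytoplasmic")

_CODON_TO_AA = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
START_CODON = "ATG"


class BundleError(Exception):
    """Base class for reference-bundle problems."""


class BundleParseError(BundleError):
    """A bundle file failed to parse; message carries the file and line."""


class ResolutionError(BundleError):
    """A cross-reference (chrom or protein id) did not resolve."""


class BundleValidationError(BundleError):
    """One or more records violated a structural invariant."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "bundle validation failed:\n" + "\n".join(f"  - {v}" for v in violations)
        )


class SequenceBoundsError(BundleError):
    """An interval fell outside its chromosome or protein."""


@dataclass(frozen=True)
class GenomeSequence:
    chrom: str
    seq: str

    def __post_init__(self):
        if not self.chrom:
            raise BundleValidationError(["genome record with empty chrom name"])
        if not self.seq:
            raise BundleValidationError([f"{self.chrom}: empty sequence"])
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)

    def slice(self, start: int, end: int) -> str:
        """1-based inclusive slice with bounds checking."""
        if start < 1 or end > len(self.seq) or start > end:
            raise SequenceBoundsError(
                f"{self.chrom}:{start}-{end} outside 1-{len(self.seq)}"
            )
        return self.seq[start - 1 : end]


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware CDS exon structure tying a genomic locus to a protein."""

    gene_id: str
    chrom: str
    strand: str
    cds_exons: tuple[tuple[int, int], ...]
    protein_id: str
    build: str = "toy37"

    def __post_init__(self):
        object.__setattr__(
            self, "cds_exons", tuple((int(s), int(e)) for s, e in self.cds_exons)
        )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint: first exon start to last exon end."""
        return self.cds_exons[0][0], self.cds_exons[-1][1]

    def structural_violations(self) -> list[str]:
        out = []
        if self.strand not in VALID_STRANDS:
            out.append(f"{self.gene_id}: invalid strand {self.strand!r}")
        if not self.cds_exons:
            out.append(f"{self.gene_id}: no CDS exons")
            return out
        prev_end = 0
        for s, e in self.cds_exons:
            if s < 1 or e < s:
                out.append(f"{self.gene_id}: malformed exon interval {s}-{e}")
            if s <= prev_end:
                out.append(f"{self.gene_id}: exons overlap or are unsorted at {s}-{e}")
            prev_end = max(prev_end, e)
        if self.cds_length % 3 != 0:
            out.append(f"{self.gene_id}: CDS length not divisible by 3 ({self.cds_length})")
        return out


@dataclass(frozen=True)
class TopologyFeature:
    kind: str
    start: int
    end: int

    def __post_init__(self):
        if self.kind not in TOPOLOGY_KINDS:
            raise BundleValidationError([f"unknown topology kind {self.kind!r}"])

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    sequence: str
    topology: tuple[TopologyFeature, ...] = ()
    xrefs: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(
            self, "topology", tuple(sorted(self.topology, key=lambda f: f.start))
        )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def transmembrane_features(self) -> tuple[TopologyFeature, ...]:
        return tuple(f for f in self.topology if f.kind == "transmembrane")

    @property
    def is_bitopic(self) -> bool:
        """Single-pass membrane protein (exactly one TM span)."""
        return len(self.transmembrane_features) == 1

    def structural_violations(self) -> list[str]:
        out = []
        n = len(self.sequence)
        prev_end = 0
        for f in self.topology:
            if not (1 <= f.start <= f.end <= n):
                out.append(
                    f"{self.protein_id}: feature {f.kind} {f.start}-{f.end} outside 1-{n}"
                )
            if f.start <= prev_end:
                out.append(
                    f"{self.protein_id}: overlapping features at {f.kind} {f.start}-{f.end}"
                )
            prev_end = max(prev_end, f.end)
        return out


@dataclass
class AnnotationBundle:
    """In-memory reference store serving annotation queries."""

    genome: dict[str, GenomeSequence]
    models: dict[str, GeneModel]
    proteins: dict[str, ProteinRecord]
    rsid_lookup: dict[tuple[str, int, str, str], str] = field(default_factory=dict)
    drug_lookup: dict[str, list[str]] = field(default_factory=dict)

    @property
    def build(self) -> str:
        builds = {m.build for m in self.models.values()}
        return next(iter(builds)) if len(builds) == 1 else "mixed"


# ---------------------------------------------------------------------------
# Core sequence operations
# ---------------------------------------------------------------------------

def reverse_complement(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


def cds_sequence(model: GeneModel, genome: dict[str, GenomeSequence] | AnnotationBundle) -> str:
    """Spliced, strand-corrected coding sequence of a gene model.

    Exon slices are concatenated in genomic order and reverse-complemented
    as a whole for '-' strand genes, which equals concatenating the
    reverse-complemented exons in transcription order.
    """
    chroms = genome.genome if isinstance(genome, AnnotationBundle) else genome
    if model.chrom not in chroms:
        raise ResolutionError(f"{model.gene_id}: chrom {model.chrom!r} not in genome")
    chrom = chroms[model.chrom]
    forward = "".join(chrom.slice(s, e) for s, e in model.cds_exons)
    return reverse_complement(forward) if model.strand == "-" else forward


def translate(dna: str) -> tuple[str, bool]:
    """Translate codon-by-codon from position 1, standard nuclear code.

    Stops at the first stop codon (excluded from the returned protein);
    ``terminated`` is False when no stop codon is reached.  A trailing
    partial codon is discarded.  Any codon containing a base outside
    A/C/G/T (e.g. N) translates to 'X'.
    """
    dna = dna.upper()
    aas = []
    for i in range(0, len(dna) - len(dna) % 3, 3):
        codon = dna[i : i + 3]
        if codon in STOP_CODONS:
            return "".join(aas), True
        aas.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(aas), False


# ---------------------------------------------------------------------------
# Bundle file readers / writers
# ---------------------------------------------------------------------------

def read_genome_fasta(path) -> dict[str, GenomeSequence]:
    out: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise BundleParseError(f"{path}: duplicate chrom {rec.id!r}")
        out[rec.id] = GenomeSequence(rec.id, str(rec.seq))
    if not out:
        raise BundleParseError(f"{path}: no FASTA records")
    return out


def _parse_exons(text: str, path, lineno: int) -> tuple[tuple[int, int], ...]:
    exons = []
    for part in text.split(";"):
        try:
            s, e = part.split("-")
            exons.append((int(s), int(e)))
        except ValueError as exc:
            raise BundleParseError(
                f"{path}:{lineno}: malformed exon interval {part!r}"
            ) from exc
    return tuple(exons)


MODELS_COLUMNS = ["gene_id", "chrom", "strand", "protein_id", "build", "exons"]


def read_gene_models_tsv(path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != MODELS_COLUMNS[:4]:
            raise BundleParseError(f"{path}: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise BundleParseError(f"{path}:{lineno}: expected {len(header)} columns")
            row = dict(zip(header, fields))
            models.append(
                GeneModel(
                    gene_id=row["gene_id"],
                    chrom=row["chrom"],
                    strand=row["strand"],
                    cds_exons=_parse_exons(row["exons"], path, lineno),
                    protein_id=row["protein_id"],
                    build=row.get("build", "toy37"),
                )
            )
    return models


def read_gene_models_gff3(path, build: str = "toy37") -> list[GeneModel]:
    """GFF3-subset reader: CDS feature rows grouped by their ID attribute.

    Expected attributes per CDS row: ``ID=<gene_id>;protein_id=<pid>``.
    """
    groups: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise BundleParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "CDS":
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if "ID" not in attr:
                raise BundleParseError(f"{path}:{lineno}: CDS row without ID attribute")
            g = groups.setdefault(
                attr["ID"],
                {"chrom": chrom, "strand": strand,
                 "protein_id": attr.get("protein_id", attr["ID"]), "exons": []},
            )
            try:
                g["exons"].append((int(start), int(end)))
            except ValueError as exc:
                raise BundleParseError(f"{path}:{lineno}: malformed interval") from exc
    return [
        GeneModel(
            gene_id=gid,
            chrom=g["chrom"],
            strand=g["strand"],
            cds_exons=tuple(sorted(g["exons"])),
            protein_id=g["protein_id"],
            build=build,
        )
        for gid, g in groups.items()
    ]


def read_topology_tsv(path) -> dict[str, list[TopologyFeature]]:
    out: dict[str, list[TopologyFeature]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["protein_id", "kind", "start", "end"]:
            raise BundleParseError(f"{path}: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                pid, kind, start, end = line.rstrip("\n").split("\t")
                feat = TopologyFeature(kind, int(start), int(end))
            except (ValueError, BundleValidationError) as exc:
                raise BundleParseError(f"{path}:{lineno}: {exc}") from exc
            out.setdefault(pid, []).append(feat)
    return out


def read_protein_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_rsid_tsv(path) -> dict[tuple[str, int, str, str], str]:
    out = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["chrom", "pos", "ref", "alt", "rsid"]:
            raise BundleParseError(f"{path}: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                chrom, pos, ref, alt, rsid = line.rstrip("\n").split("\t")
                out[(chrom, int(pos), ref, alt)] = rsid
            except ValueError as exc:
                raise BundleParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def read_drug_tsv(path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["protein_id", "agent"]:
            raise BundleParseError(f"{path}: unexpected header {header!r}")
        for line in fh:
            if not line.strip():
                continue
            pid, agent = line.rstrip("\n").split("\t")
            out.setdefault(pid, []).append(agent)
    return out


def load_bundle(
    genome_path,
    models_path,
    topology_path,
    proteins_path,
    rsid_path=None,
    drugs_path=None,
    *,
    strict: bool = True,
) -> AnnotationBundle:
    """Load and validate a reference bundle from its on-disk files.

    Validation failures are collected per record; with ``strict`` (default)
    any failure raises :class:`BundleValidationError` listing all of them.
    """
    genome = read_genome_fasta(genome_path)
    models = read_gene_models_tsv(models_path)
    topology = read_topology_tsv(topology_path)
    sequences = read_protein_fasta(proteins_path)

    proteins = {
        pid: ProteinRecord(pid, seq, tuple(topology.get(pid, ())))
        for pid, seq in sequences.items()
    }
    bundle = AnnotationBundle(
        genome=genome,
        models={m.gene_id: m for m in models},
        proteins=proteins,
        rsid_lookup=read_rsid_tsv(rsid_path) if rsid_path else {},
        drug_lookup=read_drug_tsv(drugs_path) if drugs_path else {},
    )
    violations = validate_bundle(bundle)
    if strict and violations:
        raise BundleValidationError(violations)
    return bundle


def validate_bundle(bundle: AnnotationBundle) -> list[str]:
    """Structural and consistency report; empty list means a clean bundle."""
    violations: list[str] = []
    builds = {m.build for m in bundle.models.values()}
    if len(builds) > 1:
        violations.append(f"mixed genome builds in one bundle: {sorted(builds)}")
    for model in bundle.models.values():
        violations.extend(model.structural_violations())
        if model.chrom not in bundle.genome:
            violations.append(
                f"{model.gene_id}: unresolved chrom {model.chrom!r}"
            )
            continue
        if model.protein_id not in bundle.proteins:
            violations.append(
                f"{model.gene_id}: unresolved protein {model.protein_id!r}"
            )
            continue
        if model.structural_violations():
            continue
        try:
            cds = cds_sequence(model, bundle)
        except SequenceBoundsError as exc:
            violations.append(f"{model.gene_id}: {exc}")
            continue
        if cds[:3] != START_CODON:
            violations.append(f"{model.gene_id}: CDS does not start with ATG")
        if cds[-3:] not in STOP_CODONS:
            violations.append(f"{model.gene_id}: CDS does not end with a stop codon")
        protein, _terminated = translate(cds)
        expected = bundle.proteins[model.protein_id].sequence
        if protein != expected:
            violations.append(
                f"{model.protein_id}: protein sequence does not equal CDS translation"
            )
    for record in bundle.proteins.values():
        violations.extend(record.structural_violations())
    return violations


def write_bundle(bundle: AnnotationBundle, outdir) -> dict[str, str]:
    """Serialize a bundle back to its on-disk formats; returns the paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "models": os.path.join(outdir, "models.tsv"),
        "topology": os.path.join(outdir, "topology.tsv"),
        "proteins": os.path.join(outdir, "proteins.fa"),
    }
    with open(paths["genome"], "w") as fh:
        for chrom in bundle.genome.values():
            fh.write(f">{chrom.chrom}\n")
            for i in range(0, len(chrom.seq), 70):
                fh.write(chrom.seq[i : i + 70] + "\n")
    with open(paths["models"], "w") as fh:
        fh.write("\t".join(MODELS_COLUMNS) + "\n")
        for m in bundle.models.values():
            exons = ";".join(f"{s}-{e}" for s, e in m.cds_exons)
            fh.write(
                f"{m.gene_id}\t{m.chrom}\t{m.strand}\t{m.protein_id}\t{m.build}\t{exons}\n"
            )
    with open(paths["topology"], "w") as fh:
        fh.write("protein_id\tkind\tstart\tend\n")
        for p in bundle.proteins.values():
            for f in p.topology:
                fh.write(f"{p.protein_id}\t{f.kind}\t{f.start}\t{f.end}\n")
    with open(paths["proteins"], "w") as fh:
        for p in bundle.proteins.values():
            fh.write(f">{p.protein_id}\n")
            for i in range(0, len(p.sequence), 70):
                fh.write(p.sequence[i : i + 70] + "\n")
    if bundle.rsid_lookup:
        paths["rsid"] = os.path.join(outdir, "rsid.tsv")
        with open(paths["rsid"], "w") as fh:
            fh.write("chrom\tpos\tref\talt\trsid\n")
            for (chrom, pos, ref, alt), rsid in bundle.rsid_lookup.items():
                fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{rsid}\n")
    if bundle.drug_lookup:
        paths["drugs"] = os.path.join(outdir, "drugs.tsv")
        with open(paths["drugs"], "w") as fh:
            fh.write("protein_id\tagent\n")
            for pid, agents in bundle.drug_lookup.items():
                for agent in agents:
                    fh.write(f"{pid}\t{agent}\n")
    return paths


def mutated_protein_record(record: ProteinRecord, sequence: str, topology) -> ProteinRecord:
    """A copy of ``record`` with a replacement sequence and topology."""
    return replace(record, sequence=sequence, topology=tuple(topology))
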