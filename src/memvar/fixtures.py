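"""Synthetic reference bundles, cohorts and VCFs with planted truth.

The generator emulates the study conditions the annotator targets: type I,
type II and multi-pass membrane proteins with curated topology, tyrosine
motifs planted in the juxtamembrane (membrane-proximal) cytoplasmic window,
a back-translated CDS embedded in a toy genome (optionally with an intron),
and a multi-sample cohort VCF realizing planned effect classes — including
the hallmark per-genome burden of homozygous truncating variants (7
frameshift + 5 stop-gain by default) and motif creation / deletion /
retention scenarios.

Truth is geometric: background protein sequence contains no tyrosine and
residues flanking planted motifs are guarded, so the planted inventory *is*
the complete wild-type hit set, and every planned variant's expected motif
changes follow from plant positions and the edit's coordinate arithmetic
alone.  Frameshift candidates are retried until the shifted tail encodes no
tyrosine and the first changed residue falls clear of every plant, keeping
created-motif truth trivially empty.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .consequence import cds_to_genomic
from .reference_store import (
    AnnotationBundle,
    GeneModel,
    GenomeSequence,
    ProteinRecord,
    TopologyFeature,
    reverse_complement,
    translate,
    validate_bundle,
)
from .vcf_io import Variant, Zygosity, normalize_variant

BACKGROUND_AA = sorted(set("ACDEFGHIKLMNPQRSTVW"))  # the 20 standard minus Y

_CODONS_FOR = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS_FOR.setdefault(aa, []).append(codon)
for aa in _CODONS_FOR:
    _CODONS_FOR[aa].sort()

STOPS = sorted(standard_dna_table.stop_codons)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: planted motif templates; all are guard-compatible (no accidental
#: cross-class match given G-G guards and >=25-residue slot spacing)
TEMPLATES = {
    "YXXQ": "YKKQ",
    "YXXQ2": "YNNQ",
    "ITAM": "YKKLGAGAGAYKKL",  # gap 6
    "ITIM": "SAYKKV",
    "PRECURSOR": "SKKQ",  # S->Y single-base change completes a YxxQ
}


class FixtureError(Exception):
    """The requested layout or plan is unrealizable."""


@dataclass(frozen=True)
class PlantedMotif:
    motif_class: str
    start: int
    end: int
    tyrosines: tuple[int, ...]
    membrane_proximal: bool


@dataclass
class GeneFixture:
    """Per-gene construction record used to realize planned variants."""

    model: GeneModel
    protein: ProteinRecord
    topology_class: str
    sense_cds: str  # spliced CDS in transcription orientation (incl. stop)
    codons: list[str]  # sense codons for residues 1..L (stop excluded)
    stop_codon: str
    planted: list[PlantedMotif]
    precursor_pos: int | None  # protein position of the plantable S residue
    jm_intervals: tuple[tuple[int, int], ...]  # geometric proximal window
    protected: set[int] = field(default_factory=set)  # plant + guard positions

    @property
    def length(self) -> int:
        return len(self.protein.sequence)

    def domain_of(self, pos: int) -> str:
        for f in self.protein.topology:
            if f.start <= pos <= f.end:
                return f.kind
        return "unannotated"

    def in_window(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.jm_intervals)


@dataclass
class BundleFixture:
    bundle: AnnotationBundle
    genes: list[GeneFixture]
    chrom: str
    downstream_flank: str


# ---------------------------------------------------------------------------
# Bundle generation
# ---------------------------------------------------------------------------

def _layout(rng, cls: str):
    """Topology features + (anchor, window intervals, L) for one class."""
    if cls == "type1":
        t = int(rng.integers(60, 90))
        L = t + 21 + int(rng.integers(115, 150))
        feats = [
            TopologyFeature("signal_peptide", 1, 20),
            TopologyFeature("extracellular", 21, t - 1),
            TopologyFeature("transmembrane", t, t + 20),
            TopologyFeature("cytoplasmic", t + 21, L),
        ]
        anchor = t + 21
        window = ((anchor, min(anchor + 79, L)),)
    elif cls == "type2":
        c = int(rng.integers(100, 130))
        L = c + 21 + int(rng.integers(30, 60))
        feats = [
            TopologyFeature("cytoplasmic", 1, c),
            TopologyFeature("transmembrane", c + 1, c + 21),
            TopologyFeature("extracellular", c + 22, L),
        ]
        anchor = max(1, c - 79)
        window = ((anchor, c),)
    elif cls == "multipass":
        a = int(rng.integers(15, 30))
        loop = int(rng.integers(95, 120))
        b = a + 21 + loop
        L = b + 21 + int(rng.integers(40, 70))
        feats = [
            TopologyFeature("extracellular", 1, a),
            TopologyFeature("transmembrane", a + 1, a + 21),
            TopologyFeature("cytoplasmic", a + 22, b),
            TopologyFeature("transmembrane", b + 1, b + 21),
            TopologyFeature("extracellular", b + 22, L),
        ]
        anchor = a + 22
        # both TMs abut the loop: first 80 from TM1's C side, last 80 from
        # TM2's N side
        window = tuple(sorted({(anchor, min(anchor + 79, b)), (max(anchor, b - 79), b)}))
    else:
        raise FixtureError(f"unknown topology class {cls!r}")
    return feats, anchor, window, L


def _plant(seq: list[str], template: str, start: int, protected: set[int]) -> None:
    """Write template at 1-based start with G-G guards just before it."""
    for offset, aa in enumerate(template):
        seq[start - 1 + offset] = aa
    for g in (start - 2, start - 1):
        if g >= 1:
            seq[g - 1] = "G"
    protected.update(range(max(1, start - 2), start + len(template)))


def _template_hits(template_key: str, start: int):
    t = TEMPLATES[template_key]
    ys = tuple(start + i for i, aa in enumerate(t) if aa == "Y")
    cls = {"YXXQ": "YXXQ", "YXXQ2": "YXXQ", "ITAM": "ITAM", "ITIM": "ITIM"}[template_key]
    return cls, start, start + len(t) - 1, ys


def make_bundle(
    seed: int,
    n_genes: int = 20,
    classes: tuple[str, ...] = ("type1", "type2", "multipass"),
    intron_prob: float = 0.3,
    chrom: str = "toy1",
    build: str = "toy37",
) -> tuple[AnnotationBundle, BundleFixture]:
    """Generate a validated bundle of ``n_genes`` membrane proteins.

    Every gene plants one YKKQ plus a second motif cycling through
    ITAM / ITIM / a second YxxQ, plus an S-K-K-Q precursor one base away
    from a YxxQ — all inside the juxtamembrane window.  Deterministic under
    ``seed``.
    """
    if n_genes < 1:
        raise FixtureError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    downstream_flank = "GGCAGCTAA" + "".join(rng.choice(list("ACGT"), size=21))
    genome_parts: list[str] = []
    cursor = 0
    genes: list[GeneFixture] = []
    models: dict[str, GeneModel] = {}
    proteins: dict[str, ProteinRecord] = {}
    drug_lookup: dict[str, list[str]] = {}

    for idx in range(n_genes):
        cls = classes[idx % len(classes)]
        feats, anchor, window, L = _layout(rng, cls)
        seq = ["M"] + [str(rng.choice(BACKGROUND_AA)) for _ in range(L - 1)]
        protected: set[int] = set()
        slot_keys = ["YXXQ", ("ITAM", "ITIM", "YXXQ2")[idx % 3], "PRECURSOR"]
        slots = [anchor + 2, anchor + 30, anchor + 58]
        planted: list[PlantedMotif] = []
        precursor_pos = None
        for key, start in zip(slot_keys, slots):
            if start + len(TEMPLATES[key]) - 1 > L:
                raise FixtureError(f"gene {idx}: motif slot beyond protein length")
            _plant(seq, TEMPLATES[key], start, protected)
            if key == "PRECURSOR":
                precursor_pos = start
            else:
                mcls, s, e, ys = _template_hits(key, start)
                proximal = any(ws <= ys[0] <= we for ws, we in window)
                planted.append(PlantedMotif(mcls, s, e, ys, proximal))
        protein_seq = "".join(seq)

        codons = [str(rng.choice(_CODONS_FOR[aa])) for aa in protein_seq]
        if precursor_pos is not None:
            codons[precursor_pos - 1] = "TCT"  # S, one base from TAT (Y)
        for p in planted:
            if p.motif_class == "YXXQ":
                codons[p.start - 1] = "TAT"  # Y, one base from GAT (D)
        stop_codon = "TAA"
        sense_cds = "".join(codons) + stop_codon

        # optional intron exercising multi-exon projection
        if rng.random() < intron_prob:
            cut = int(rng.integers(30, len(sense_cds) - 30))
            intron = "GT" + "".join(rng.choice(list("ACGT"), size=26)) + "AG"
            sense_region = sense_cds[:cut] + intron + sense_cds[cut:]
            sense_exons = [(1, cut), (cut + len(intron) + 1, len(sense_region))]
        else:
            sense_region = sense_cds
            sense_exons = [(1, len(sense_region))]

        strand = "+" if rng.random() < 0.5 else "-"
        pad = "".join(rng.choice(list("ACGT"), size=25))
        if strand == "+":
            region_genomic = sense_region
            prefix = pad
            suffix = downstream_flank
        else:
            region_genomic = reverse_complement(sense_region)
            prefix = pad + reverse_complement(downstream_flank)
            suffix = ""
        region_start = cursor + len(prefix) + 1
        genome_parts.extend([prefix, region_genomic, suffix])
        cursor += len(prefix) + len(region_genomic) + len(suffix)

        R = len(sense_region)
        if strand == "+":
            exons = [(region_start + a - 1, region_start + b - 1) for a, b in sense_exons]
        else:
            exons = sorted(
                (region_start + (R - b), region_start + (R - a)) for a, b in sense_exons
            )
        gene_id, protein_id = f"G{idx:03d}", f"P{idx:03d}"
        model = GeneModel(gene_id, chrom, strand, tuple(exons), protein_id, build)
        record = ProteinRecord(protein_id, protein_seq, tuple(feats))
        models[gene_id] = model
        proteins[protein_id] = record
        if idx % 4 == 0:
            drug_lookup[protein_id] = [f"agent{idx}a", f"agent{idx}b"]
        genes.append(
            GeneFixture(
                model=model,
                protein=record,
                topology_class=cls,
                sense_cds=sense_cds,
                codons=codons,
                stop_codon=stop_codon,
                planted=planted,
                precursor_pos=precursor_pos,
                jm_intervals=window,
                protected=protected,
            )
        )

    bundle = AnnotationBundle(
        genome={chrom: GenomeSequence(chrom, "".join(genome_parts))},
        models=models,
        proteins=proteins,
        drug_lookup=drug_lookup,
    )
    violations = validate_bundle(bundle)
    if violations:
        raise FixtureError("generated bundle failed validation: " + "; ".join(violations))
    return bundle, BundleFixture(bundle, genes, chrom, downstream_flank)


# ---------------------------------------------------------------------------
# Cohort plans and variant realization
# ---------------------------------------------------------------------------

@dataclass
class CohortPlan:
    """Per-cohort counts of planted effects; burden counts are per sample."""

    n_samples: int = 5
    hom_frameshift_per_sample: int = 7
    hom_stop_gain_per_sample: int = 5
    het_missense: int = 3
    synonymous: int = 2
    start_loss: int = 1
    stop_loss: int = 1
    inframe_deletion: int = 1
    inframe_insertion: int = 1
    motif_create: int = 1
    motif_delete: int = 1
    motif_retain_truncation: int = 1

    @classmethod
    def empty(cls, n_samples: int = 2) -> "CohortPlan":
        return cls(n_samples, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0)


@dataclass(frozen=True)
class TruthChange:
    motif_class: str
    status: str
    start: int
    end: int
    membrane_proximal: bool


@dataclass
class TruthRow:
    """Expected annotation for one planted variant (one gene each)."""

    variant: Variant
    gene_id: str
    protein_id: str
    effect_class: str
    hgvs_p: str
    domain: str | None
    motif_changes: tuple[TruthChange, ...]
    genotypes: dict[str, Zygosity]
    rsid: str | None = None

    @property
    def expected_af(self) -> float | None:
        called = sum(2 for z in self.genotypes.values() if z is not Zygosity.MISSING)
        if called == 0:
            return None
        alt = sum(
            2 if z is Zygosity.HOM_ALT else 1 if z is Zygosity.HET else 0
            for z in self.genotypes.values()
        )
        return alt / called

    @property
    def expected_maf(self) -> float | None:
        af = self.expected_af
        return None if af is None else min(af, 1.0 - af)


@dataclass
class TruthTable:
    rows: list[TruthRow]
    samples: list[str]

    def expected_burdens(self) -> dict[str, tuple[int, int]]:
        out = {s: [0, 0] for s in self.samples}
        for row in self.rows:
            slot = {"frameshift": 0, "stop_gain": 1}.get(row.effect_class)
            if slot is None:
                continue
            for sample, z in row.genotypes.items():
                if z is Zygosity.HOM_ALT:
                    out[sample][slot] += 1
        return {s: (a, b) for s, (a, b) in out.items()}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "chrom\tpos\tref\talt\trsid\tgene_id\tprotein_id\tconsequence\t"
                "hgvs_p\tdomain\tmotif_changes\tmembrane_proximal\tmaf\n"
            )
            for r in self.rows:
                changes = ";".join(
                    f"{c.motif_class}:{c.status}:{c.start}-{c.end}"
                    for c in r.motif_changes
                )
                prox = ";".join(
                    "1" if c.membrane_proximal else "0" for c in r.motif_changes
                )
                maf = f"{r.expected_maf:.6g}" if r.expected_maf is not None else "."
                v = r.variant
                fh.write(
                    f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{r.rsid or '.'}\t"
                    f"{r.gene_id}\t{r.protein_id}\t{r.effect_class}\t{r.hgvs_p}\t"
                    f"{r.domain or '.'}\t{changes or '.'}\t{prox or '.'}\t{maf}\n"
                )


def _sorted_changes(changes):
    return tuple(sorted(changes, key=lambda c: (c.start, c.motif_class, c.end, c.status)))


class _Realizer:
    """Turns planned effect classes into concrete variants on a fixture."""

    def __init__(self, fixture: BundleFixture, rng):
        self.fx = fixture
        self.rng = rng
        self.genome = fixture.bundle.genome[fixture.chrom]
        # per-call codon reservations, keeping make_cohort_vcf a pure
        # function of (fixture, seed, plan)
        self._used: dict[str, set[int]] = {}

    # -- genomic plumbing ---------------------------------------------------

    def _genomic_snv(self, g: GeneFixture, cds_pos: int, new_sense_base: str) -> Variant:
        pos = cds_to_genomic(g.model, cds_pos)
        ref = self.genome.seq[pos - 1]
        alt = new_sense_base if g.model.strand == "+" else new_sense_base.translate(_COMPLEMENT)
        return Variant(g.model.chrom, pos, ref, alt)

    def _contiguous(self, g: GeneFixture, cds_positions) -> bool:
        gp = [cds_to_genomic(g.model, p) for p in cds_positions]
        step = 1 if g.model.strand == "+" else -1
        return all(b - a == step for a, b in zip(gp, gp[1:]))

    def _genomic_del(self, g: GeneFixture, del_start_cds: int, n_del: int) -> Variant:
        """Delete sense CDS bases [del_start, del_start+n_del-1], VCF-anchored.

        On '+' the anchor is the sense base before the run; on '-' the
        genomic base preceding the deleted window is the sense base *after*
        the run.  Caller must have checked genomic contiguity over
        [del_start-1, del_start+n_del].
        """
        if g.model.strand == "+":
            pos = cds_to_genomic(g.model, del_start_cds - 1)
        else:
            pos = cds_to_genomic(g.model, del_start_cds + n_del)
        ref = self.genome.seq[pos - 1 : pos + n_del]
        return Variant(g.model.chrom, pos, ref, ref[0])

    def _genomic_ins(self, g: GeneFixture, after_cds: int, sense_insert: str) -> Variant:
        """Insert sense bases between after_cds and after_cds+1."""
        if g.model.strand == "+":
            pos = cds_to_genomic(g.model, after_cds)
            ref = self.genome.seq[pos - 1]
            return Variant(g.model.chrom, pos, ref, ref + sense_insert)
        pos = cds_to_genomic(g.model, after_cds + 1)
        ref = self.genome.seq[pos - 1]
        return Variant(g.model.chrom, pos, ref, ref + reverse_complement(sense_insert))

    # -- shared helpers -----------------------------------------------------

    def _used_codons(self, g: GeneFixture) -> set[int]:
        return self._used.setdefault(g.model.gene_id, set())

    def _free_codons(self, g: GeneFixture, lo: int, hi: int, margin: int = 0):
        used = self._used_codons(g)
        lo, hi = max(2, lo), min(g.length, hi)
        ks = [
            k
            for k in range(lo, hi + 1)
            if not any(k + d in used for d in (-1, 0, 1))
            and (margin == 0 or all(abs(k - p) > margin for p in g.protected))
        ]
        self.rng.shuffle(ks)
        return ks

    def _reserve(self, g: GeneFixture, *codon_idx: int) -> None:
        self._used_codons(g).update(codon_idx)

    def _plant_truth(self, g: GeneFixture):
        """(class, start, end, proximal) for every planted wild-type hit."""
        return [
            TruthChange(p.motif_class, "retained", p.start, p.end, p.membrane_proximal)
            for p in g.planted
        ]

    def _truncation_changes(self, g: GeneFixture, first_lost: int):
        """Plants wholly below ``first_lost`` retained, the rest deleted."""
        return _sorted_changes(
            TruthChange(
                p.motif_class,
                "retained" if p.end < first_lost else "deleted",
                p.start,
                p.end,
                p.membrane_proximal,
            )
            for p in g.planted
        )

    # -- effect realizers ---------------------------------------------------

    def stop_gain(self, g: GeneFixture, lo: int, hi: int):
        for k in self._free_codons(g, lo, hi):
            if k in g.protected:
                continue
            codon = g.codons[k - 1]
            for j, base in itertools.product(range(3), "ACGT"):
                if base == codon[j]:
                    continue
                if codon[:j] + base + codon[j + 1 :] in STOPS:
                    self._reserve(g, k)
                    variant = self._genomic_snv(g, 3 * (k - 1) + j + 1, base)
                    aa = g.protein.sequence[k - 1]
                    return variant, "stop_gain", f"p.{aa}{k}*", g.domain_of(k), \
                        self._truncation_changes(g, k)
            # fallthrough: next candidate codon
        return None

    def frameshift(self, g: GeneFixture, lo: int, hi: int):
        wt = g.protein.sequence
        plant_lo = min(p.start for p in g.planted)
        plant_hi = max(p.end for p in g.planted)
        for k in self._free_codons(g, lo, hi):
            p0 = 3 * (k - 1) + 1  # codon k base 1 (kept anchor)
            if p0 + 3 > len(g.sense_cds) - 3:
                continue
            # deleting sense bases p0+1, p0+2; contiguity incl. both anchors
            if not self._contiguous(g, [p0, p0 + 1, p0 + 2, p0 + 3]):
                continue
            mut_cds = g.sense_cds[:p0] + g.sense_cds[p0 + 2 :]
            mut_prot, terminated = translate(mut_cds)
            if not terminated:
                continue
            f = next(
                (i + 1 for i, (a, b) in enumerate(zip(wt, mut_prot)) if a != b),
                min(len(wt), len(mut_prot)) + 1,
            )
            if f > len(wt):
                continue
            if "Y" in mut_prot[f - 1 :]:
                continue
            upstream_ok = f <= plant_lo - 3
            downstream_ok = f >= plant_hi + 5
            if not (upstream_ok or downstream_ok):
                continue
            self._reserve(g, k)
            variant = self._genomic_del(g, p0 + 1, 2)
            return variant, "frameshift", f"p.{wt[f - 1]}{f}fs", g.domain_of(f), \
                self._truncation_changes(g, f)
        return None

    def missense(self, g: GeneFixture, forbid_aa=frozenset("Y*")):
        wt = g.protein.sequence
        for k in self._free_codons(g, 2, g.length, margin=4):
            codon = g.codons[k - 1]
            for j, base in itertools.product(range(3), "ACGT"):
                if base == codon[j]:
                    continue
                new = codon[:j] + base + codon[j + 1 :]
                aa = standard_dna_table.forward_table.get(new)
                if aa is None or aa == wt[k - 1] or aa in forbid_aa:
                    continue
                self._reserve(g, k)
                variant = self._genomic_snv(g, 3 * (k - 1) + j + 1, base)
                return variant, "missense", f"p.{wt[k - 1]}{k}{aa}", g.domain_of(k), \
                    _sorted_changes(self._plant_truth(g))
        return None

    def synonymous(self, g: GeneFixture):
        for k in self._free_codons(g, 2, g.length, margin=4):
            codon = g.codons[k - 1]
            for base in "ACGT":
                if base == codon[2]:
                    continue
                new = codon[:2] + base
                if standard_dna_table.forward_table.get(new) != g.protein.sequence[k - 1]:
                    continue
                self._reserve(g, k)
                variant = self._genomic_snv(g, 3 * k, base)
                aa = g.protein.sequence[k - 1]
                return variant, "synonymous", f"p.{aa}{k}=", g.domain_of(k), ()
        return None

    def start_loss(self, g: GeneFixture):
        if 1 in self._used_codons(g):
            return None
        self._reserve(g, 1)
        variant = self._genomic_snv(g, 2, "C")  # ATG -> ACG
        changes = _sorted_changes(
            TruthChange(p.motif_class, "deleted", p.start, p.end, p.membrane_proximal)
            for p in g.planted
        )
        return variant, "start_loss", "p.M1?", g.domain_of(1), changes

    def stop_loss(self, g: GeneFixture):
        stop_cds1 = 3 * g.length + 1
        key = g.length + 1
        if key in self._used_codons(g):
            return None
        self._reserve(g, key)
        variant = self._genomic_snv(g, stop_cds1, "C")  # TAA -> CAA (Q)
        return variant, "stop_loss", f"p.*{g.length + 1}ext", None, \
            _sorted_changes(self._plant_truth(g))

    def inframe_deletion(self, g: GeneFixture):
        wt = g.protein.sequence
        for k in self._free_codons(g, 3, g.length - 1, margin=20):
            if wt[k - 1] == wt[k]:
                continue  # repeat would move the first changed residue
            start = 3 * (k - 1) + 1  # codon k base 1
            if not self._contiguous(g, list(range(start - 1, start + 4))):
                continue
            self._reserve(g, k - 1, k, k + 1)
            variant = self._genomic_del(g, start, 3)
            changes = _sorted_changes(
                TruthChange(p.motif_class, "retained", p.start, p.end, p.membrane_proximal)
                for p in g.planted
            )
            return variant, "inframe_deletion", f"p.{wt[k - 1]}{k}del", g.domain_of(k), changes
        return None

    def inframe_insertion(self, g: GeneFixture):
        wt = g.protein.sequence
        for k in self._free_codons(g, 3, g.length - 2, margin=20):
            if wt[k] == "W" or wt[k - 1] == "W":
                continue
            after = 3 * k
            if not self._contiguous(g, [after, after + 1]):
                continue
            self._reserve(g, k, k + 1)
            variant = self._genomic_ins(g, after, "TGG")  # inserts W
            changes = _sorted_changes(self._plant_truth(g))
            return variant, "inframe_insertion", f"p.{wt[k]}{k + 1}insW", \
                g.domain_of(k + 1), changes
        return None

    def motif_create(self, g: GeneFixture):
        p = g.precursor_pos
        if p is None or p in self._used_codons(g):
            return None
        self._reserve(g, p)
        variant = self._genomic_snv(g, 3 * (p - 1) + 2, "A")  # TCT -> TAT (S->Y)
        created = TruthChange("YXXQ", "created", p, p + 3, g.in_window(p))
        changes = _sorted_changes([*self._plant_truth(g), created])
        return variant, "missense", f"p.S{p}Y", g.domain_of(p), changes

    def motif_delete(self, g: GeneFixture):
        target = next((p for p in g.planted if p.motif_class == "YXXQ"), None)
        if target is None or target.start in self._used_codons(g):
            return None
        q = target.start
        self._reserve(g, q)
        variant = self._genomic_snv(g, 3 * (q - 1) + 1, "G")  # TAT -> GAT (Y->D)
        changes = []
        for p in g.planted:
            status = "deleted" if p is target else "retained"
            changes.append(
                TruthChange(p.motif_class, status, p.start, p.end, p.membrane_proximal)
            )
        return variant, "missense", f"p.Y{q}D", g.domain_of(q), _sorted_changes(changes)

    def motif_retain_truncation(self, g: GeneFixture):
        """FLT3-style: truncate the cytoplasmic tail past every planted motif."""
        plant_hi = max(p.end for p in g.planted)
        return self.stop_gain(g, plant_hi + 3, g.length - 3)


def _zygosities(rng, samples, mode: str) -> dict[str, Zygosity]:
    if mode == "hom_all":
        return {s: Zygosity.HOM_ALT for s in samples}
    out = {}
    for s in samples:
        r = rng.random()
        if mode == "no_hom":  # truncating scenario variants stay het/ref
            out[s] = Zygosity.HET if r < 0.6 else Zygosity.HOM_REF
        else:
            if r < 0.35:
                out[s] = Zygosity.HET
            elif r < 0.50:
                out[s] = Zygosity.HOM_ALT
            elif r < 0.60:
                out[s] = Zygosity.MISSING
            else:
                out[s] = Zygosity.HOM_REF
    return out


_GT = {
    Zygosity.HOM_REF: "0/0",
    Zygosity.HET: "0/1",
    Zygosity.HOM_ALT: "1/1",
    Zygosity.MISSING: "./.",
}


def write_vcf_text(rows: list[TruthRow], samples: list[str], chrom_lengths: dict[str, int]) -> str:
    lines = ["##fileformat=VCFv4.2"]
    for chrom, length in chrom_lengths.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    lines.append("\t".join(header + samples))
    for row in sorted(rows, key=lambda r: (r.variant.chrom, r.variant.pos, r.variant.alt)):
        v = row.variant
        gts = "\t".join(_GT[row.genotypes[s]] for s in samples)
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}"
        )
    return "\n".join(lines) + "\n"


def make_cohort_vcf(
    fixture: BundleFixture,
    seed: int,
    plan: CohortPlan | None = None,
) -> tuple[str, TruthTable]:
    """Synthesize a multi-sample cohort VCF realizing the plan, plus truth.

    Returns the VCF text and the machine-readable truth table.  Roughly
    half the planted variants get an rsID entry, exposed via
    ``TruthTable`` rows and meant to be merged into the bundle's rsid
    lookup.  Deterministic under ``seed``.
    """
    plan = plan or CohortPlan()
    rng = np.random.default_rng(seed + 104729)
    samples = [f"S{i + 1:03d}" for i in range(plan.n_samples)]
    realizer = _Realizer(fixture, rng)
    genes = fixture.genes
    gene_cycle = itertools.cycle(range(len(genes)))

    tasks: list[tuple[str, str]] = []  # (realizer name, zygosity mode)
    tasks += [("frameshift_burden", "hom_all")] * plan.hom_frameshift_per_sample
    tasks += [("stop_gain_burden", "hom_all")] * plan.hom_stop_gain_per_sample
    tasks += [("missense", "random")] * plan.het_missense
    tasks += [("synonymous", "random")] * plan.synonymous
    tasks += [("start_loss", "no_hom")] * plan.start_loss
    tasks += [("stop_loss", "random")] * plan.stop_loss
    tasks += [("inframe_deletion", "random")] * plan.inframe_deletion
    tasks += [("inframe_insertion", "random")] * plan.inframe_insertion
    tasks += [("motif_create", "random")] * plan.motif_create
    tasks += [("motif_delete", "random")] * plan.motif_delete
    tasks += [("motif_retain_truncation", "no_hom")] * plan.motif_retain_truncation

    rows: list[TruthRow] = []
    rs_counter = itertools.count(900001)
    for task, zyg_mode in tasks:
        realized = None
        for _attempt in range(len(genes)):
            g = genes[next(gene_cycle)]
            if task == "frameshift_burden":
                plant_hi = max(p.end for p in g.planted)
                realized = realizer.frameshift(g, plant_hi + 6, g.length - 12)
            elif task == "stop_gain_burden":
                plant_hi = max(p.end for p in g.planted)
                realized = realizer.stop_gain(g, plant_hi + 3, g.length - 3)
            elif task == "motif_retain_truncation":
                if len([p for p in g.planted if p.motif_class == "YXXQ"]) >= 2:
                    realized = realizer.motif_retain_truncation(g)
            else:
                realized = getattr(realizer, task)(g)
            if realized is not None:
                break
        if realized is None:
            raise FixtureError(f"plan unrealizable: could not place a {task} variant")
        variant, effect, hgvs, domain, changes = realized
        variant = normalize_variant(variant)
        rows.append(
            TruthRow(
                variant=variant,
                gene_id=g.model.gene_id,
                protein_id=g.model.protein_id,
                effect_class=effect,
                hgvs_p=hgvs,
                domain=domain,
                motif_changes=changes,
                genotypes=_zygosities(rng, samples, zyg_mode),
                rsid=f"rs{next(rs_counter)}" if rng.random() < 0.5 else None,
            )
        )

    chrom_lengths = {c: len(s) for c, s in fixture.bundle.genome.items()}
    vcf_text = write_vcf_text(rows, samples, chrom_lengths)
    return vcf_text, TruthTable(rows, samples)


def rsid_lookup_from_truth(truth: TruthTable) -> dict[tuple[str, int, str, str], str]:
    return {r.variant.key: r.rsid for r in truth.rows if r.rsid}
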