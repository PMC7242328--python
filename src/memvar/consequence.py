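"""Project a variant into a gene model's CDS, re-translate, classify.

This is the core mapping path: genomic position -> spliced CDS offset ->
edited CDS -> mutant full-length protein -> effect class derived from the
difference between wild-type and mutant translations.  Edits are applied on
the forward-spliced exon concatenation, so '-' strand correction (including
reverse-complementing the alt allele) falls out of a single final
reverse-complement.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from functools import lru_cache

from .reference_store import (
    START_CODON,
    AnnotationBundle,
    GeneModel,
    GenomeSequence,
    reverse_complement,
    translate,
)
from .vcf_io import Variant, edit_span


class ReferenceMismatchError(Exception):
    """The VCF ref allele disagrees with the bundle genome at that locus."""


class MalformedCdsError(Exception):
    """Mutant CDS translated to nothing despite an intact start codon."""


class EffectClass(str, enum.Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    START_LOSS = "start_loss"
    FRAMESHIFT = "frameshift"
    INFRAME_INSERTION = "inframe_insertion"
    INFRAME_DELETION = "inframe_deletion"
    NON_CODING = "non_coding"

    def __str__(self) -> str:
        return self.value


#: severity order used by --collapse (most severe first)
SEVERITY_ORDER = [
    EffectClass.START_LOSS,
    EffectClass.FRAMESHIFT,
    EffectClass.STOP_GAIN,
    EffectClass.STOP_LOSS,
    EffectClass.MISSENSE,
    EffectClass.INFRAME_INSERTION,
    EffectClass.INFRAME_DELETION,
    EffectClass.SYNONYMOUS,
    EffectClass.NON_CODING,
]

TRUNCATING = {EffectClass.STOP_GAIN, EffectClass.FRAMESHIFT, EffectClass.START_LOSS}


@dataclass(frozen=True)
class CodingEffect:
    """Wild-type -> mutant protein delta for one (variant, gene model) pair."""

    gene_id: str
    protein_id: str
    effect_class: EffectClass
    protein_pos: int | None
    ref_aa: str
    alt_aa: str
    mutant_protein: str
    net_protein_shift: int
    truncation_pos: int | None = None
    partial_exonic: bool = False
    terminated: bool = True

    @property
    def alters_protein(self) -> bool:
        return self.effect_class not in (EffectClass.SYNONYMOUS, EffectClass.NON_CODING)


# ---------------------------------------------------------------------------
# Coordinate projection
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4096)
def _exon_offsets(cds_exons: tuple[tuple[int, int], ...]) -> tuple[tuple[int, int, int], ...]:
    """Per exon: (start, end, cumulative length before this exon)."""
    out, cum = [], 0
    for s, e in cds_exons:
        out.append((s, e, cum))
        cum += e - s + 1
    return tuple(out)


def genomic_to_cds(model: GeneModel, pos: int) -> int | None:
    """1-based offset into the spliced strand-corrected CDS, or None.

    On the '-' strand the mapping reverses orientation: the highest exonic
    genomic position of the gene is CDS position 1.
    """
    for s, e, cum in _exon_offsets(model.cds_exons):
        if s <= pos <= e:
            forward = cum + (pos - s + 1)
            if model.strand == "+":
                return forward
            return model.cds_length - forward + 1
    return None


def cds_to_genomic(model: GeneModel, cds_pos: int) -> int:
    """Inverse of :func:`genomic_to_cds`; raises for out-of-range offsets."""
    if not 1 <= cds_pos <= model.cds_length:
        raise ValueError(f"CDS position {cds_pos} outside 1-{model.cds_length}")
    forward = cds_pos if model.strand == "+" else model.cds_length - cds_pos + 1
    for s, e, cum in _exon_offsets(model.cds_exons):
        if cum < forward <= cum + (e - s + 1):
            return s + (forward - cum) - 1
    raise AssertionError("unreachable")


def _in_exon(model: GeneModel, pos: int) -> bool:
    return any(s <= pos <= e for s, e in model.cds_exons)


# ---------------------------------------------------------------------------
# CDS surgery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AppliedEdit:
    """Result of projecting a variant's edit onto a spliced CDS."""

    mutant_cds: str
    partial_exonic: bool
    cds_edit_pos: int | None  # CDS offset of the first affected base


def apply_variant_to_cds(
    cds: str,
    model: GeneModel,
    variant: Variant,
    genome: dict[str, GenomeSequence] | AnnotationBundle,
) -> AppliedEdit | None:
    """Replace the edited reference bases by the alt allele inside the exons.

    Returns None when the edit span is wholly intronic/intergenic.  Edits
    straddling an exon boundary apply only their intra-exonic part and set
    ``partial_exonic``.  A ref-allele disagreement with the bundle genome
    raises :class:`ReferenceMismatchError` (silent mis-anchoring would
    corrupt every downstream motif call).
    """
    chroms = genome.genome if isinstance(genome, AnnotationBundle) else genome
    chrom = chroms[variant.chrom] if variant.chrom in chroms else None
    if chrom is None or model.chrom != variant.chrom:
        return None
    observed = chrom.slice(variant.pos, variant.pos + len(variant.ref) - 1)
    if observed != variant.ref:
        raise ReferenceMismatchError(
            f"{variant.chrom}:{variant.pos} ref {variant.ref!r} != genome {observed!r}"
        )

    span = edit_span(variant)
    forward = "".join(chrom.slice(s, e) for s, e in model.cds_exons)
    offsets = _exon_offsets(model.cds_exons)

    def fwd_index(pos: int) -> int | None:
        for s, e, cum in offsets:
            if s <= pos <= e:
                return cum + (pos - s)
        return None

    if span.is_insertion:
        # inserted between span.start-1 and span.start: intra-exonic only if
        # both flanking bases sit in the (same) exon
        left, right = fwd_index(span.start - 1), fwd_index(span.start)
        if left is None or right is None or right != left + 1:
            return None
        mutant_forward = forward[:right] + span.alt + forward[right:]
        first_affected = right  # 0-based forward index of first inserted base
        partial = False
    else:
        exonic = [p for p in span.positions if _in_exon(model, p)]
        if not exonic:
            return None
        partial = len(exonic) < len(span.ref)
        idx = sorted(fwd_index(p) for p in exonic)
        # exonic positions are contiguous in spliced coordinates
        alt_part = span.alt if (not partial or _in_exon(model, span.start)) else ""
        mutant_forward = forward[: idx[0]] + alt_part + forward[idx[-1] + 1 :]
        first_affected = idx[0]
        partial = partial or len(exonic) < (span.end - span.start + 1)

    if model.strand == "-":
        mutant_cds = reverse_complement(mutant_forward)
        cds_edit_pos = model.cds_length - first_affected  # 1-based from the other end
    else:
        mutant_cds = mutant_forward
        cds_edit_pos = first_affected + 1
    cds_edit_pos = max(1, min(cds_edit_pos, model.cds_length))
    return AppliedEdit(mutant_cds, partial, cds_edit_pos)


# ---------------------------------------------------------------------------
# Effect classification
# ---------------------------------------------------------------------------

def _first_difference(a: str, b: str) -> int:
    """1-based index of the first differing residue (min length + 1 on prefix)."""
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            return i + 1
    return min(len(a), len(b)) + 1


def _common_suffix_len(a: str, b: str, keep_prefix: int) -> int:
    """Longest common suffix not reaching into the first ``keep_prefix`` chars."""
    s = 0
    while (
        s < len(a) - keep_prefix
        and s < len(b) - keep_prefix
        and a[len(a) - 1 - s] == b[len(b) - 1 - s]
    ):
        s += 1
    return s


def classify_effect(
    wt_protein: str,
    wt_cds: str,
    mutant_cds: str,
    *,
    gene_id: str = "",
    protein_id: str = "",
    three_prime_context: str = "",
    partial_exonic: bool = False,
    cds_edit_pos: int | None = None,
) -> CodingEffect:
    """Translate the mutant CDS and classify the protein-level effect.

    Precedence: start-codon loss, then frameshift (a premature stop arising
    from a shifted frame is a consequence of the shift, so frameshift wins),
    then stop gain / stop loss, then synonymous / missense / inframe indels.
    ``three_prime_context`` is downstream transcript sequence appended before
    translation so that stop-loss read-through can find the next in-frame
    stop.
    """
    net_cds = len(mutant_cds) - len(wt_cds)
    n_wt = len(wt_protein)

    def make(effect_class, protein_pos, ref_aa, alt_aa, mutant_protein,
             truncation_pos=None, terminated=True):
        return CodingEffect(
            gene_id=gene_id,
            protein_id=protein_id,
            effect_class=effect_class,
            protein_pos=protein_pos,
            ref_aa=ref_aa,
            alt_aa=alt_aa,
            mutant_protein=mutant_protein,
            net_protein_shift=len(mutant_protein) - n_wt,
            truncation_pos=truncation_pos,
            partial_exonic=partial_exonic,
            terminated=terminated,
        )

    if mutant_cds[:3] != START_CODON:
        # initiator codon destroyed; no product is modelled (no re-initiation)
        return make(EffectClass.START_LOSS, 1, wt_protein[:1], "", "", truncation_pos=1)

    mut_protein, terminated = translate(mutant_cds)
    if not terminated and three_prime_context:
        extra = len(mutant_cds) % 3
        readthrough = mutant_cds + three_prime_context
        mut_protein, terminated = translate(readthrough[: len(readthrough) - (len(readthrough) % 3)])
        del extra
    if not mut_protein and not terminated:
        raise MalformedCdsError(f"{gene_id}: empty mutant translation with intact start")

    n_mut = len(mut_protein)
    f = _first_difference(wt_protein, mut_protein)

    if net_cds % 3 != 0:
        return make(
            EffectClass.FRAMESHIFT,
            f,
            wt_protein[f - 1 : f],
            mut_protein[f - 1 : f],
            mut_protein,
            truncation_pos=f,
            terminated=terminated,
        )
    if mut_protein == wt_protein:
        pp = (cds_edit_pos - 1) // 3 + 1 if cds_edit_pos else None
        aa = wt_protein[pp - 1] if pp and pp <= n_wt else ""
        return make(EffectClass.SYNONYMOUS, pp, aa, aa, mut_protein)
    if not terminated:
        return make(
            EffectClass.STOP_LOSS, f, "*", mut_protein[f - 1 : f], mut_protein,
            terminated=False,
        )

    expected_len = n_wt + net_cds // 3
    if n_mut < expected_len:
        # premature in-frame stop: truncation dominates
        return make(
            EffectClass.STOP_GAIN,
            f,
            wt_protein[f - 1 : f],
            "*",
            mut_protein,
            truncation_pos=n_mut + 1,
        )
    if n_mut == n_wt:
        last = n_wt - _common_suffix_len(wt_protein, mut_protein, f)
        return make(
            EffectClass.MISSENSE,
            f,
            wt_protein[f - 1 : last],
            mut_protein[f - 1 : last],
            mut_protein,
        )
    if n_mut > n_wt and net_cds == 0:
        # substitution removed the wild-type stop codon
        return make(
            EffectClass.STOP_LOSS, f, "*", mut_protein[f - 1 : f], mut_protein
        )
    s = _common_suffix_len(wt_protein, mut_protein, f - 1)
    ref_aa = wt_protein[f - 1 : n_wt - s]
    alt_aa = mut_protein[f - 1 : n_mut - s]
    cls = EffectClass.INFRAME_INSERTION if n_mut > n_wt else EffectClass.INFRAME_DELETION
    return make(cls, f, ref_aa, alt_aa, mut_protein)


def hgvs_p(effect: CodingEffect, wt_protein: str) -> str:
    """Simplified protein-level HGVS string for an effect."""
    cls, pos = effect.effect_class, effect.protein_pos
    if cls is EffectClass.NON_CODING:
        raise ValueError("non-coding effects have no protein HGVS")
    if cls is EffectClass.START_LOSS:
        return "p.M1?"
    if cls is EffectClass.SYNONYMOUS:
        return f"p.{effect.ref_aa}{pos}=" if pos else "p.="
    ref = wt_protein[pos - 1] if pos and pos <= len(wt_protein) else effect.ref_aa[:1]
    if cls is EffectClass.MISSENSE:
        return f"p.{effect.ref_aa}{pos}{effect.alt_aa}"
    if cls is EffectClass.STOP_GAIN:
        return f"p.{ref}{pos}*"
    if cls is EffectClass.FRAMESHIFT:
        return f"p.{ref}{pos}fs"
    if cls is EffectClass.STOP_LOSS:
        return f"p.*{pos}ext"
    if cls is EffectClass.INFRAME_DELETION:
        return f"p.{effect.ref_aa}{pos}del"
    if cls is EffectClass.INFRAME_INSERTION:
        return f"p.{ref}{pos}ins{effect.alt_aa}"
    raise AssertionError(cls)


# ---------------------------------------------------------------------------
# Wild-type -> mutant coordinate map
# ---------------------------------------------------------------------------

class CoordinateMap:
    """Maps wild-type protein positions to mutant positions (or None).

    Identity below the first changed residue; inframe edits shift positions
    past the edit by the net length change; all positions at or beyond a
    truncation (and everything downstream of a frameshift's first changed
    residue) map to None.
    """

    def __init__(self, effect: CodingEffect, wt_len: int):
        self.effect = effect
        self.wt_len = wt_len

    def __call__(self, pos: int) -> int | None:
        if not 1 <= pos <= self.wt_len:
            return None
        e = self.effect
        cls = e.effect_class
        if cls in (EffectClass.NON_CODING, EffectClass.SYNONYMOUS,
                   EffectClass.MISSENSE, EffectClass.STOP_LOSS):
            return pos
        if cls is EffectClass.START_LOSS:
            return None
        if cls is EffectClass.STOP_GAIN:
            return pos if pos < e.truncation_pos else None
        if cls is EffectClass.FRAMESHIFT:
            return pos if pos < e.truncation_pos else None
        # inframe indel
        first = e.protein_pos
        replaced = len(e.ref_aa)
        if pos < first:
            return pos
        if pos <= first + replaced - 1:
            return None
        return pos + e.net_protein_shift

    def map_span(self, start: int, end: int) -> tuple[int, int] | None:
        """Mapped (start, end) if every position in the span maps; else None."""
        mapped = [self(p) for p in range(start, end + 1)]
        if any(m is None for m in mapped):
            return None
        return mapped[0], mapped[-1]


def coordinate_map(effect: CodingEffect, wt_len: int) -> CoordinateMap:
    return CoordinateMap(effect, wt_len)
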