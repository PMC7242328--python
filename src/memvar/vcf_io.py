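"""VCF parsing into normalized variants and genotype calls; TSV report writing.

Multi-allelic records are split into one :class:`Variant` per ALT allele, and
per-sample genotypes are re-expressed against each split allele.  Indels stay
VCF-anchored (leading shared base kept) but every variant exposes a computed
*edit span* — the first..last replaced reference base after trimming shared
prefix/suffix — plus the net length change, which is what downstream CDS
surgery operates on.
"""

from __future__ import annotations

import enum
import logging
import os
import tempfile
from dataclasses import dataclass, replace

from cyvcf2 import VCF

from .reference_store import VALID_DNA

log = logging.getLogger("memvar.vcf")


class VcfFormatError(Exception):
    """The input is not parseable VCF 4.x (e.g. missing #CHROM header)."""


class NullVariantError(ValueError):
    """ref == alt after normalization: not a variant."""


class Zygosity(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.value


@dataclass(frozen=True)
class Variant:
    """One normalized ALT allele anchored at ``pos`` (1-based)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    source_id: str | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def net_change(self) -> int:
        return len(self.alt) - len(self.ref)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class EditSpan:
    """Fully trimmed view of a variant: the replaced reference bases.

    ``start..end`` covers the reference bases actually replaced; for a pure
    insertion the span is empty (``end == start - 1``) and the inserted bases
    go between ``start - 1`` and ``start``.
    """

    start: int
    end: int
    ref: str
    alt: str

    @property
    def is_insertion(self) -> bool:
        return not self.ref

    @property
    def positions(self) -> range:
        return range(self.start, self.end + 1)


def normalize_variant(v: Variant) -> Variant:
    """Trim shared suffix then shared prefix, keeping >=1 base per allele.

    ``pos`` advances by the prefix trim.  Idempotent.  Raises
    :class:`NullVariantError` when ref == alt.
    """
    if v.ref == v.alt:
        raise NullVariantError(f"{v.chrom}:{v.pos} {v.ref}>{v.alt} is not a variant")
    ref, alt, pos = v.ref, v.alt, v.pos
    while min(len(ref), len(alt)) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while min(len(ref), len(alt)) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:
        raise NullVariantError(f"{v.chrom}:{v.pos} {v.ref}>{v.alt} trims to nothing")
    return replace(v, pos=pos, ref=ref, alt=alt)


def edit_span(v: Variant) -> EditSpan:
    """Maximally trimmed edit span (empty alleles allowed, unlike normalize)."""
    ref, alt, pos = v.ref, v.alt, v.pos
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if not ref and not alt:
        raise NullVariantError(f"{v.chrom}:{v.pos} {v.ref}>{v.alt} is not a variant")
    return EditSpan(start=pos, end=pos + len(ref) - 1, ref=ref, alt=alt)


@dataclass(frozen=True)
class GenotypeCall:
    sample: str
    variant: Variant
    zygosity: Zygosity


def _allele_ok(allele: str) -> bool:
    return bool(allele) and set(allele) <= VALID_DNA


def _is_symbolic(allele: str) -> bool:
    return allele.startswith("<") or "[" in allele or "]" in allele or allele in {"*", "."}


def _zygosity_for_allele(gt_alleles: list[int], alt_index: int) -> Zygosity:
    """Zygosity of one split allele; other alt indices count as ref here."""
    if any(a is None or a < 0 for a in gt_alleles) or not gt_alleles:
        return Zygosity.MISSING
    n = sum(1 for a in gt_alleles if a == alt_index)
    if n == len(gt_alleles):
        return Zygosity.HOM_ALT
    return Zygosity.HET if n > 0 else Zygosity.HOM_REF


def read_vcf(source) -> tuple[list[Variant], list[GenotypeCall], list[str]]:
    """Parse VCF 4.x (plain or gzip path, or a file-like object).

    Returns one Variant per ALT allele in record order, genotype calls
    re-expressed per split allele, and the sample names.  Records carrying
    symbolic or non-ACGTN alleles are skipped with a logged warning.
    """
    tmp_path = None
    if hasattr(source, "read"):
        data = source.read()
        if isinstance(data, str):
            data = data.encode()
        fd, tmp_path = tempfile.mkstemp(suffix=".vcf")
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        path = tmp_path
    else:
        path = str(source)
    try:
        try:
            vcf = VCF(path)
        except Exception as exc:  # htslib raises bare Exceptions on bad headers
            raise VcfFormatError(f"not parseable as VCF 4.x: {exc}") from exc
        samples = list(vcf.samples)
        variants: list[Variant] = []
        calls: list[GenotypeCall] = []
        for rec in vcf:
            if not _allele_ok(rec.REF):
                log.warning("skipping %s:%s: non-ACGTN REF %r", rec.CHROM, rec.POS, rec.REF)
                continue
            gts = rec.genotypes if samples else []
            for alt_index, alt in enumerate(rec.ALT, start=1):
                if _is_symbolic(alt):
                    log.warning(
                        "skipping %s:%s allele %r: symbolic alleles unsupported",
                        rec.CHROM, rec.POS, alt,
                    )
                    continue
                if not _allele_ok(alt):
                    log.warning(
                        "skipping %s:%s allele %r: non-ACGTN", rec.CHROM, rec.POS, alt
                    )
                    continue
                try:
                    variant = normalize_variant(
                        Variant(rec.CHROM, rec.POS, rec.REF, alt, rec.ID or None)
                    )
                except NullVariantError:
                    log.warning("skipping %s:%s %s>%s: null variant",
                                rec.CHROM, rec.POS, rec.REF, alt)
                    continue
                variants.append(variant)
                for sample, gt in zip(samples, gts):
                    alleles = [a for a in gt[:-1]]  # last element is phasing flag
                    calls.append(
                        GenotypeCall(sample, variant, _zygosity_for_allele(alleles, alt_index))
                    )
        return variants, calls, samples
    finally:
        if tmp_path is not None:
            os.unlink(tmp_path)


# ---------------------------------------------------------------------------
# Annotated TSV output
# ---------------------------------------------------------------------------

OUTPUT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "rsid", "gene_id", "protein_id", "build",
    "consequence", "hgvs_p", "domain", "motif_changes", "membrane_proximal",
    "drugs", "maf",
]


def write_annotations(records, dest) -> None:
    """Write annotation records as TSV: header + one row each, input order.

    ``records`` must expose ``as_row()`` returning the OUTPUT_COLUMNS values.
    ``dest`` may be a path or a text stream.
    """
    own = not hasattr(dest, "write")
    fh = open(dest, "w") if own else dest
    try:
        fh.write("\t".join(OUTPUT_COLUMNS) + "\n")
        for rec in records:
            row = rec.as_row()
            if len(row) != len(OUTPUT_COLUMNS):
                raise ValueError(f"record row has {len(row)} columns, expected {len(OUTPUT_COLUMNS)}")
            fh.write("\t".join(row) + "\n")
    finally:
        if own:
            fh.close()
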