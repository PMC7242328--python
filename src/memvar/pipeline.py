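"""End-to-end annotation pipeline: bundle + VCF -> annotated TSV report.

For every variant, each gene model whose locus overlaps the variant's edit
span is annotated independently: project into the CDS, apply the edit,
re-translate, classify, scan wild-type and mutant proteins for
phosphotyrosine motifs, and diff the two hit inventories through the
effect's coordinate map.  rsID and drug-agent lookups are exact-key joins.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace

from intervaltree import IntervalTree

from . import cohort as cohort_mod
from .consequence import (
    CodingEffect,
    EffectClass,
    SEVERITY_ORDER,
    apply_variant_to_cds,
    classify_effect,
    coordinate_map,
    hgvs_p,
)
from .motifs import (
    DEFAULT_PATTERNS,
    DELETED,
    MotifChange,
    MotifPattern,
    scan_motifs,
)
from .reference_store import (
    AnnotationBundle,
    cds_sequence,
    load_bundle,
    mutated_protein_record,
    reverse_complement,
)
from .topology import carry_topology, domain_at, proximal_window
from .vcf_io import Variant, edit_span, read_vcf, write_annotations

log = logging.getLogger("memvar.pipeline")

MISSING = "."


@dataclass
class PipelineOptions:
    proximal_width: int = 80
    proximal_only: bool = False
    bitopic_only: bool = False
    collapse: bool = False
    motif_patterns: tuple[MotifPattern, ...] = DEFAULT_PATTERNS


@dataclass
class AnnotationRecord:
    """One output row: a variant allele annotated against one gene model."""

    variant: Variant
    gene_id: str | None = None
    protein_id: str | None = None
    build: str | None = None
    effect_class: EffectClass = EffectClass.NON_CODING
    hgvs_p: str | None = None
    domain: str | None = None
    motif_changes: list[MotifChange] = field(default_factory=list)
    rsid: str | None = None
    drugs: list[str] = field(default_factory=list)
    maf: float | None = None
    effect: CodingEffect | None = None

    def as_row(self) -> list[str]:
        v = self.variant
        changes = ";".join(
            f"{c.motif_class}:{c.status}:{c.hit.start}-{c.hit.end}"
            for c in self.motif_changes
        )
        proximal = ";".join(
            "1" if c.membrane_proximal else "0" for c in self.motif_changes
        )
        return [
            v.chrom,
            str(v.pos),
            v.ref,
            v.alt,
            self.rsid or MISSING,
            self.gene_id or MISSING,
            self.protein_id or MISSING,
            self.build or MISSING,
            str(self.effect_class),
            self.hgvs_p or MISSING,
            self.domain or MISSING,
            changes or MISSING,
            proximal or MISSING,
            ",".join(self.drugs) or MISSING,
            f"{self.maf:.6g}" if self.maf is not None else MISSING,
        ]


class Annotator:
    """Caches gene lookup trees, wild-type CDSs and motif inventories."""

    def __init__(self, bundle: AnnotationBundle, options: PipelineOptions | None = None):
        self.bundle = bundle
        self.options = options or PipelineOptions()
        self._trees: dict[str, IntervalTree] = {}
        for model in bundle.models.values():
            start, end = model.span
            self._trees.setdefault(model.chrom, IntervalTree()).addi(
                start, end + 1, model.gene_id
            )
        self._wt_cds: dict[str, str] = {}
        self._wt_hits: dict[str, list] = {}
        self._windows: dict[str, object] = {}

    # -- caches -------------------------------------------------------------

    def wt_cds(self, gene_id: str) -> str:
        if gene_id not in self._wt_cds:
            self._wt_cds[gene_id] = cds_sequence(self.bundle.models[gene_id], self.bundle)
        return self._wt_cds[gene_id]

    def wt_window(self, protein_id: str):
        if protein_id not in self._windows:
            self._windows[protein_id] = proximal_window(
                self.bundle.proteins[protein_id], self.options.proximal_width
            )
        return self._windows[protein_id]

    def wt_hits(self, protein_id: str) -> list:
        if protein_id not in self._wt_hits:
            record = self.bundle.proteins[protein_id]
            self._wt_hits[protein_id] = scan_motifs(
                record.sequence,
                self.options.motif_patterns,
                window=self.wt_window(protein_id),
            )
        return self._wt_hits[protein_id]

    # -- core ---------------------------------------------------------------

    def overlapping_models(self, variant: Variant):
        tree = self._trees.get(variant.chrom)
        if tree is None:
            return []
        span = edit_span(variant)
        start = span.start - 1 if span.is_insertion else span.start
        hits = tree.overlap(start, span.end + 1)
        return [self.bundle.models[iv.data] for iv in sorted(hits, key=lambda i: i.data)]

    def three_prime_context(self, model, n: int = 90) -> str:
        """Transcript-direction genomic sequence just past the CDS end."""
        chrom = self.bundle.genome[model.chrom]
        start, end = model.span
        if model.strand == "+":
            lo, hi = end + 1, min(end + n, len(chrom))
            return chrom.slice(lo, hi) if lo <= hi else ""
        lo, hi = max(1, start - n), start - 1
        return reverse_complement(chrom.slice(lo, hi)) if lo <= hi else ""

    def annotate_variant(self, variant: Variant) -> list[AnnotationRecord]:
        models = self.overlapping_models(variant)
        records: list[AnnotationRecord] = []
        for model in models:
            record = self._annotate_against_model(variant, model)
            if record is not None:
                records.append(record)
        if not records:
            records.append(AnnotationRecord(variant=variant))
        for record in records:
            self.attach_lookups(record)
        return records

    def _annotate_against_model(self, variant: Variant, model) -> AnnotationRecord | None:
        protein = self.bundle.proteins[model.protein_id]
        applied = apply_variant_to_cds(self.wt_cds(model.gene_id), model, variant, self.bundle)
        if applied is None:
            return AnnotationRecord(
                variant=variant,
                gene_id=model.gene_id,
                protein_id=model.protein_id,
                build=model.build,
            )
        effect = classify_effect(
            protein.sequence,
            self.wt_cds(model.gene_id),
            applied.mutant_cds,
            gene_id=model.gene_id,
            protein_id=model.protein_id,
            three_prime_context=self.three_prime_context(model),
            partial_exonic=applied.partial_exonic,
            cds_edit_pos=applied.cds_edit_pos,
        )
        domain = None
        if effect.protein_pos and 1 <= effect.protein_pos <= len(protein):
            domain = domain_at(protein, effect.protein_pos)
        changes = self._motif_changes(protein, effect)
        return AnnotationRecord(
            variant=variant,
            gene_id=model.gene_id,
            protein_id=model.protein_id,
            build=model.build,
            effect_class=effect.effect_class,
            hgvs_p=hgvs_p(effect, protein.sequence),
            domain=domain,
            motif_changes=changes,
            effect=effect,
        )

    def _motif_changes(self, protein, effect: CodingEffect) -> list[MotifChange]:
        """Wild-type vs mutant motif inventory diff for protein-altering effects."""
        if not effect.alters_protein or effect.partial_exonic:
            return []
        if self.options.bitopic_only and not protein.is_bitopic:
            return []
        wt_hits = self.wt_hits(protein.protein_id)
        if effect.effect_class is EffectClass.START_LOSS:
            # no product is modelled: every wild-type motif is lost
            return [MotifChange(h.motif_class, DELETED, h, None) for h in wt_hits]
        cmap = coordinate_map(effect, len(protein))
        mut_topology = carry_topology(protein, cmap, effect.mutant_protein)
        mut_record = mutated_protein_record(protein, effect.mutant_protein, mut_topology)
        mut_hits = scan_motifs(
            effect.mutant_protein,
            self.options.motif_patterns,
            record=mut_record,
            width=self.options.proximal_width,
        )
        from .motifs import diff_motifs

        return diff_motifs(wt_hits, mut_hits, cmap)

    def attach_lookups(self, record: AnnotationRecord) -> AnnotationRecord:
        """Fill rsid and drugs from exact-key joins; absent keys leave '.'."""
        v = record.variant
        record.rsid = self.bundle.rsid_lookup.get(v.key) or v.source_id
        if record.protein_id:
            record.drugs = list(self.bundle.drug_lookup.get(record.protein_id, []))
        return record


def collapse_records(records: list[AnnotationRecord]) -> list[AnnotationRecord]:
    """Keep the most severe record per variant allele (stable for ties)."""
    rank = {cls: i for i, cls in enumerate(SEVERITY_ORDER)}
    best: dict[tuple, AnnotationRecord] = {}
    order: list[tuple] = []
    for rec in records:
        key = rec.variant.key
        if key not in best:
            best[key] = rec
            order.append(key)
        elif rank[rec.effect_class] < rank[best[key].effect_class]:
            best[key] = rec
    return [best[k] for k in order]


def filter_proximal(records: list[AnnotationRecord]) -> list[AnnotationRecord]:
    """Rows restricted to membrane-proximal motif changes only."""
    out = []
    for rec in records:
        proximal = [c for c in rec.motif_changes if c.membrane_proximal]
        if proximal:
            out.append(replace_changes(rec, proximal))
    return out


def replace_changes(rec: AnnotationRecord, changes) -> AnnotationRecord:
    return replace(rec, motif_changes=list(changes))


def annotate_all(
    bundle: AnnotationBundle,
    variants: list[Variant],
    genotypes=None,
    options: PipelineOptions | None = None,
) -> tuple[list[AnnotationRecord], Counter]:
    """Annotate every variant; returns records (input order) and counters."""
    options = options or PipelineOptions()
    annotator = Annotator(bundle, options)
    maf_by_key = {}
    if genotypes:
        for row in cohort_mod.allele_frequencies(genotypes):
            maf_by_key[row.variant.key] = row.maf
    records: list[AnnotationRecord] = []
    stats: Counter = Counter()
    for variant in variants:
        stats["variants"] += 1
        for record in annotator.annotate_variant(variant):
            record.maf = maf_by_key.get(variant.key)
            records.append(record)
            stats[f"consequence:{record.effect_class}"] += 1
            for change in record.motif_changes:
                stats[f"motif:{change.motif_class}:{change.status}"] += 1
    if options.proximal_only:
        records = filter_proximal(records)
    if options.collapse:
        records = collapse_records(records)
    stats["records"] = len(records)
    return records, stats


@dataclass
class BundlePaths:
    genome: str
    models: str
    topology: str
    proteins: str
    rsid: str | None = None
    drugs: str | None = None


def run_pipeline(
    bundle_paths: BundlePaths,
    vcf_path,
    out_path,
    options: PipelineOptions | None = None,
) -> Counter:
    """Load, annotate, write the TSV report; returns the run counters.

    Deterministic for fixed inputs and options.  Inputs are fully read and
    annotated before any output is written, so an unreadable input never
    leaves a partial report behind.
    """
    bundle = load_bundle(
        bundle_paths.genome,
        bundle_paths.models,
        bundle_paths.topology,
        bundle_paths.proteins,
        rsid_path=bundle_paths.rsid,
        drugs_path=bundle_paths.drugs,
    )
    variants, genotypes, samples = read_vcf(vcf_path)
    records, stats = annotate_all(bundle, variants, genotypes, options)
    stats["samples"] = len(samples)
    write_annotations(records, out_path)
    for key in sorted(stats):
        log.info("count %s=%d", key, stats[key])
    return stats
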