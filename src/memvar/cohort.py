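"""Cohort-level aggregation: allele frequencies, truncation burden, spectra.

Allele frequency is computed from genotype calls (hom-alt contributes 2,
het 1; missing genotypes leave the denominator), MAF folds at 0.5.  The
per-individual truncation burden counts distinct homozygous frameshift /
stop-gain variants in transmembrane proteins, mirroring per-genome counts
of deleterious membrane-protein alleles.  The domain spectrum tallies
unique (variant, protein) annotations per topological domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .consequence import TRUNCATING, EffectClass
from .reference_store import AnnotationBundle
from .vcf_io import GenotypeCall, Variant, Zygosity

DOMAIN_KINDS = ("signal_peptide", "extracellular", "transmembrane",
                "cytoplasmic", "unannotated")


@dataclass(frozen=True)
class AlleleFrequencyRow:
    variant: Variant
    alt_count: int
    called_alleles: int
    af: float | None
    maf: float | None

    @property
    def flagged(self) -> bool:
        """True when no alleles were called and the frequency is undefined."""
        return self.called_alleles == 0


def allele_frequencies(genotypes: list[GenotypeCall]) -> list[AlleleFrequencyRow]:
    """Per-variant allele frequencies in first-seen variant order."""
    order: list[Variant] = []
    tallies: dict[tuple, list[int]] = {}  # key -> [alt_count, called_alleles]
    for call in genotypes:
        key = call.variant.key
        if key not in tallies:
            tallies[key] = [0, 0]
            order.append(call.variant)
        if call.zygosity is Zygosity.MISSING:
            continue
        t = tallies[key]
        t[1] += 2
        if call.zygosity is Zygosity.HOM_ALT:
            t[0] += 2
        elif call.zygosity is Zygosity.HET:
            t[0] += 1
    rows = []
    for variant in order:
        alt, called = tallies[variant.key]
        af = alt / called if called else None
        maf = min(af, 1.0 - af) if af is not None else None
        rows.append(AlleleFrequencyRow(variant, alt, called, af, maf))
    return rows


@dataclass(frozen=True)
class SampleBurden:
    sample: str
    n_hom_frameshift: int
    n_hom_stop_gain: int


def sample_burdens(
    annotations,
    genotypes: list[GenotypeCall],
    bundle: AnnotationBundle,
) -> list[SampleBurden]:
    """Per-sample counts of homozygous truncating variants in TM proteins.

    Counts distinct variants (a variant hitting two overlapping models
    counts once) whose effect is frameshift or stop-gain in a protein
    carrying at least one transmembrane feature, restricted to hom-alt
    genotypes.
    """
    def tm(protein_id: str | None) -> bool:
        rec = bundle.proteins.get(protein_id)
        return rec is not None and bool(rec.transmembrane_features)

    frameshift_keys = set()
    stop_gain_keys = set()
    for ann in annotations:
        if not tm(ann.protein_id):
            continue
        if ann.effect_class == EffectClass.FRAMESHIFT:
            frameshift_keys.add(ann.variant.key)
        elif ann.effect_class == EffectClass.STOP_GAIN:
            stop_gain_keys.add(ann.variant.key)

    samples: list[str] = []
    counts: dict[str, list[int]] = {}
    for call in genotypes:
        if call.sample not in counts:
            counts[call.sample] = [0, 0]
            samples.append(call.sample)
        if call.zygosity is not Zygosity.HOM_ALT:
            continue
        key = call.variant.key
        if key in frameshift_keys:
            counts[call.sample][0] += 1
        if key in stop_gain_keys:
            counts[call.sample][1] += 1
    return [SampleBurden(s, counts[s][0], counts[s][1]) for s in samples]


@dataclass(frozen=True)
class DomainSpectrum:
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            return {k: 0.0 for k in self.counts}
        return {k: 100.0 * v / total for k, v in self.counts.items()}


def domain_spectrum(annotations) -> DomainSpectrum:
    """Distribution of mutations over topological domains.

    Counts unique (variant, protein) pairs carrying a domain label; coding
    annotations only (non-coding records have no domain).
    """
    seen = set()
    counts = {k: 0 for k in DOMAIN_KINDS}
    for ann in annotations:
        domain = getattr(ann, "domain", None)
        if domain not in counts:
            continue
        key = (ann.variant.key, ann.protein_id)
        if key in seen:
            continue
        seen.add(key)
        counts[domain] += 1
    return DomainSpectrum(counts)


def filter_by_maf(
    rows: list[AlleleFrequencyRow], threshold: float, direction: str = ">"
) -> list[AlleleFrequencyRow]:
    """Rows with defined MAF strictly above (or below) the threshold."""
    if not 0.0 <= threshold <= 0.5:
        raise ValueError(f"MAF threshold {threshold} outside [0, 0.5]")
    if direction not in {">", "<"}:
        raise ValueError(f"direction must be '>' or '<', got {direction!r}")
    if direction == ">":
        return [r for r in rows if r.maf is not None and r.maf > threshold]
    return [r for r in rows if r.maf is not None and r.maf < threshold]


# ---------------------------------------------------------------------------
# Tabular views (TSV-friendly DataFrames)
# ---------------------------------------------------------------------------

def frequency_table(rows: list[AlleleFrequencyRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.variant.chrom for r in rows],
            "pos": [r.variant.pos for r in rows],
            "ref": [r.variant.ref for r in rows],
            "alt": [r.variant.alt for r in rows],
            "alt_count": [r.alt_count for r in rows],
            "called_alleles": [r.called_alleles for r in rows],
            "af": [r.af for r in rows],
            "maf": [r.maf for r in rows],
        }
    )


def burden_table(burdens: list[SampleBurden]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [b.sample for b in burdens],
            "n_hom_frameshift": [b.n_hom_frameshift for b in burdens],
            "n_hom_stop_gain": [b.n_hom_stop_gain for b in burdens],
        }
    )


def spectrum_table(spectrum: DomainSpectrum) -> pd.DataFrame:
    pct = spectrum.percentages
    return pd.DataFrame(
        {
            "domain": list(spectrum.counts),
            "count": list(spectrum.counts.values()),
            "percent": [round(pct[k], 4) for k in spectrum.counts],
        }
    )


def compare_cohorts(
    rows_a: list[AlleleFrequencyRow],
    rows_b: list[AlleleFrequencyRow],
    names: tuple[str, str] = ("cohort_a", "cohort_b"),
) -> pd.DataFrame:
    """Outer join of two cohorts' frequency tables on the variant key."""
    a, b = frequency_table(rows_a), frequency_table(rows_b)
    key = ["chrom", "pos", "ref", "alt"]
    a = a[key + ["maf"]].rename(columns={"maf": f"maf_{names[0]}"})
    b = b[key + ["maf"]].rename(columns={"maf": f"maf_{names[1]}"})
    return a.merge(b, on=key, how="outer").sort_values(key).reset_index(drop=True)
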