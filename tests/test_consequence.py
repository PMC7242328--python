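import numpy as np
import pytest

from memvar.consequence import (
    EffectClass,
    ReferenceMismatchError,
    apply_variant_to_cds,
    classify_effect,
    coordinate_map,
    cds_to_genomic,
    genomic_to_cds,
    hgvs_p,
)
from memvar.reference_store import cds_sequence, translate
from memvar.vcf_io import Variant

from conftest import build_toy_bundle
from oracles import oracle_snv_effect


def _classify(bundle, variant, ctx=""):
    model = bundle.models["G1"]
    cds = cds_sequence(model, bundle)
    applied = apply_variant_to_cds(cds, model, variant, bundle)
    if applied is None:
        return None
    return classify_effect(
        bundle.proteins["P1"].sequence,
        cds,
        applied.mutant_cds,
        gene_id="G1",
        protein_id="P1",
        three_prime_context=ctx,
        partial_exonic=applied.partial_exonic,
        cds_edit_pos=applied.cds_edit_pos,
    )


class TestGenomicToCds:
    def test_forward_first_base(self):
        bundle = build_toy_bundle("ATGAAATAA", pad=100)
        model = bundle.models["G1"]
        assert genomic_to_cds(model, 101) == 1
        assert genomic_to_cds(model, 100) is None

    def test_reverse_strand_orientation(self):
        bundle = build_toy_bundle("ATGAAATAA", strand="-", pad=100)
        model = bundle.models["G1"]
        start, end = model.span
        # highest genomic exon base is CDS position 1 on '-'
        assert genomic_to_cds(model, end) == 1
        assert genomic_to_cds(model, start) == 9

    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("intron_at", [None, 4])
    def test_round_trip_with_introns(self, strand, intron_at):
        bundle = build_toy_bundle("ATGAAATAA", strand=strand, intron_at=intron_at)
        model = bundle.models["G1"]
        for cds_pos in range(1, 10):
            g = cds_to_genomic(model, cds_pos)
            assert genomic_to_cds(model, g) == cds_pos


class TestApplyVariant:
    def test_snv_inside_exon(self):
        bundle = build_toy_bundle("ATGAAATAA", pad=100)
        applied = apply_variant_to_cds(
            "ATGAAATAA", bundle.models["G1"], Variant("chr_t", 104, "A", "T"), bundle
        )
        assert applied.mutant_cds == "ATGTAATAA"

    def test_deletion_shortens_cds_by_two(self):
        # the chr15 AGG/A deletion pattern
        bundle = build_toy_bundle("ATGAGGAAATAA", pad=100)
        applied = apply_variant_to_cds(
            "ATGAGGAAATAA", bundle.models["G1"], Variant("chr_t", 104, "AGG", "A"), bundle
        )
        assert len(applied.mutant_cds) == 10

    def test_intronic_snv_returns_none(self):
        bundle = build_toy_bundle("ATGAAATAA", intron_at=4, pad=100)
        model = bundle.models["G1"]
        intron_pos = model.cds_exons[0][1] + 2
        applied = apply_variant_to_cds(
            cds_sequence(model, bundle), model,
            Variant("chr_t", intron_pos, bundle.genome["chr_t"].seq[intron_pos - 1], "A"
                    if bundle.genome["chr_t"].seq[intron_pos - 1] != "A" else "C"),
            bundle,
        )
        assert applied is None

    def test_reference_mismatch_raises(self):
        bundle = build_toy_bundle("ATGAAATAA", pad=100)
        wrong_ref = "C" if bundle.genome["chr_t"].seq[103] != "C" else "G"
        with pytest.raises(ReferenceMismatchError, match="chr_t:104"):
            apply_variant_to_cds(
                "ATGAAATAA", bundle.models["G1"],
                Variant("chr_t", 104, wrong_ref, "T"), bundle,
            )

    def test_deletion_straddling_exon_boundary_is_partial(self):
        bundle = build_toy_bundle("ATGAAATAA", intron_at=4, pad=100)
        model = bundle.models["G1"]
        boundary = model.cds_exons[0][1]  # last base of exon 1
        ref = bundle.genome["chr_t"].seq[boundary - 2 : boundary + 2]
        applied = apply_variant_to_cds(
            cds_sequence(model, bundle), model,
            Variant("chr_t", boundary - 1, ref, ref[0]), bundle,
        )
        assert applied is not None and applied.partial_exonic


class TestClassify:
    def test_stop_gain_from_snv(self):
        bundle = build_toy_bundle("ATGAAATAA", pad=100)
        effect = _classify(bundle, Variant("chr_t", 104, "A", "T"))
        assert effect.effect_class is EffectClass.STOP_GAIN
        assert effect.protein_pos == 2
        assert effect.mutant_protein == "M"
        assert effect.truncation_pos == 2

    def test_two_base_deletion_is_frameshift(self):
        bundle = build_toy_bundle("ATGAGGAAAGAATAA", pad=100)
        effect = _classify(bundle, Variant("chr_t", 104, "AGG", "A"))
        assert effect.effect_class is EffectClass.FRAMESHIFT
        assert effect.truncation_pos == effect.protein_pos

    def test_start_codon_snv_is_start_loss(self):
        bundle = build_toy_bundle("ATGAAATAA", pad=100)
        effect = _classify(bundle, Variant("chr_t", 102, "T", "C"))
        assert effect.effect_class is EffectClass.START_LOSS
        assert effect.mutant_protein == ""

    def test_stop_loss_reads_through_into_context(self):
        bundle = build_toy_bundle("ATGAAATAA", pad=100)
        effect = _classify(bundle, Variant("chr_t", 107, "T", "C"), ctx="GGCAGCTAA")
        assert effect.effect_class is EffectClass.STOP_LOSS
        assert effect.mutant_protein == "MKQGS"
        assert effect.terminated

    def test_synonymous_snv(self):
        bundle = build_toy_bundle("ATGAAATAA", pad=100)
        effect = _classify(bundle, Variant("chr_t", 106, "A", "G"))  # AAA->AAG (K)
        assert effect.effect_class is EffectClass.SYNONYMOUS
        assert effect.protein_pos == 2

    def test_inframe_deletion(self):
        bundle = build_toy_bundle("ATGAAGCGGTGGTAA", pad=100)  # M K R W
        # delete codon 3 (CGG), anchored at last base of codon 2
        effect = _classify(bundle, Variant("chr_t", 106, "GCGG", "G"))
        assert effect.effect_class is EffectClass.INFRAME_DELETION
        assert effect.protein_pos == 3
        assert effect.mutant_protein == "MKW"


class TestHgvs:
    @pytest.mark.parametrize(
        "cls, pos, ref_aa, alt_aa, expected",
        [
            (EffectClass.MISSENSE, 251, "S", "Y", "p.S251Y"),
            (EffectClass.STOP_GAIN, 83, "Y", "*", "p.Y83*"),
            (EffectClass.FRAMESHIFT, 52, "S", "L", "p.S52fs"),
            (EffectClass.START_LOSS, 1, "M", "", "p.M1?"),
        ],
    )
    def test_notation(self, cls, pos, ref_aa, alt_aa, expected):
        from memvar.consequence import CodingEffect

        wt = "A" * 300
        wt = wt[: pos - 1] + ref_aa + wt[pos:]
        effect = CodingEffect(
            "G", "P", cls, pos, ref_aa, alt_aa, "", 0,
            truncation_pos=pos if cls in (EffectClass.STOP_GAIN, EffectClass.FRAMESHIFT) else None,
        )
        assert hgvs_p(effect, wt) == expected


class TestCoordinateMap:
    def test_missense_is_identity(self):
        from memvar.consequence import CodingEffect

        effect = CodingEffect("G", "P", EffectClass.MISSENSE, 251, "S", "Y", "M" * 300, 0)
        cmap = coordinate_map(effect, 300)
        assert cmap(250) == 250 and cmap(251) == 251

    def test_stop_gain_truncates(self):
        from memvar.consequence import CodingEffect

        effect = CodingEffect(
            "G", "P", EffectClass.STOP_GAIN, 83, "Y", "*", "M" * 82, -218,
            truncation_pos=83,
        )
        cmap = coordinate_map(effect, 300)
        assert cmap(82) == 82
        assert cmap(90) is None

    def test_inframe_deletion_shift(self):
        from memvar.consequence import CodingEffect

        effect = CodingEffect(
            "G", "P", EffectClass.INFRAME_DELETION, 10, "K", "", "M" * 99, -1
        )
        cmap = coordinate_map(effect, 100)
        assert cmap(9) == 9
        assert cmap(10) is None
        assert cmap(11) == 10

    def test_agrees_with_alignment_oracle_on_random_indels(self):
        # independent oracle: common-prefix / common-suffix alignment of the
        # two protein strings
        rng = np.random.default_rng(5)
        aas = list("ACDEFGHIKLMNPQRSTVW")
        for _ in range(40):
            wt = "".join(rng.choice(aas, size=40))
            k = int(rng.integers(5, 35))
            if rng.random() < 0.5:
                mut = wt[: k - 1] + wt[k:]  # delete residue k
            else:
                ins = str(rng.choice(aas))
                mut = wt[:k] + ins + wt[k:]
            if mut == wt:
                continue
            f = next(i + 1 for i, (a, b) in enumerate(zip(wt, mut)) if a != b)
            s = 0
            while s < len(wt) - f + 1 and s < len(mut) - f + 1 and wt[-1 - s] == mut[-1 - s]:
                s += 1
            from memvar.consequence import CodingEffect

            cls = (EffectClass.INFRAME_DELETION if len(mut) < len(wt)
                   else EffectClass.INFRAME_INSERTION)
            effect = CodingEffect(
                "G", "P", cls, f,
                wt[f - 1 : len(wt) - s], mut[f - 1 : len(mut) - s],
                mut, len(mut) - len(wt),
            )
            cmap = coordinate_map(effect, len(wt))
            for pos in range(1, len(wt) + 1):
                if pos < f:
                    expected = pos
                elif pos <= len(wt) - s:
                    expected = None  # inside the edited core
                else:
                    expected = pos + len(mut) - len(wt)
                assert cmap(pos) == expected, (wt, mut, pos)


class TestSnvOracle:
    """CDS-edit + re-translation equals direct protein editing, both strands."""

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_exhaustive_over_toy_gene(self, strand):
        rng = np.random.default_rng(42)
        from memvar.fixtures import _CODONS_FOR

        protein = "M" + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=28))
        cds = "".join(str(rng.choice(_CODONS_FOR[aa])) for aa in protein) + "TAA"
        bundle = build_toy_bundle(cds, strand=strand, pad=50)
        model = bundle.models["G1"]
        for cds_pos in range(1, len(cds) + 1):
            ref_base = cds[cds_pos - 1]
            for alt_base in "ACGT":
                if alt_base == ref_base:
                    continue
                g = cds_to_genomic(model, cds_pos)
                if strand == "+":
                    variant = Variant("chr_t", g, ref_base, alt_base)
                else:
                    comp = dict(zip("ACGT", "TGCA"))
                    variant = Variant("chr_t", g, comp[ref_base], comp[alt_base])
                effect = _classify(bundle, variant)
                cls, mut_protein = oracle_snv_effect(cds, cds_pos, alt_base)
                assert str(effect.effect_class) == cls, (cds_pos, alt_base, strand)
                assert effect.mutant_protein == mut_protein

    def test_strand_twins_agree(self):
        rng = np.random.default_rng(9)
        from memvar.fixtures import _CODONS_FOR

        protein = "M" + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=20))
        cds = "".join(str(rng.choice(_CODONS_FOR[aa])) for aa in protein) + "TAA"
        fwd = build_toy_bundle(cds, strand="+", pad=50)
        rev = build_toy_bundle(cds, strand="-", pad=50)
        comp = dict(zip("ACGT", "TGCA"))
        for cds_pos in range(1, len(cds) + 1):
            ref = cds[cds_pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                ef = _classify(fwd, Variant("chr_t", cds_to_genomic(fwd.models["G1"], cds_pos), ref, alt))
                er = _classify(rev, Variant("chr_t", cds_to_genomic(rev.models["G1"], cds_pos), comp[ref], comp[alt]))
                assert ef == er
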