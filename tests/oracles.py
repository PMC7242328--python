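"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's matching and classification code:
the motif oracle tests substrings directly against the written-out
consensus membership rules, and the SNV oracle edits the wild-type protein
at the affected codon using only the codon table.
"""

from Bio.Data.CodonTable import standard_dna_table

STANDARD = set("ACDEFGHIKLMNPQRSTVWY")
_TABLE = standard_dna_table.forward_table
_STOPS = set(standard_dna_table.stop_codons)

# admissible substring lengths per motif class: anything else cannot match
_ITAM_LENGTHS = range(14, 21)  # 8 fixed positions + gap of 6..12


def brute_motif_hits(seq: str) -> set[tuple[str, int, int]]:
    """Every (class, start, end) whose substring satisfies a consensus."""
    hits = set()
    n = len(seq)
    for i in range(n):
        s4 = seq[i : i + 4]
        if len(s4) == 4 and s4[0] == "Y" and s4[3] == "Q" and \
                s4[1] in STANDARD and s4[2] in STANDARD:
            hits.add(("YXXQ", i + 1, i + 4))
        s6 = seq[i : i + 6]
        if len(s6) == 6 and s6[0] in "SIVL" and s6[2] == "Y" and s6[5] in "IVL" \
                and s6[1] in STANDARD and s6[3] in STANDARD and s6[4] in STANDARD:
            hits.add(("ITIM", i + 1, i + 6))
        for L in _ITAM_LENGTHS:
            s = seq[i : i + L]
            if len(s) < L:
                break
            if (
                s[0] == "Y"
                and s[3] in "IL"
                and s[-4] == "Y"
                and s[-1] in "IL"
                and all(c in STANDARD for c in (s[1], s[2], s[-3], s[-2]))
                and all(c in STANDARD for c in s[4:-4])
            ):
                hits.add(("ITAM", i + 1, i + L))
    return hits


def oracle_snv_effect(sense_cds: str, cds_pos: int, alt_base: str) -> tuple[str, str]:
    """(effect_class, mutant_protein) for an SNV, by direct codon editing.

    The wild-type CDS must start with ATG and end with a stop codon.
    """
    codon_index = (cds_pos - 1) // 3
    offset = (cds_pos - 1) % 3
    codon = sense_cds[3 * codon_index : 3 * codon_index + 3]
    new_codon = codon[:offset] + alt_base + codon[offset + 1 :]

    def aa(c):
        return "*" if c in _STOPS else _TABLE[c]

    codons = [sense_cds[i : i + 3] for i in range(0, len(sense_cds), 3)]
    wt_protein = ""
    for c in codons:
        if c in _STOPS:
            break
        wt_protein += _TABLE[c]

    if codon_index == 0:
        if new_codon == "ATG":
            return "synonymous", wt_protein
        return "start_loss", ""
    old_aa, new_aa = aa(codon), aa(new_codon)
    mut_codons = codons.copy()
    mut_codons[codon_index] = new_codon
    mut_protein = ""
    terminated = False
    for c in mut_codons:
        if c in _STOPS:
            terminated = True
            break
        mut_protein += _TABLE[c]
    if new_aa == old_aa:
        return "synonymous", wt_protein
    if old_aa == "*":
        return "stop_loss", mut_protein if terminated else mut_protein
    if new_aa == "*":
        return "stop_gain", mut_protein
    return "missense", mut_protein
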