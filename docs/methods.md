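# Methods

## Scope and model

`memvar` models the consequence of a genomic variant on a membrane
protein as a three-stage transformation: genomic edit → mutated coding
sequence → mutant full-length protein, followed by a motif-level diff of
the wild-type and mutant products. The unit of annotation is one (variant
allele, gene model) pair; a variant overlapping two gene models yields two
independent records, and a variant overlapping none yields a single
`non_coding` record.

All coordinates at the interfaces are 1-based inclusive (VCF convention):
genomic positions, spliced CDS offsets, and protein residues. Half-open
arithmetic is used internally but never exposed.

## Reference bundle

The bundle is a local, validated stand-in for a genome build plus protein
knowledgebase: chromosome FASTA, gene models (tab-delimited exon lists or
a GFF3 subset of CDS rows grouped by `ID`), protein FASTA, topology
features (signal peptide / extracellular / transmembrane / cytoplasmic
spans), and optional exact-key rsID and drug-agent lookup tables.
Structural invariants are enforced at load time: exons sorted and
non-overlapping, CDS length divisible by 3, CDS starting with ATG and
ending in a stop, topology features in range and non-overlapping, every
cross-reference resolving, one build tag per bundle (no liftover), and —
the strongest check — the translation of every model's CDS must equal its
protein record exactly. One canonical protein per gene model; isoforms are
out of scope.

Translation uses the standard nuclear code only (no selenocysteine, no
mitochondrial table); a codon containing any non-ACGT base translates to
`X`, and motifs never match through `X` — the conservative choice for
ambiguous reference sequence.

## Variant normalization and CDS surgery

Variants stay VCF-anchored (the leading shared base is kept) but each
exposes a fully trimmed *edit span*: shared suffix then shared prefix
removed, giving the first..last replaced reference base and the net length
change. A pure insertion has an empty span anchored between two genomic
positions. Normalization is a local trim only — no left-alignment against
the reference — because bundle-relative correctness is established by
projection round-trips rather than by a normalization convention.

Edits are applied on the forward-spliced exon concatenation and the whole
mutant splice is reverse-complemented once for `-` strand genes, which
makes alt-allele strand correction automatic. A ref-allele mismatch with
the bundle genome raises an error rather than skipping: a silently
mis-anchored edit would corrupt every downstream motif call. Edits
straddling an exon boundary apply only their intra-exonic part, are
flagged `partial_exonic`, and are excluded from motif analysis; wholly
intronic or intergenic edits annotate as `non_coding`. Insertions exactly
at an exon edge are treated as intronic.

## Effect classification

Precedence, applied to the translated mutant CDS:

1. **start_loss** — mutant CDS no longer begins with ATG. No product is
   modelled (no re-initiation scanning); the mutant protein is empty and
   every wild-type motif is reported deleted.
2. **frameshift** — net CDS length change not divisible by 3. A premature
   stop arising in the shifted frame is a *consequence* of the shift, so
   frameshift wins over stop_gain; this keeps the frameshift and
   stop-insertion tallies distinct in cohort summaries.
3. **stop_gain** — the mutant translation terminates before the expected
   length (early in-frame stop), including in-frame indels that introduce
   a stop.
4. **stop_loss** — the wild-type stop codon is lost; translation reads
   through into downstream transcript sequence (the pipeline supplies up
   to 90 nt of 3′ genomic context in transcription orientation) until the
   next in-frame stop, else the product is flagged unterminated.
5. **synonymous / missense / in-frame insertion / deletion** — by
   comparing the two protein strings; a multi-codon substitution of equal
   length is reported as missense spanning the first..last differing
   residues. For synonymous effects the affected codon is recovered from
   the CDS edit position so the record still carries a meaningful domain.

`protein_pos` is the first differing residue; `truncation_pos` is the
first lost wild-type residue of a truncating effect. HGVS output is the
simplified protein-level form (`p.S251Y`, `p.Y83*`, `p.S52fs`, `p.M1?`,
`p.K10del`, `p.A10insW`, `p.*300ext`), not the full recommendation
grammar.

### Coordinate map

Each effect induces a wild-type→mutant position map used for motif
retention and topology carry-over: identity below the first change;
in-frame edits shift positions past the replaced core by the net protein
length change (positions inside a deleted core map to nothing);
truncating effects map nothing at or beyond the truncation; everything
downstream of a frameshift's first changed residue maps to nothing even
where the shifted sequence coincidentally matches — scrambled sequence is
not the same residue. The map is checked in tests against a
common-prefix/common-suffix alignment oracle.

## Topology and the membrane-proximal window

Domain assignment is a direct lookup into the curated features; positions
covered by no feature are `unannotated` rather than inferred — no
hydropathy-based TM prediction is attempted, mirroring reliance on curated
topology. The juxtamembrane window takes, for each TM span, the first
`proximal_width` residues of the *abutting* cytoplasmic feature: the
C-terminal side for type I orientation, the N-terminal side for type II,
both sides of a cytoplasmic loop in multi-pass proteins. Orientation is
inferred purely from feature order.

**Width default = 80 residues.** No quantitative definition of
"membrane-proximal" exists for these motifs; 80 comfortably covers
receptor juxtamembrane exemplars (YxxQ motifs ~3–12 residues past the TM
end) while excluding distal tails, and it is configurable
(`--proximal-width`). Because the cutoff is a judgment call, the default
output annotates *all* motif changes and carries a per-change
membrane-proximal flag; `--proximal-only` restricts rows to flagged
changes instead of silently discarding anything.

Mutant-protein topology is carried through the coordinate map: each
feature keeps the mapped extent of its surviving residues, features wholly
lost to truncation are dropped, and novel frameshift tails are
unannotated (so nothing in a scrambled tail can count as
membrane-proximal).

## Motif scanning and diffing

Patterns are data: ordered residue-set constraints with optional bounded
gaps (`Y,x,x,[IL],gap(6,12),Y,x,x,[IL]`; `[SIVL],x,Y,x,x,[IVL]`;
`Y,x,x,Q`), where `x` is any of the 20 standard residues. The compiled
matcher enumerates *every* (start, end) satisfying the constraints —
overlapping hits included, one hit per admissible ITAM gap length — since
downstream diffing needs the complete inventory, not a maximal
non-overlapping cover. The scanner is verified by exact set-equality
against a brute-force substring enumerator on 1000 seeded random
sequences. Input is uppercased; `X` and non-standard letters match no
constraint. Patterns can be redefined in a YAML config so new motif
classes or looser bounds need no code change.

A hit is membrane-proximal iff its **first tyrosine** lies in the
juxtamembrane window — anchoring on the functional residue keeps the flag
stable when a truncation clips the tail of a hit's span.

The diff pairs a wild-type hit with a mutant hit when every position of
the wild-type hit survives the coordinate map and the mapped span carries
a same-class mutant hit (`retained`); unmapped or unpaired wild-type hits
are `deleted`; unpaired mutant hits are `created`. By construction
|retained|+|deleted| = |wild-type hits| and |retained|+|created| =
|mutant hits|.

### Known discrepancy: published ITAM-creating contexts

Two published juxtamembrane peptide contexts reported as gaining an ITAM —
CLM1 p.S251Y (`YLTLGAEDQEPTYCNMGHLSSHLPGRGPEEPTEYSTIS`) and OSMR p.H793Y
(`YPDIPDPYKSSILSLIKFKENPYLIIMNVSDCIPDAIE`) — contain **no** match under
the strict stated consensus `Y-x-x-[I/L]-x(6..12)-Y-x-x-[I/L]`; the
original calls evidently used a wider spacer or a looser second-half set.
Rather than guess an undocumented pattern, the scanner implements the
stated consensus as the default, keeps the bounds configurable, and this
behaviour is pinned by a dedicated test (scanner and independent
enumerator both find zero ITAMs in those 38-mers).

## Cohort aggregation

Allele frequency is `alt/called` with hom-alt contributing 2, het 1, and
missing genotypes excluded from the denominator; MAF folds at 0.5. The
per-sample truncation burden counts *distinct* homozygous
frameshift/stop-gain variants in proteins with ≥1 TM feature — per
variant, not per annotation, so a variant hitting two overlapping models
counts once per genome. The domain spectrum tallies unique (variant,
protein) pairs per topological domain. Phasing is ignored (`0|1` ≡
`0/1`); heterozygous alleles of one site are annotated independently;
multi-allelic sites are counted per split allele. Cohort comparison is a
key-join of two independent frequency runs — no statistical test is
attached because none is defined for this comparison.

## Synthetic data generator

The generator emulates the annotator's study conditions: cohorts of type
I, type II and multi-pass membrane proteins (cycled 1:1:1), protein
lengths ~180–260 residues with a 21-residue TM helix, 30% of genes
carrying one intron to exercise multi-exon projection, strands assigned
~1:1, and motifs planted in the juxtamembrane window (each gene gets a
YxxQ, a second motif cycling ITAM/ITIM/YxxQ, and an `SKKQ` precursor that
one transversion turns into `YKKQ` — mirroring a serine→tyrosine
motif-creating missense). The default cohort plan plants **7 homozygous
frameshift and 5 homozygous stop-gain variants per genome**, the reported
per-individual burden of deleterious membrane-protein alleles, plus
heterozygous missense, synonymous, start-loss, stop-loss, in-frame
indels, and motif create/delete/retain scenarios; sample count defaults
to 5 per cohort.

Truth is geometric, not scanner-derived: background sequence contains no
tyrosine and two glycine guards precede every plant, so the planted
inventory *is* the wild-type hit set and expected motif changes follow
from plant positions and coordinate arithmetic. Frameshift candidates are
retried until the shifted tail encodes no tyrosine, the shifted frame
terminates inside the CDS, and the first changed residue falls clear of
every plant — keeping created-motif truth empty by construction (the
first-changed-residue position itself is derived with the same codon
table the oracle tests pin down). Back-translation picks codons uniformly
at random (no codon-usage model); every output is a pure function of
(seed, parameters), and each planted variant's ref allele is asserted
against the generated genome.

What the generator does **not** emulate: realistic allele-frequency
spectra or mutation-rate models, overlapping gene models, splice-site
disruption, compound haplotypes, isoforms. Passing the planted-truth
suite therefore demonstrates correctness of the projection → re-translation
→ motif-diff machinery under controlled conditions, not calibration
against population genomic data.

## Numerical and procedural choices

- Collapse severity order (for `--collapse`): start_loss > frameshift >
  stop_gain > stop_loss > missense > in-frame insertion > in-frame
  deletion > synonymous > non_coding; this package's convention.
- Symbolic alleles (`<DEL>`, breakends) and non-ACGTN alleles are skipped
  with a logged warning; a missing `#CHROM` header is a format error.
- rsID and drug lookups are exact-key joins; an rsID present in both the
  lookup table and the VCF ID column prefers the table.
- Output is deterministic: rows follow input variant order; repeated runs
  are byte-identical.
- Problem sizes in the validation suite — 1000 random sequences (length
  ≤200) for the scanner oracle, a 300-nt toy gene × every position × 3
  alt bases × both strands for the consequence oracle, ten 20-gene /
  5-sample cohorts for planted-truth recovery, 100 random genotype
  matrices for frequency arithmetic — were chosen to exhaust each
  code path many times over while keeping the default suite fast.

## Limitations

- No NMD modelling, no re-initiation after start loss, no splice-site
  effects, no phased compound effects.
- Stop-loss read-through depends on the supplied 3′ context length
  (default 90 nt); genes at a contig edge may remain unterminated.
- HGVS strings are simplified (no 3-letter codes, no `fs*N` tail length,
  no normalization of repeated-residue indels to the 3′-most position).
- The ITAM gap discrepancy above means motif calls on real receptors may
  undercount relative to published looser-pattern tools unless the bounds
  are widened in the motif config.
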