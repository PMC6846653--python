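# Methods

This note records the models, conventions and numerical choices behind
`bsjkit`, in the order data flows through the package.

## Coordinates and junction identity

All internal coordinates are 1-based inclusive. A backsplice junction is
identified by `(chrom, donor_pos, acceptor_pos, strand)` where
`donor_pos` is the first intron base on the donor side and
`acceptor_pos` the last intron base on the acceptor side, exactly as
splice-aware aligners report chimeric junctions. The backsplice
inversion means `acceptor_pos < donor_pos` on `+` and the reverse on
`-`; the circularised sequence occupies the coordinates strictly between
the two. External tables are normalised at parse time: CIRI2 is already
1-based inclusive, circExplorer2 starts are 0-based (BED heritage) and
shifted +1 on import, so the same circle from either source maps to one
internal key.

Sample grouping strips the *longest* recognised filename suffix
(`.Chimeric.out.junction`, `.SJ.out.tab`, `.ReadsPerGene.out.tab`,
`.ciri`, `.ce`), so sample ids containing dots survive. Gzip inputs are
accepted transparently.

## BSJ detection

Within-read chimeric records (junction code ≥ 0) are accepted when
donor and acceptor share a chromosome and strand, are in backsplice
orientation, and span at most `max_span` (default 1,000,000 bp — the
aligner reports arbitrary chimeras and some cutoff is needed; the value
is configurable and generous relative to known circRNA). Records are
deduplicated by `(read_id, junction)` so a read pair contributes at most
one count, matching junction-read counting in comparable callers.

Pair-encompassing records (code −1, mates flanking but not containing
the junction — "type IV") never create a junction and never enter the
total; they are tallied as supporting evidence on an already-detected
key when both mate positions fall inside the circular span within a
fragment-length tolerance (default 300 bp) of their respective
boundaries. Everything else is discarded with a per-reason count, so
`counted + type-IV + discarded = input records` (tested).

With `same_strand_required=False`, records whose two segments disagree
on strand are folded onto an unstranded (`.`) key using the `+`
orientation convention, so the same physical junction maps to one key.

## Mate classification and the RAD score

In a paired-end chimeric alignment the mate-gap operator `p` splits each
segment CIGAR into a mate-1 portion (before `p`) and a mate-2 portion
(after). The longest contiguous run of `M` operations across the
attributed portions identifies the *intact* mate — the mate that does
not contain the junction — and the BSJ is assigned to the other mate:
intact mate 2 ⇒ type II (junction in mate 1), intact mate 1 ⇒ type III.
Segments without `p` cannot be attributed to a mate and are ignored for
attribution; records with no `p` at all (single-end) and exact ties are
classified AMBIGUOUS. Ties get no directional guess because either
choice would bias the RAD numerator; ambiguous reads still count toward
the junction total but never toward the RAD ratio.

`RAD = typeII / (typeII + typeIII)`, reported only when
`typeII + typeIII ≥ 10` (default): below that, single-read fluctuations
move the ratio too much to be interpretable. The filter keeps
`0.1 < RAD < 0.9`; junctions with *undefined* RAD are never removed by
the RAD filter itself — culling low-count junctions is the separate
`min_count` filter's job. Filtering is per-sample by default (a row
survives if it passes in any sample); a `mean` mode averages defined RAD
values across samples first, useful when replicates are shallow.

## FSJ support

A forward junction supports a BSJ boundary when its intron start (or
end) equals the BSJ donor (or acceptor) coordinate on the same
chromosome; each supported boundary adds 1, giving a score of 0, 1 or 2.
By default matching is position-only (strand-agnostic), since unstranded
libraries are supported and coordinate equality is already a strong
condition; `strand_aware=True` pins the boundary roles (donor ↔ intron
start on `+`, mirrored on `-`). The score is monotone in the FSJ table:
adding junctions can only raise it. It is meaningless on RNase-R-treated
libraries, where linear evidence has been degraded.

## Alignment-type model

For a circle of size `C`, fragment length `F`, read length `R` and
minimum junction overhang `m` (defaults 300 / 100 / 0 nt), with the
junction uniform on the circle:

```
p1 = (C − F) / C                 (C ≥ F; 0 otherwise)
p2 = p3 = (R − 2m) / C
p4 = (F − 2R + 4m) / C           (clamped at 0 when reads overlap)
```

`p4` absorbs both the unsequenced inter-mate gap and the `2m` of
overhang slack at the fragment edges where a junction is present but
undetectable, which keeps the four proportions an exact partition. For
`C < F` the fragment wraps: every fragment contains the junction
(`p1 = 0`) and the read regions are mapped to the circle as interval
unions; positions captured by both reads (possible once the fragment
wraps, or when `F < 2R`) are split evenly between types II and III.
This even split preserves the II/III symmetry that the uniform-junction
model implies — a first-lap-only rule would bias type II for small
circles. The model is continuous (length fractions); the discrepancy
against discrete base counting is O(1/C). It agrees with an independent
Monte-Carlo fragment-placement oracle within 3 standard errors at 10⁶
draws (tested). The expected type-I load given an observed BSJ count is
`count · p1 / (p2 + p3)`.

## Normalisation

Two options: counts per million of the sample's total BSJ counts, or
counts per billion of the sample's total mapped gene counts (the
spliced-reads-per-billion-mapped scale), the latter taken from the
unstranded column of the gene-count files. Zero denominators yield NaN
and a per-sample flag rather than an error.

## Sequence assembly

The predicted circRNA sequence for a junction is built from the single
transcript whose exons inside the circular span (a) all fit within it
and (b) whose outermost selected boundaries coincide exactly with the
span edges — i.e. `donor_pos = last selected exon end + 1` and
`acceptor_pos = first selected exon start − 1`. Among qualifying
transcripts the largest total selected-exon length wins; ties break on
the lexicographically smallest transcript id for determinism. Sequences
are concatenated in genomic order and reverse-complemented for `-`
transcripts, so the string is 5′→3′ and linearised acceptor→donor (the
junction sits between the last and first base). Junctions matching no
transcript return an explicit "no compatible model" value, not an
exception — circles formed inside coding exons are real and simply have
no model-derived sequence. Ambiguity codes (N) pass through unchanged.

The junction window is `flank + '.' + flank` characters cut from the
circularised sequence (default flank 50, total 101); circles shorter
than the flank wrap with repetition.

## ORFs and miRNA seeds

The circular ORF scan translates the sequence concatenated three times —
enough for any frame to cross the junction and lap the circle — and
reports the longest ATG-initiated ORF whose start codon lies in the
first copy (earliest start on ties). An ORF with no stop within the
tripled scan is truncated there and flagged `rolling`; one longer than
`⌊L/3⌋` amino acids is flagged as exceeding linear coding capacity (a
1099 nt circle carrying a 388-residue frame exceeds its linear maximum
of 366 by 22). Standard genetic code; codons containing N translate to
`X` and never act as start or stop. A stop-to-stop mode (no ATG
requirement) is available behind a flag. Only the sense strand is
scanned — the circle is already stranded.

Seed scanning matches the reverse complement of the miRNA seed (1-based
positions 2–8 of the mature sequence by default; length 6–8 nt
enforced) against `circle + first (k−1) bases`, so junction-straddling
sites are found and total hit counts are rotation-invariant (tested).
A minimum-hit filter suppresses the single-site noise inherent to short
seeds.

## FSJ coverage and biogenesis

Relative to a BSJ span, a gene's forward junctions partition into
*internal* (both intron ends strictly inside), *spanning* (intron
enclosing the whole span — the exon-skipping signature) and *canonical*
(everything else; junctions with exactly one end inside are deliberately
classed canonical, as are junctions reusing the BSJ coordinates
themselves, since both leave the span). Internal and canonical are
summarised as mean unique-read counts per junction; spanning support is
summed in reads and divided by the BSJ count so the comparison tracks
abundance. Spanning support at ≥ 5% of the BSJ count (configurable; the
threshold formalises what is otherwise a visual judgement) calls the
circle a transcript by-product; internal support without spanning calls
it transcript-derived; no junction evidence is indeterminate.

## Simulator

The simulator defines the test conditions end to end. Defaults: 100 nt
paired reads, 300 nt fragments, FR orientation, error-free reads with
constant high base quality, junction offsets uniform within
`[m, R − m]` of the junction-bearing read with `m = 15` (the chimeric
overhang minimum typical of aligner settings), 12 pairs per junction,
50/50 type II/III. All randomness flows from one seeded generator;
identical seeds give byte-identical outputs.

Fragments are drawn from the doubled circular sequence so they wrap the
junction; read 2 is the reverse complement of the fragment end. Read ids
encode `junction|type|offset|serial` and parse back to a full truth
record. Chimeric records are constructed from the truth geometry with
the exact positions and CIGARs (including the `p` mate-gap) an aligner
would emit, letting the classifier and detector run hermetically; CIGAR
operations are written in read order, and record construction treats the
circle as a contiguous genomic span (single-exon geometry) — multi-exon
reads in the FASTQ path are spliced, but the record path does not insert
`N` operations for internal introns. Type I pairs are refused for
circles not larger than a fragment (no junction-free placement exists),
and record simulation requires `F ≥ 2R` (non-overlapping mates).

Synthetic gene models place non-overlapping multi-exon genes on both
strands with exons of 90–260 nt and introns of 120–420 nt — small
enough for fast tests, large enough that internal exon blocks exceed a
fragment. FSJ tables draw Poisson unique counts (mean 20) per adjacent
exon pair; selected junctions can be zeroed to emulate RNase-R-depleted
linear evidence.

What the simulator does *not* emulate — and what passing tests therefore
do not show about real data: sequencing errors and quality variation,
fragment-length dispersion, multi-mapping and alignment ambiguity,
linear-transcript background reads, homology-driven false chimeras, and
aligner-specific quirks (e.g. blind spots near read ends). The
classifier's measured accuracy on simulated records is a property of the
decision rule under clean geometry, an upper bound on real-data
behaviour.

## Problem sizes

The test suite and the acceptance script run everything at desk scale:
10⁶ Monte-Carlo draws for the model check, 1000 simulated read pairs
over 120+ junctions for classifier accuracy, 200 pairs for the balanced-
RAD check, genomes of 2 × 60 kb with 6 genes for the end-to-end round
trip. These sizes give comfortable statistical margins for every
assertion while keeping the whole suite in the seconds range.

## Known limitations

* Detection trusts the aligner's chimeric calls; no realignment or
  sequence-level verification of the junction is attempted.
* Integer counting only; multi-mapping chimeric reads are not counted
  fractionally.
* Internal alternative splicing of the circle is not reconstructed
  (FSJ coverage exposes the evidence but no isoform model is built).
* The FSJ support score requires forward-splice evidence in the same
  sample and is unusable on RNase-R-only designs.
* Whether annotated "canonical" transcripts should outrank the
  longest-exon-sum transcript during sequence assembly is an open
  modelling choice; the longest-sum rule is used because it needs no
  annotation tiering.
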