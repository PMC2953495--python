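# Methods

## The detection model

A conjoined gene (CG) call is purely positional: a spliced transcript
alignment is linked to every annotated locus on its chromosome and strand
whose exons its blocks intersect by at least `min_exon_overlap_bp`
(default 1 bp — "at least part of one exon" is the defining criterion, and
the parameter exists only because 1 bp is sensitive to alignment noise). A
call requires ≥ 2 such parents; parents are ordered 5′→3′ in transcription
direction, and genes whose whole span lies inside the transcript span
without contributing exonic overlap are recorded as *bypassed* rather than
breaking the call, since read-through events can skip over internally
located genes. Calls three and four parents deep are supported. No maximum
parent distance is imposed: genuine events span up to hundreds of kb.

Before detection, gene records on the same strand whose exons overlap by
≥ 1 bp are collapsed into single loci (union–find on exon overlap; union of
exons, lexicographically smallest id as representative, all symbols
retained). This removes the classic artifact in which naming variants or
splice variants of one locus masquerade as two parents.

### Curation

Manual curation of false positives is operationalized as three automated,
documented filters, each attaching a named rejection reason:

- `short_alignment`: aligned length < `min_aligned_length_bp` (default
  200 bp) — a reproducible proxy for "short/poor-quality EST", since the
  inputs here are already-aligned blocks without base qualities;
- `unspliced`: no gap ≥ `min_intron_bp` (default 40 bp) when
  `require_spliced` is set, mirroring the restriction to spliced evidence;
- `paralog_suspect`: the parents' exonic sequences contain a local
  alignment stretch of ≥ `paralog_min_len_bp` (100) columns at
  ≥ `paralog_identity` (0.90) — the signature of a transcript mis-aligned
  across duplicated gene-family members. The test is applied to a window
  within the best-scoring local alignment, not to the alignment as a
  whole: score-optimal alignments extend a duplicated core into noisy
  flanks, which can dilute whole-alignment identity just below threshold
  while a ≥ 100 bp / ≥ 90 % core is plainly present.

## Splicing classification

The *junction-intron pattern* is true when a single transcript intron fully
contains the interval from the start of the upstream parent's terminal exon
(transcription order) to the end of the downstream parent's initial exon —
one new intron bridging terminal exon, intergenic region and initial exon.
Multi-parent calls evaluate the pattern per adjacent pair and report the
conjunction plus the per-pair vector.

A block is a *novel exon* iff it intersects no parent exon; its origin is
judged against the parents (within a parent intron → intronic; within the
inter-parent gap → intergenic; outside the joint span → flanking on the
respective transcription side; otherwise mixed).

A splice-site boundary is *conserved* iff its genomic coordinate coincides
with the corresponding boundary (donor with donor, acceptor with acceptor,
strand-aware) of any annotated intron of any parent — per boundary, not per
intron pair. Because "new sites" can be counted per site or per intron, the
report carries both granularities (`n_new_sites`, `n_new_introns`).
Canonicality means the transcribed-strand intron begins GT and ends AG
(plus-strand genomic CT…AC for minus-strand transcripts); dinucleotides
containing N, and introns shorter than 4 bp, are non-canonical.

## ORF analysis

When no annotated CDS is supplied for the transcript, the ORF is the
longest ATG-initiated reading frame, ties broken 5′-most; an ORF with no
in-frame stop runs to the transcript end and is flagged incomplete (product
classification still proceeds; NMD is then not applicable).

Frame comparison is coordinate-based and therefore invariant to synonymous
(indeed to any) base changes: the ORF is mapped through the exon chain to
genomic positions with codon phases; a parent's frame is *conserved* iff
every genomic position coding in both the ORF and the parent CDS
(≥ `min_shared_coding_bp`, default 30, to exclude trivial overlaps) carries
the same phase, *different* iff phases disagree anywhere over such a shared
set, and *no_overlap* below the floor. Product classes follow: conserved
with every CDS-bearing parent → chimeric; with exactly one → similar to
that parent, recording the 5′/3′ side so directional statistics can be
computed on any corpus; otherwise novel-or-non-coding.

NMD candidacy uses the standard 50-nt boundary rule (`--nmd-distance`,
default 50): the transcript is a candidate iff its stop codon ends ≥ 50 nt
upstream of the last exon–exon junction; single-exon transcripts are never
candidates. The rule is a deliberate, exposed operationalization — NMD
prediction is not otherwise specified by positional data alone.

A caveat on the "frame-shifting novel exon ⇒ downstream parent different"
intuition: it holds only when the shifted reading actually survives ≥ 30 nt
into the downstream CDS without hitting a premature stop. On random
sequence the shifted frame often terminates early (giving `no_overlap`), so
the property is exercised in tests on constructed sequences whose shifted
frames are stop-free.

## Junction exons, SHS, conservation

The junction exon is the transcript region containing sequence from both
parents: a single block when one block crosses both parents' exonic
territory, else the spliced region from the last upstream-parent block
through the first downstream-parent block, intervening novel exons
included. The breakpoint marks where upstream-derived sequence ends; in
single-block mode it sits at the end of the upstream parent's exonic
overlap, falling back to the midpoint of the unassigned gap (flagged
ambiguous) when the two parents' overlaps do not abut.

SHS (short homologous sequence) detection — the footprint expected under
the transcriptional-slippage model of chimera formation — enumerates all
maximal exact common substrings ≥ `shs_min_len` (4 bp) between the
`window` (20 nt) bases ending at and starting at the breakpoint. The
window size is a free construction parameter, exposed because the SHS
concept does not fix it.

Conservation search replaces an external aligner with an in-package
seed-and-extend engine: exact k-mer seeds (k = 11, both strands) gate a
full affine-gap Smith–Waterman (match +1, mismatch −1, gap of length L
costs 2 + L) computed column-wise with numpy; vertical-gap scores use a
decayed prefix-max, which is exact because re-opening a gap from within a
gap is always dominated. A target is reported iff coverage > 0.90 of the
junction sequence and identity > 0.90 over the aligned columns and score
≥ `min_score` (default 30). The raw-score floor stands in for a
statistical significance cut-off, whose definition is aligner-specific;
the 90/90 thresholds are the primary criteria. Tests verify score
agreement with an independent full-DP implementation (biopython's
`PairwiseAligner`) and hit/no-hit agreement at the thresholds.

## Candidate pairs

Same-chromosome, same-strand gene pairs with intergenic gap
0 ≤ g < `max_gap` (10 kb) are the candidate substrate for CG formation;
overlapping loci are excluded (they belong to locus collapse). Pairs are
not restricted to adjacent genes, matching the observation that CGs bypass
internal genes; `--adjacent-only` reproduces the conservative screen used
when designing validation experiments. Validation regions are the
transcription-direction second-to-last exon of the upstream gene and second
exon of the downstream gene — the exons most likely retained in a CG
transcript, since terminal/initial exons are typically spliced out.
Distance summaries use the standard even/odd median rule and list pairs
> 100 kb apart as named outliers.

## The simulator

`simulate_scene` emulates the real input set — genome FASTA, GTF annotation
with phase-annotated CDSs, BED12 spliced alignments — at desk scale, with
the truth fully known. Parent genes carry 3–6 exons of 80–300 bp,
introns of 100–2000 bp with canonical GT-AG sites planted on the
transcribed strand, a wholly-UTR first exon, a CDS starting at an ATG with
phase 0, and ≥ 20 nt of 3′ UTR. Intergenic gaps are 500–15000 bp, so the
median planted parent gap lands near 10 kb, the regime where read-through
pairs actually live. The default scene plants 50 CGs spread over eight
classes (junction-intron pattern, retained terminal exon, intergenic and
intronic novel exons, in-frame chimeric fusion, frameshifted
similar-to-5′, NMD-positive, SHS-positive with repeat lengths 4–8) and 50
negatives in five classes (antisense overlap, unspliced EST, single-locus
multi-name, paralog mimic sharing a ~97 %-identical 150 bp exon, monogenic
transcript), plus 30 background genes without transcripts.

Planted classes are realised by construction — which exons the transcript
keeps, where the upstream parent's stop codon falls, what is inserted
between the parents — and the sequence-dependent truth labels (longest ORF
identity, NMD distance, maximal junction repeat) are then re-derived from
the emitted sequences by small independent oracles inside the generator,
with targeted repair (scrubbing stray ATGs outside the planted ORF,
truncating chance competitors) and bounded resampling when a random draw
violates a planted label. The truth table is therefore consistent with the
emitted files by construction, not by assumption. All randomness flows from
the single config seed, and equal seeds give byte-identical files.

The default chromosome length is auto-sized from the layout (the default
scene needs ~2.6 Mb); an explicit `chrom_length` too small for the
requested content raises a sizing error naming the required minimum.

What the simulator does *not* model — and hence what passing tests do not
show about real data: alignment error and base-call noise (blocks are
exact), expression levels and tissue specificity, paralogy beyond the
planted single-exon duplications, non-canonical splice sites in parents,
genes on multiple chromosomes, and annotation incompleteness. Results on
real corpora depend on those factors; the tests establish correctness of
the machinery, not corpus-level fractions.

## Numerical and design choices

- Coordinates are 0-based half-open internally everywhere; GTF's 1-based
  inclusive convention is converted only at file boundaries. BED12 needs no
  shift and round-trips bit-exactly.
- Gene exon sets are union-merged across transcripts per gene id: parents
  are treated as single loci.
- Alternative splicing within a CG group compares intron chains only;
  differing terminal block ends alone do not count.
- Aligner tie-breaks prefer diagonal moves, giving compact alignments;
  traceback metrics count gap columns in the identity denominator.
- Degenerate inputs: empty annotations yield empty results; a gene with
  < 2 exons yields a named not-applicable signal from validation-region
  selection; an incomplete ORF yields NMD "not applicable" rather than
  false; junction sequences shorter than the seed k raise an instructive
  error.
- Problem sizes in the test-suite oracle comparisons (100 random detection
  scenes, 1000 random ORF sequences, 1000 SHS window pairs, conservation
  sweeps of ~50 replicates at 400 bp) were chosen to exercise the
  state spaces densely while keeping the whole suite around ten seconds.

## Known limitations

- ORF analysis uses the longest-ATG rule whenever no CDS annotation for
  the transcript is given; corpus statistics computed from curated CDS
  databases will differ where those annotations disagree with the rule.
- The paralog filter sees only the two parents' exonic sequences; it
  cannot recognise mis-alignments against family members absent from the
  annotation.
- Conservation search targets transcript FASTA sets, not whole genomes,
  and reports per-target best hits only.
- `detect_alternative_splicing` needs ≥ 2 supporting transcripts and
  returns not-applicable otherwise.
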