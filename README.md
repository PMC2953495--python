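# conjoinscan

Detection and characterization of **conjoined genes** (CGs, also called
read-through or cis-fusion transcripts) from spliced transcript alignments.

A conjoined gene is a transcript that combines at least part of one exon
from each of two or more distinct *parent* genes lying on the same
chromosome and in the same orientation. Such transcripts arise from
transcriptional read-through across neighbouring loci, and they matter in
two ways: in-frame fusions can encode chimeric proteins, while out-of-frame
fusions can silence a parent gene, often through nonsense-mediated decay
(NMD) of the fused transcript. `conjoinscan` is for genome annotators and
transcriptomics researchers who have a genome, a gene annotation and a set
of pre-aligned mRNA/EST (or long-read) transcripts, and want to find and
characterize the read-through events in them.

## What it computes

Given a genome (FASTA), a gene annotation with exons and CDSs (GTF), and
spliced transcript alignments (BED12 or GTF), the pipeline:

1. **Detects** transcripts whose exon blocks overlap exons of ≥ 2 distinct
   same-strand loci (after collapsing naming variants of single loci), with
   parents ordered 5′→3′ in transcription direction.
2. **Curates** the classic false-positive modes: short alignments
   (< 200 bp), unspliced ESTs (no intron ≥ 40 bp), and paralogous
   mis-alignments — parents whose exonic sequences share a local alignment
   stretch of ≥ 100 bp at ≥ 90 % identity.
3. **Classifies splicing**: whether one new intron bridges the parents
   (spanning the upstream gene's terminal exon, the intergenic region and
   the downstream gene's initial exon), novel exons and their origins
   (intergenic / intronic / flanking), and per-intron splice-site
   conservation and GT-AG canonicality.
4. **Analyses the ORF**: the longest ATG-initiated reading frame, per-parent
   codon-phase conservation (conserved with all parents → *chimeric
   protein*; with exactly one → *similar to the 5′ or 3′ parent*; with
   none → *novel or non-coding*), and NMD candidacy by the 50-nt rule
   (stop codon ≥ 50 nt upstream of the last exon–exon junction).
5. **Examines the junction exon** — the region containing sequence from
   both parents — for short homologous sequences (SHS, exact repeats
   ≥ 4 bp on both sides of the breakpoint) and for conservation in another
   species' transcript set, using a seed-and-extend local aligner with the
   > 90 % coverage / > 90 % identity acceptance rule.
6. **Enumerates candidate pairs**: same-strand gene pairs < 10 kb apart
   (the raw material for read-through), with second-to-last/second-exon
   validation regions, and parent-distance statistics.

A deterministic simulator (`conjoinscan simulate`) generates complete toy
scenes — genome, annotation, alignments — with planted CGs of every
splicing/ORF/NMD/SHS class, labelled negatives, and a truth table, so every
stage is testable without any download.

## Worked example

```bash
conjoinscan simulate --seed 5 --out-dir scene/
conjoinscan all --genes scene/genes.gtf --alignments scene/alignments.bed12 \
    --genome scene/genome.fa --out combined.tsv
```

prints

```
scene: 220 genes, 100 transcripts -> scene/
...
50 CG groups (20 calls rejected); 92 candidate pairs < 10000 bp
```

i.e. of the 100 simulated transcripts, 50 survive detection and curation —
exactly the 50 planted CGs; the 20 detectable negatives (unspliced ESTs and
paralog mimics) are rejected with named reasons, the remaining negatives
never produce a call — and 92 same-strand gene pairs in the collapsed
annotation lie under 10 kb apart.
`combined.tsv` holds one row per CG group with every classification; its
`#` header lines echo all thresholds used. Each stage is also available
separately (`detect`, `classify`, `orf`, `junction`, `pairs`) and as
library functions (`conjoinscan.detect_conjoined`, `orf_report`, ...).

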