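"""The Conjoin detection step.

A conjoined gene (CG) call is a spliced transcript whose exon blocks overlap
exons of two or more distinct parent genes lying on the same chromosome and
strand. Detection is purely positional; curation then removes the classic
false-positive classes (short alignments, unspliced ESTs, paralogous
mis-alignments), and naming variants of a single locus are collapsed first
so they can never masquerade as two parents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .align import best_local_alignment
from .models import (
    AnnotationSet,
    GeneModel,
    GenomeSequence,
    Interval,
    TranscriptAlignment,
    ValidationError,
    merge_intervals,
    overlap_bp,
)


@dataclass
class DetectionParams:
    """Thresholds for detection and curation.

    min_exon_overlap_bp
        Minimum exon/block intersection for a gene to count as a parent
        ("at least part of one exon"; 1 bp by definition, configurable
        because single-base overlaps are alignment-noise sensitive).
    min_aligned_length_bp
        Shorter alignments are rejected as short/poor-quality ESTs.
    min_intron_bp / require_spliced
        A call must contain at least one gap this long to count as spliced.
    paralog_identity / paralog_min_len_bp / enable_paralog_filter
        Two parents whose exonic sequences locally align at or above this
        identity over at least this length are treated as one duplicated
        gene family member mis-aligned, not a true CG.
    """

    min_exon_overlap_bp: int = 1
    min_aligned_length_bp: int = 200
    min_intron_bp: int = 40
    require_spliced: bool = True
    paralog_identity: float = 0.90
    paralog_min_len_bp: int = 100
    enable_paralog_filter: bool = True

    def __post_init__(self) -> None:
        for name in ("min_exon_overlap_bp", "min_aligned_length_bp", "min_intron_bp",
                     "paralog_min_len_bp"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 < self.paralog_identity <= 1:
            raise ValidationError("paralog_identity must be in (0, 1]")


@dataclass
class ConjoinedGeneCall:
    """One transcript linked to >= 2 ordered parent genes."""

    transcript: TranscriptAlignment
    parents: list[GeneModel]  # 5' -> 3' in transcription direction
    overlap_bp: dict[str, int]  # gene_id -> exonic overlap with the transcript
    bypassed_gene_ids: list[str] = field(default_factory=list)
    flags: set = field(default_factory=set)

    @property
    def parent_tuple(self) -> tuple[str, ...]:
        return tuple(g.gene_id for g in self.parents)

    @property
    def cg_id(self) -> str:
        return f"{self.transcript.transcript_id}|{'--'.join(self.parent_tuple)}"


@dataclass
class CGGroup:
    """All curated calls sharing one ordered parent tuple."""

    parent_tuple: tuple[str, ...]
    calls: list[ConjoinedGeneCall]

    @property
    def supporting_transcript_ids(self) -> list[str]:
        return [c.transcript.transcript_id for c in self.calls]

    @property
    def multi_support(self) -> bool:
        return len(self.calls) >= 2

    @property
    def parents(self) -> list[GeneModel]:
        return self.calls[0].parents


def collapse_loci(annotation: AnnotationSet) -> AnnotationSet:
    """Merge same-strand, exon-overlapping gene records into single loci.

    Gene records whose exons overlap by >= 1 bp on the same strand are naming
    variants (or splice variants) of one locus; treating them as distinct
    parents would fabricate CG calls. The representative id is the
    lexicographically smallest member id; all member symbols are retained
    joined with '/'.
    """
    parent_of: dict[str, str] = {g.gene_id: g.gene_id for g in annotation}

    def find(x: str) -> str:
        while parent_of[x] != x:
            parent_of[x] = parent_of[parent_of[x]]
            x = parent_of[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent_of[max(ra, rb)] = min(ra, rb)

    for gene in annotation:
        for s, e in gene.exons:
            for other in annotation.query(gene.chrom, gene.strand, s, e):
                if other.gene_id != gene.gene_id:
                    union(gene.gene_id, other.gene_id)

    clusters: dict[str, list[GeneModel]] = {}
    for gene in annotation:
        clusters.setdefault(find(gene.gene_id), []).append(gene)

    merged = []
    for rep, members in clusters.items():
        members.sort(key=lambda g: g.gene_id)
        if len(members) == 1:
            merged.append(members[0])
            continue
        exons = merge_intervals(iv for g in members for iv in g.exons)
        cds_ivs = [c for g in members if g.cds for c in g.cds]
        cds = None
        if cds_ivs:
            phase_by_start = {s: p for s, e, p in sorted(cds_ivs)}
            cds = [
                (s, e, phase_by_start.get(s, 0))
                for s, e in merge_intervals([(s, e) for s, e, _ in cds_ivs])
            ]
        symbol = "/".join(g.symbol for g in members)
        first = members[0]
        merged.append(GeneModel(rep, symbol, first.chrom, first.strand, exons, cds))
    return AnnotationSet(merged)


def _exon_overlap(transcript: TranscriptAlignment, gene: GeneModel) -> int:
    total = 0
    for b in transcript.blocks:
        for x in gene.exons:
            if x[0] >= b[1]:
                break
            total += overlap_bp(b, x)
    return total


def detect_conjoined(
    alignments: list[TranscriptAlignment],
    annotation: AnnotationSet,
    params: Optional[DetectionParams] = None,
    collapse: bool = True,
) -> list[ConjoinedGeneCall]:
    """Identify transcripts whose blocks overlap exons of >= 2 distinct loci.

    Parents are ordered 5'->3' in transcription direction. Genes whose span
    lies inside the transcript span but contribute no exonic overlap are
    recorded as bypassed (read-through over internally located genes) and do
    not break the call.
    """
    params = params or DetectionParams()
    ann = collapse_loci(annotation) if collapse else annotation
    calls = []
    for tx in alignments:
        candidates: dict[str, int] = {}
        for s, e in tx.blocks:
            for gene in ann.query(tx.chrom, tx.strand, s, e):
                if gene.gene_id not in candidates:
                    candidates[gene.gene_id] = _exon_overlap(tx, gene)
        parents = [
            ann.get(gid)
            for gid, ov in candidates.items()
            if ov >= params.min_exon_overlap_bp
        ]
        if len(parents) < 2:
            continue
        parents.sort(key=lambda g: g.span[0], reverse=(tx.strand == "-"))
        bypassed = _bypassed_genes(ann, tx, {g.gene_id for g in parents})
        calls.append(
            ConjoinedGeneCall(
                transcript=tx,
                parents=parents,
                overlap_bp={g.gene_id: candidates[g.gene_id] for g in parents},
                bypassed_gene_ids=bypassed,
            )
        )
    return calls


def _bypassed_genes(
    ann: AnnotationSet, tx: TranscriptAlignment, parent_ids: set
) -> list[str]:
    lo, hi = tx.span
    out = []
    for gene in ann.query(tx.chrom, tx.strand, lo, hi):
        if gene.gene_id in parent_ids:
            continue
        gs, ge = gene.span
        if lo <= gs and ge <= hi:
            out.append(gene.gene_id)
    return sorted(out)


def curate(
    calls: list[ConjoinedGeneCall],
    genome: Optional[GenomeSequence] = None,
    params: Optional[DetectionParams] = None,
) -> tuple[list[ConjoinedGeneCall], list[tuple[ConjoinedGeneCall, str]]]:
    """Apply the automated stand-ins for the manual curation filters.

    Returns (kept, rejected-with-reason). Rejection reasons: short_alignment,
    unspliced, paralog_suspect.
    """
    params = params or DetectionParams()
    if params.enable_paralog_filter and genome is None:
        raise ValidationError(
            "paralog filter requires a genome; pass genome= or disable it"
        )
    kept, rejected = [], []
    for call in calls:
        reason = None
        tx = call.transcript
        if tx.aligned_length < params.min_aligned_length_bp:
            reason = "short_alignment"
        elif params.require_spliced and not any(
            e - s >= params.min_intron_bp for s, e in tx.introns
        ):
            reason = "unspliced"
        elif params.enable_paralog_filter and genome is not None:
            if _paralogous_parents(call, genome, params):
                reason = "paralog_suspect"
        if reason is None:
            kept.append(call)
        else:
            call.flags.add(reason)
            rejected.append((call, reason))
    return kept, rejected


def _paralogous_parents(
    call: ConjoinedGeneCall, genome: GenomeSequence, params: DetectionParams
) -> bool:
    seqs = [p.exonic_sequence(genome) for p in call.parents]
    for i in range(len(seqs) - 1):
        for j in range(i + 1, len(seqs)):
            hit = best_local_alignment(seqs[i], seqs[j])
            if hit is not None and hit.has_identity_window(
                params.paralog_min_len_bp, params.paralog_identity
            ):
                return True
    return False


def group_calls(calls: list[ConjoinedGeneCall]) -> list[CGGroup]:
    """Group curated calls by ordered parent tuple (one group = one CG)."""
    groups: dict[tuple[str, ...], list[ConjoinedGeneCall]] = {}
    for call in calls:
        groups.setdefault(call.parent_tuple, []).append(call)
    return [CGGroup(t, cs) for t, cs in groups.items()]


def detect_alternative_splicing(group: CGGroup) -> Optional[bool]:
    """True iff >= 2 supporting transcripts have distinct intron chains.

    Returns None (not applicable) for single-transcript groups; terminal
    block-end differences alone do not count as alternative splicing.
    """
    if len(group.calls) < 2:
        return None
    chains = {c.transcript.intron_chain for c in group.calls}
    return len(chains) > 1
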