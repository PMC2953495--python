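"""ORF prediction, reading-frame comparison with parent CDSs, and NMD.

The CG transcript's ORF is the annotated CDS when one exists, else the
longest ATG-initiated open reading frame of the spliced sequence. Frame
comparison works on genomic coordinates: a parent's frame is conserved when
every genomic position coding in both the CG ORF and the parent CDS carries
the same codon phase. Product classes follow from the per-parent verdicts:
conserved with every parent -> chimeric protein; with exactly one ->
similar to that parent (5' or 3'); otherwise novel or non-coding.

NMD candidacy uses the standard 50-nt rule: a stop codon ending >= 50 nt
upstream of the last exon-exon junction marks the transcript for decay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .detect import ConjoinedGeneCall
from .models import GeneModel, GenomeSequence, Interval, ValidationError

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class Orf:
    """An open reading frame in transcript coordinates (0-based half-open).

    ``end`` includes the stop codon when ``complete``; length is always a
    multiple of three.
    """

    start: int
    end: int
    complete: bool  # ends at a stop codon (vs running off the transcript)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ParentFrameStatus:
    gene_id: str
    frame_status: str  # conserved | different | no_overlap
    shared_coding_bp: int


@dataclass
class OrfReport:
    cg_id: str
    orf: Optional[Orf]
    source: str  # annotated_cds | longest_atg_orf | none
    per_parent: list[ParentFrameStatus]
    product_class: str  # chimeric | similar_to_5p | similar_to_3p | novel_or_noncoding
    nmd_candidate: Optional[bool]
    ptc_to_last_junction_nt: Optional[int]


def predict_orf(seq: str, annotated_cds: Optional[tuple[int, int]] = None) -> Optional[Orf]:
    """Longest ATG-initiated ORF of a spliced transcript sequence.

    Ties are broken toward the 5'-most start. An ORF with no in-frame stop
    runs to the transcript end (truncated to a codon multiple) and is
    flagged incomplete. Returns None when no ATG exists.
    """
    seq = seq.upper()
    if set(seq) - set("ACGTN"):
        raise ValidationError("transcript sequence contains non-ACGTN characters")
    if annotated_cds is not None:
        start, end = annotated_cds
        return Orf(start, end, complete=seq[end - 3 : end] in STOP_CODONS)
    best: Optional[Orf] = None
    n = len(seq)
    for start in _atg_positions(seq):
        end = None
        for p in range(start, n - 2, 3):
            if seq[p : p + 3] in STOP_CODONS:
                end = p + 3
                break
        if end is None:
            orf = Orf(start, start + (n - start) // 3 * 3, complete=False)
        else:
            orf = Orf(start, end, complete=True)
        if orf.length >= 3 and (best is None or orf.length > best.length):
            best = orf
    return best


def _atg_positions(seq: str):
    pos = seq.find("ATG")
    while pos != -1:
        yield pos
        pos = seq.find("ATG", pos + 1)


# ---------------------------------------------------------------------------
# Transcript <-> genome coordinate maps


def transcript_to_genomic(blocks_tx: list[Interval], strand: str, tx_pos: int) -> int:
    """Genomic coordinate of a transcript position (blocks in tx order)."""
    off = tx_pos
    for s, e in blocks_tx:
        n = e - s
        if off < n:
            return s + off if strand == "+" else e - 1 - off
        off -= n
    raise ValueError("transcript position beyond spliced length")


def orf_genomic_phase_map(
    orf: Orf, blocks_tx: list[Interval], strand: str
) -> dict[int, int]:
    """Map genomic position -> codon phase (0/1/2) for every ORF base."""
    out = {}
    tx_pos = orf.start
    for i in range(orf.length):
        g = transcript_to_genomic(blocks_tx, strand, tx_pos + i)
        out[g] = i % 3
    return out


def parent_cds_phase_map(gene: GeneModel) -> dict[int, int]:
    """Genomic position -> codon phase for an annotated parent CDS.

    Phase here is the offset of the position within its codon, counted in
    transcription direction from the (phase-adjusted) CDS start.
    """
    if not gene.cds:
        return {}
    segs = gene.cds if gene.strand == "+" else gene.cds[::-1]
    # GTF phase = bases to remove from the segment start to reach a codon start
    first_phase = segs[0][2]
    pos_iter = (
        g
        for s, e, _ in segs
        for g in (range(s, e) if gene.strand == "+" else range(e - 1, s - 1, -1))
    )
    return {g: (k - first_phase) % 3 for k, g in enumerate(pos_iter)}


def classify_frames(
    call: ConjoinedGeneCall,
    orf: Optional[Orf],
    genome: GenomeSequence,
    min_shared_bp: int = 30,
) -> tuple[list[ParentFrameStatus], str]:
    """Per-parent frame conservation and the resulting product class."""
    if orf is None:
        statuses = [
            ParentFrameStatus(p.gene_id, "no_overlap", 0) for p in call.parents
        ]
        return statuses, "novel_or_noncoding"
    tx = call.transcript
    orf_map = orf_genomic_phase_map(orf, tx.blocks_tx, tx.strand)
    statuses = []
    for parent in call.parents:
        cds_map = parent_cds_phase_map(parent)
        shared = [g for g in orf_map if g in cds_map]
        if len(shared) < min_shared_bp:
            statuses.append(ParentFrameStatus(parent.gene_id, "no_overlap", len(shared)))
            continue
        agree = all(orf_map[g] == cds_map[g] for g in shared)
        statuses.append(
            ParentFrameStatus(
                parent.gene_id, "conserved" if agree else "different", len(shared)
            )
        )
    with_cds = [s for s, p in zip(statuses, call.parents) if p.cds]
    conserved = [s for s in statuses if s.frame_status == "conserved"]
    if with_cds and all(s.frame_status == "conserved" for s in with_cds):
        product = "chimeric"
    elif len(conserved) == 1:
        which = next(
            i for i, s in enumerate(statuses) if s.frame_status == "conserved"
        )
        product = "similar_to_5p" if which == 0 else "similar_to_3p"
    else:
        product = "novel_or_noncoding"
    return statuses, product


def detect_nmd(
    orf: Optional[Orf],
    blocks_tx: list[Interval],
    nmd_distance: int = 50,
) -> tuple[Optional[bool], Optional[int]]:
    """50-nt rule: stop >= nmd_distance upstream of the last junction.

    Returns (candidate, distance). Not applicable (None, None) for missing
    or incomplete ORFs; single-exon transcripts are never candidates.
    """
    if orf is None or not orf.complete:
        return None, None
    if len(blocks_tx) < 2:
        return False, None
    last_junction = sum(e - s for s, e in blocks_tx[:-1])
    distance = last_junction - orf.end
    return distance >= nmd_distance, distance


def orf_report(
    call: ConjoinedGeneCall,
    genome: GenomeSequence,
    annotated_cds: Optional[tuple[int, int]] = None,
    min_shared_bp: int = 30,
    nmd_distance: int = 50,
) -> OrfReport:
    seq = call.transcript.spliced_sequence(genome)
    orf = predict_orf(seq, annotated_cds)
    source = (
        "annotated_cds"
        if annotated_cds is not None
        else ("longest_atg_orf" if orf else "none")
    )
    statuses, product = classify_frames(call, orf, genome, min_shared_bp)
    nmd, dist = detect_nmd(orf, call.transcript.blocks_tx, nmd_distance)
    return OrfReport(
        cg_id=call.cg_id,
        orf=orf,
        source=source,
        per_parent=statuses,
        product_class=product,
        nmd_candidate=nmd,
        ptc_to_last_junction_nt=dist,
    )
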