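"""Junction exons, short homologous sequences (SHS), and conservation search.

The junction exon of a CG is the transcript region containing sequence from
both parents: either one block crossing both parents' exons (single_exon
mode) or the spliced stretch from the last block overlapping the upstream
parent through the first block overlapping the downstream parent
(spanning_region mode), novel exons in between included. The breakpoint
marks where upstream-parent-derived sequence ends within that spliced
sequence.

SHS detection looks for exact repeats (>= 4 bp by default) present in
windows on both sides of the breakpoint — the footprint expected under the
transcriptional-slippage model. Conservation search aligns the junction
sequence against another species' transcript set and reports targets
covering > 90% of the junction at > 90% identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .align import seeded_search
from .detect import ConjoinedGeneCall
from .models import GenomeSequence, Interval, ValidationError, overlap_bp, revcomp

log = logging.getLogger(__name__)


@dataclass
class JunctionExon:
    cg_id: str
    mode: str  # single_exon | spanning_region
    genomic_span: Interval
    spliced_seq: str
    breakpoint: int  # offset in spliced_seq where 5'-parent-derived sequence ends
    breakpoint_ambiguous: bool = False


@dataclass
class SHSHit:
    length: int
    sequence: str
    offset_5p: int  # start offset within the 5'-side window
    offset_3p: int  # start offset within the 3'-side window


@dataclass
class ConservationHit:
    target_id: str
    coverage: float
    identity: float
    score: int
    strand: str


@dataclass
class ConservationParams:
    seed_k: int = 11
    min_score: int = 30
    min_coverage: float = 0.90
    min_identity: float = 0.90


def extract_junction_exon(call: ConjoinedGeneCall, genome: GenomeSequence) -> JunctionExon:
    """Junction exon of the first adjacent parent pair of a call."""
    up, down = call.parents[0], call.parents[1]
    tx = call.transcript
    blocks_tx = tx.blocks_tx

    def overlaps(block, gene):
        return any(overlap_bp(block, x) > 0 for x in gene.exons)

    last_up = max(
        (i for i, b in enumerate(blocks_tx) if overlaps(b, up)), default=None
    )
    first_down = min(
        (i for i, b in enumerate(blocks_tx) if overlaps(b, down)), default=None
    )
    if last_up is None or first_down is None:
        raise ValidationError(f"{call.cg_id}: a parent has no overlapping block")

    if last_up == first_down:
        block = blocks_tx[last_up]
        seq = genome.spliced(tx.chrom, [block], tx.strand)
        bp, ambiguous = _single_block_breakpoint(block, up, down, tx.strand)
        return JunctionExon(call.cg_id, "single_exon", block, seq, bp, ambiguous)

    if last_up > first_down:
        raise ValidationError(f"{call.cg_id}: parent overlaps out of order")
    region = blocks_tx[last_up : first_down + 1]
    genomic = sorted(region)
    seq = genome.spliced(tx.chrom, genomic, tx.strand)
    breakpoint = region[0][1] - region[0][0]  # full contribution of the 5'-parent block
    span = (genomic[0][0], genomic[-1][1])
    return JunctionExon(call.cg_id, "spanning_region", span, seq, breakpoint)


def _single_block_breakpoint(block, up, down, strand) -> tuple[int, bool]:
    """Transcript-direction offset where the upstream parent's exonic overlap
    ends within a block shared by both parents; midpoint rule on ambiguity."""
    s, e = block
    up_ov = [(max(s, xs), min(e, xe)) for xs, xe in up.exons if overlap_bp(block, (xs, xe))]
    down_ov = [(max(s, xs), min(e, xe)) for xs, xe in down.exons if overlap_bp(block, (xs, xe))]
    if strand == "+":
        up_end = max(oe for _, oe in up_ov)
        down_start = min(os_ for os_, _ in down_ov)
        if up_end <= down_start:
            gap_mid = (up_end + down_start) // 2
            ambiguous = up_end < down_start
            cut = up_end if not ambiguous else gap_mid
            return cut - s, ambiguous
        return up_end - s, False
    up_end = min(os_ for os_, _ in up_ov)  # transcription-direction end = genomic start
    down_start = max(oe for _, oe in down_ov)
    if down_start <= up_end:
        ambiguous = down_start < up_end
        cut = up_end if not ambiguous else (up_end + down_start + 1) // 2
        return e - cut, ambiguous
    return e - up_end, False


def detect_shs(
    junction: JunctionExon, window: int = 20, min_len: int = 4
) -> list[SHSHit]:
    """Maximal common substrings (>= min_len) of the two breakpoint windows.

    The 5'-side window is the ``window`` bases ending at the breakpoint, the
    3'-side window the ``window`` bases starting there; windows are truncated
    at the sequence ends. Hits are sorted by length descending, then by
    5'-side offset.
    """
    seq, bp = junction.spliced_seq, junction.breakpoint
    if bp < window or len(seq) - bp < window:
        log.warning("%s: SHS window truncated at sequence bounds", junction.cg_id)
    w5 = seq[max(0, bp - window) : bp]
    w3 = seq[bp : bp + window]
    return find_common_substrings(w5, w3, min_len)


def find_common_substrings(a: str, b: str, min_len: int) -> list[SHSHit]:
    """All maximal common substrings of a and b with length >= min_len."""
    common: dict[str, tuple[int, int]] = {}
    for length in range(min(len(a), len(b)), min_len - 1, -1):
        for i in range(len(a) - length + 1):
            sub = a[i : i + length]
            j = b.find(sub)
            if j != -1 and sub not in common:
                if not any(sub in longer for longer in common):
                    common[sub] = (i, j)
    hits = [SHSHit(len(s), s, i, j) for s, (i, j) in common.items()]
    hits.sort(key=lambda h: (-h.length, h.offset_5p))
    return hits


def search_conservation(
    junction: JunctionExon,
    targets: dict[str, str],
    params: Optional[ConservationParams] = None,
) -> list[ConservationHit]:
    """Seed-and-extend search of the junction sequence in a transcript set.

    A target is reported iff its best local alignment covers > min_coverage
    of the junction sequence at > min_identity over the aligned columns and
    scores >= min_score; one best hit per target, both strands searched.
    """
    params = params or ConservationParams()
    query = junction.spliced_seq
    if len(query) < params.seed_k:
        raise ValidationError(
            f"junction sequence shorter than seed k={params.seed_k}; lower seed_k"
        )
    if not targets:
        raise ValidationError("empty target set")
    hits = []
    for tid, tseq in targets.items():
        aln = seeded_search(query, tseq, k=params.seed_k)
        if aln is None or aln.score < params.min_score:
            continue
        coverage = aln.coverage_of(len(query))
        if coverage > params.min_coverage and aln.identity > params.min_identity:
            hits.append(
                ConservationHit(tid, coverage, aln.identity, aln.score, aln.strand)
            )
    hits.sort(key=lambda h: -h.score)
    return hits
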