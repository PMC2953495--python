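"""Splicing-pattern classification for conjoined-gene transcripts.

Three questions per call: does a single new intron bridge the two parents
(spanning the upstream gene's terminal exon, the intergenic region and the
downstream gene's initial exon); which transcript blocks are novel exons and
where did they come from; and is each splice site conserved from a parent
gene and canonical (GT-AG on the transcribed strand)?
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .detect import ConjoinedGeneCall
from .models import (
    AnnotationSet,
    GeneModel,
    GenomeSequence,
    Interval,
    ValidationError,
    overlap_bp,
)

NovelOrigin = str  # intergenic | intronic | flanking_upstream | flanking_downstream | mixed


@dataclass
class SpliceSiteRecord:
    """Per-intron classification (intron in genomic coordinates)."""

    intron: Interval
    donor_status: str  # conserved | new
    acceptor_status: str
    canonical: bool


@dataclass
class SplicingReport:
    cg_id: str
    junction_intron_pattern: Optional[bool]
    per_pair_pattern: list[bool]
    novel_exons: list[tuple[Interval, NovelOrigin]]
    splice_sites: list[SpliceSiteRecord]

    @property
    def any_new_site(self) -> bool:
        return any(
            s.donor_status == "new" or s.acceptor_status == "new"
            for s in self.splice_sites
        )

    @property
    def n_new_sites(self) -> int:
        """Site-level count of new boundaries (each intron has two sites)."""
        return sum(
            (s.donor_status == "new") + (s.acceptor_status == "new")
            for s in self.splice_sites
        )

    @property
    def n_new_introns(self) -> int:
        """Intron-level count: introns with at least one new boundary."""
        return sum(
            s.donor_status == "new" or s.acceptor_status == "new"
            for s in self.splice_sites
        )


def _pair_bridge_region(up: GeneModel, down: GeneModel) -> Interval:
    """Genomic interval from the upstream parent's terminal exon start to the
    downstream parent's initial exon end (orientation-normalised)."""
    up_terminal = up.exons_tx[-1]
    down_initial = down.exons_tx[0]
    return (
        min(up_terminal[0], down_initial[0]),
        max(up_terminal[1], down_initial[1]),
    )


def classify_junction_pattern(call: ConjoinedGeneCall) -> Optional[bool]:
    """True iff, for every adjacent parent pair, one transcript intron fully
    contains [upstream terminal exon ... downstream initial exon]."""
    introns = call.transcript.introns
    per_pair = []
    for up, down in zip(call.parents, call.parents[1:]):
        lo, hi = _pair_bridge_region(up, down)
        per_pair.append(any(s <= lo and hi <= e for s, e in introns))
    return all(per_pair) if per_pair else None


def find_novel_exons(
    call: ConjoinedGeneCall, annotation: Optional[AnnotationSet] = None
) -> list[tuple[Interval, NovelOrigin]]:
    """Blocks intersecting no parent exon, labelled by their genomic origin.

    Origins are judged against the call's parents: between two consecutive
    parents' spans -> intergenic; inside a parent intron -> intronic; outside
    the joint span -> flanking on the respective transcription side; anything
    straddling categories -> mixed.
    """
    parents = call.parents
    joint_lo = min(p.span[0] for p in parents)
    joint_hi = max(p.span[1] for p in parents)
    strand = call.transcript.strand
    # genomic-order parents for gap computation
    genomic = sorted(parents, key=lambda g: g.span[0])
    gaps = [
        (genomic[i].span[1], genomic[i + 1].span[0])
        for i in range(len(genomic) - 1)
        if genomic[i].span[1] <= genomic[i + 1].span[0]
    ]
    out = []
    for block in call.transcript.blocks:
        if any(overlap_bp(block, x) > 0 for p in parents for x in p.exons):
            continue
        origin = _origin_of(block, parents, gaps, joint_lo, joint_hi, strand)
        out.append((block, origin))
    return out


def _origin_of(block, parents, gaps, joint_lo, joint_hi, strand) -> NovelOrigin:
    s, e = block
    if any(gs <= s and e <= ge for gs, ge in gaps):
        return "intergenic"
    for p in parents:
        if any(is_ <= s and e <= ie for is_, ie in p.introns):
            return "intronic"
    if e <= joint_lo:
        return "flanking_upstream" if strand == "+" else "flanking_downstream"
    if s >= joint_hi:
        return "flanking_downstream" if strand == "+" else "flanking_upstream"
    return "mixed"


def classify_splice_sites(
    call: ConjoinedGeneCall, genome: GenomeSequence
) -> list[SpliceSiteRecord]:
    """Per-intron donor/acceptor conservation and GT-AG canonicality.

    A boundary is conserved iff it coincides with the matching boundary of
    any annotated intron of any parent (donor with donor, acceptor with
    acceptor, strand-aware). Dinucleotides containing N are non-canonical.
    """
    tx = call.transcript
    strand = tx.strand
    donor_coords: set[int] = set()
    acceptor_coords: set[int] = set()
    for p in call.parents:
        for is_, ie in p.introns:
            if strand == "+":
                donor_coords.add(is_)
                acceptor_coords.add(ie)
            else:
                donor_coords.add(ie)
                acceptor_coords.add(is_)
    records = []
    for s, e in tx.introns:
        if strand == "+":
            donor_pos, acceptor_pos = s, e
            donor_nt = genome.sequence(tx.chrom, s, min(s + 2, e))
            acceptor_nt = genome.sequence(tx.chrom, max(e - 2, s), e)
        else:
            donor_pos, acceptor_pos = e, s
            donor_nt = genome.sequence(tx.chrom, max(e - 2, s), e)
            acceptor_nt = genome.sequence(tx.chrom, s, min(s + 2, e))
        if e - s < 4:
            canonical = False
        elif strand == "+":
            canonical = donor_nt == "GT" and acceptor_nt == "AG"
        else:
            # transcribed-strand GT..AG reads AC..CT on the plus strand,
            # i.e. plus-strand genomic CT(intron)AC
            canonical = donor_nt == "AC" and acceptor_nt == "CT"
        records.append(
            SpliceSiteRecord(
                intron=(s, e),
                donor_status="conserved" if donor_pos in donor_coords else "new",
                acceptor_status="conserved" if acceptor_pos in acceptor_coords else "new",
                canonical=canonical,
            )
        )
    return records


def splicing_report(
    call: ConjoinedGeneCall,
    genome: GenomeSequence,
    annotation: Optional[AnnotationSet] = None,
) -> SplicingReport:
    return SplicingReport(
        cg_id=call.cg_id,
        junction_intron_pattern=classify_junction_pattern(call),
        per_pair_pattern=[
            any(
                s <= lo and hi <= e
                for s, e in call.transcript.introns
                for lo, hi in [_pair_bridge_region(up, down)]
            )
            for up, down in zip(call.parents, call.parents[1:])
        ],
        novel_exons=find_novel_exons(call, annotation),
        splice_sites=classify_splice_sites(call, genome),
    )
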