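"""Candidate CG-forming gene pairs and parent-distance statistics.

Genes lying close together on the same strand are the raw material for
read-through transcription; enumerating same-strand pairs under a gap
threshold (10 kb by default) yields the candidate set, and the
second-to-last exon of the upstream gene plus the second exon of the
downstream gene are the natural validation targets, since the terminal and
initial exons are the ones most CG transcripts splice out.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Optional

from .detect import CGGroup
from .models import AnnotationSet, GeneModel, Interval, ValidationError


@dataclass
class CandidatePair:
    upstream_gene: GeneModel  # transcription order
    downstream_gene: GeneModel
    gap_bp: int
    chrom: str
    strand: str


@dataclass
class PairEnumeration:
    pairs: list[CandidatePair]
    n_unique_genes: int


def _ordered_gap(a: GeneModel, b: GeneModel) -> Optional[tuple[GeneModel, GeneModel, int]]:
    """(upstream, downstream, gap) in transcription order, None if overlapping."""
    left, right = (a, b) if a.span[0] <= b.span[0] else (b, a)
    gap = right.span[0] - left.span[1]
    if gap < 0:
        return None
    if a.strand == "+":
        return left, right, gap
    return right, left, gap


def enumerate_pairs(
    annotation: AnnotationSet,
    max_gap: int = 10_000,
    adjacent_only: bool = False,
) -> PairEnumeration:
    """All same-chrom, same-strand gene pairs with 0 <= gap < max_gap.

    Overlapping loci are excluded (they belong to locus collapse, not
    pairing). With ``adjacent_only`` a pair is kept only when no third gene
    span starts inside the gap — the conservative screen for designing
    validation experiments.
    """
    by_key: dict[tuple[str, str], list[GeneModel]] = {}
    for gene in annotation:
        by_key.setdefault((gene.chrom, gene.strand), []).append(gene)
    pairs: list[CandidatePair] = []
    for (chrom, strand), genes in sorted(by_key.items()):
        genes.sort(key=lambda g: g.span[0])
        for i, left in enumerate(genes):
            for right in genes[i + 1 :]:
                if right.span[0] - left.span[1] >= max_gap:
                    break
                ordered = _ordered_gap(left, right)
                if ordered is None:
                    continue
                up, down, gap = ordered
                if gap >= max_gap:
                    continue
                if adjacent_only and any(
                    left.span[1] <= g.span[0] < right.span[0]
                    for g in genes
                    if g is not left and g is not right
                ):
                    continue
                pairs.append(CandidatePair(up, down, gap, chrom, strand))
    unique = {p.upstream_gene.gene_id for p in pairs} | {
        p.downstream_gene.gene_id for p in pairs
    }
    return PairEnumeration(pairs, len(unique))


@dataclass
class DistanceStats:
    median: float
    q1: float
    q3: float
    outliers: list[tuple[str, str, int]]  # (upstream, downstream, gap) > threshold


def parent_distance_stats(
    groups: list[CGGroup], outlier_threshold: int = 100_000
) -> DistanceStats:
    """Distribution of intergenic gaps between adjacent CG parents."""
    if not groups:
        raise ValidationError("no CG groups to summarise")
    gaps = []
    named = []
    for grp in groups:
        parents = grp.parents
        for up, down in zip(parents, parents[1:]):
            ordered = _ordered_gap(up, down)
            gap = ordered[2] if ordered else 0
            gaps.append(gap)
            named.append((up.gene_id, down.gene_id, gap))
    qs = statistics.quantiles(gaps, n=4, method="inclusive") if len(gaps) > 1 else [gaps[0]] * 3
    return DistanceStats(
        median=statistics.median(gaps),
        q1=qs[0],
        q3=qs[2],
        outliers=[t for t in named if t[2] > outlier_threshold],
    )


def select_validation_regions(
    pair: CandidatePair,
) -> tuple[Optional[Interval], Optional[Interval], list[str]]:
    """Second-to-last exon of the upstream gene and second exon of the
    downstream gene, in transcription order.

    Genes with fewer than two exons yield None for their region; their names
    are returned in the not-applicable list.
    """
    not_applicable = []
    up_exons = pair.upstream_gene.exons_tx
    down_exons = pair.downstream_gene.exons_tx
    upstream_region = up_exons[-2] if len(up_exons) >= 2 else None
    downstream_region = down_exons[1] if len(down_exons) >= 2 else None
    if upstream_region is None:
        not_applicable.append(pair.upstream_gene.gene_id)
    if downstream_region is None:
        not_applicable.append(pair.downstream_gene.gene_id)
    return upstream_region, downstream_region, not_applicable
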