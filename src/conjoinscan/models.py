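"""Core domain types shared by every stage of the pipeline.

All coordinates are 0-based half-open genomic intervals; conversion to and
from 1-based inclusive GTF happens only at file boundaries (:mod:`.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from intervaltree import IntervalTree

Interval = tuple[int, int]

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(COMPLEMENT)[::-1]


class ValidationError(ValueError):
    """Raised when an input record violates a structural invariant."""


def _check_intervals(ivs: Sequence[Interval], what: str) -> None:
    if not ivs:
        raise ValidationError(f"{what}: at least one interval required")
    prev_end = None
    for start, end in ivs:
        if end <= start:
            raise ValidationError(f"{what}: empty/inverted interval ({start}, {end})")
        if prev_end is not None and start < prev_end:
            raise ValidationError(f"{what}: intervals overlap or are unsorted at {start}")
        prev_end = end


class GenomeSequence:
    """Random-access uppercase DNA, one string per chromosome."""

    def __init__(self, chroms: dict[str, str]):
        self._chroms = {name: seq.upper() for name, seq in chroms.items()}
        bad = set("".join(self._chroms.values())) - set("ACGTN")
        if bad:
            raise ValidationError(f"genome contains non-ACGTN characters: {sorted(bad)}")

    @property
    def chrom_names(self) -> list[str]:
        return list(self._chroms)

    def chrom_length(self, chrom: str) -> int:
        return len(self._chroms[chrom])

    def sequence(self, chrom: str, start: int, end: int) -> str:
        n = self.chrom_length(chrom)
        if not (0 <= start <= end <= n):
            raise ValidationError(
                f"interval [{start}, {end}) outside chromosome {chrom} of length {n}"
            )
        return self._chroms[chrom][start:end]

    def spliced(self, chrom: str, blocks: Sequence[Interval], strand: str) -> str:
        """Spliced transcription-direction sequence over an exon chain."""
        seq = "".join(self.sequence(chrom, s, e) for s, e in blocks)
        return seq if strand == "+" else revcomp(seq)


@dataclass
class GeneModel:
    """One annotated parent gene: merged exon chain plus optional CDS."""

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: Optional[list[tuple[int, int, int]]] = None  # (start, end, phase)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        self.exons = sorted(tuple(e) for e in self.exons)
        _check_intervals(self.exons, f"gene {self.gene_id} exons")
        if self.cds is not None:
            self.cds = sorted(tuple(c) for c in self.cds)
            _check_intervals([(s, e) for s, e, _ in self.cds], f"gene {self.gene_id} CDS")
            for s, e, _ in self.cds:
                if not any(xs <= s and e <= xe for xs, xe in self.exons):
                    raise ValidationError(
                        f"gene {self.gene_id}: CDS ({s}, {e}) not contained in an exon"
                    )

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def exons_tx(self) -> list[Interval]:
        """Exons in transcription order (5' -> 3')."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    @property
    def introns(self) -> list[Interval]:
        """Gaps between consecutive exons, genomic order."""
        return [
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        ]

    def exonic_sequence(self, genome: GenomeSequence) -> str:
        return genome.spliced(self.chrom, self.exons, self.strand)


@dataclass
class TranscriptAlignment:
    """A spliced mRNA/EST placed on the genome as ordered exon blocks."""

    transcript_id: str
    source: str  # "mRNA" | "EST"
    chrom: str
    strand: str
    blocks: list[Interval]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"transcript {self.transcript_id}: bad strand")
        self.blocks = sorted(tuple(b) for b in self.blocks)
        _check_intervals(self.blocks, f"transcript {self.transcript_id} blocks")

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def span(self) -> Interval:
        return (self.blocks[0][0], self.blocks[-1][1])

    @property
    def introns(self) -> list[Interval]:
        return [
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
        ]

    @property
    def blocks_tx(self) -> list[Interval]:
        return self.blocks if self.strand == "+" else self.blocks[::-1]

    @property
    def intron_chain(self) -> tuple[Interval, ...]:
        return tuple(self.introns)

    def spliced_sequence(self, genome: GenomeSequence) -> str:
        return genome.spliced(self.chrom, self.blocks, self.strand)


class AnnotationSet:
    """A collection of gene models with a per-chromosome/strand exon index."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._genes: dict[str, GeneModel] = {}
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for gene in genes:
            if gene.gene_id in self._genes:
                raise ValidationError(f"duplicate gene_id {gene.gene_id}")
            self._genes[gene.gene_id] = gene
            tree = self._trees.setdefault((gene.chrom, gene.strand), IntervalTree())
            for s, e in gene.exons:
                tree.addi(s, e, gene.gene_id)

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def get(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    @property
    def genes(self) -> list[GeneModel]:
        return list(self._genes.values())

    def query(self, chrom: str, strand: str, start: int, end: int) -> list[GeneModel]:
        """Genes with at least one exon intersecting [start, end) on (chrom, strand)."""
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return []
        ids = {iv.data for iv in tree.overlap(start, end)}
        return [self._genes[g] for g in sorted(ids)]


def merge_intervals(ivs: Iterable[Interval]) -> list[Interval]:
    """Union of intervals, merging touching/overlapping ones."""
    out: list[Interval] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def overlap_bp(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))
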