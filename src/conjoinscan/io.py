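"""Readers and writers for the standard formats.

GTF is 1-based inclusive on disk and converted to 0-based half-open here;
BED12 is already 0-based half-open and needs no shift. These conversions
happen in this module only.
"""

from __future__ import annotations

import json
import os
import tempfile
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

from .models import (
    AnnotationSet,
    GeneModel,
    GenomeSequence,
    Interval,
    TranscriptAlignment,
    ValidationError,
    merge_intervals,
)


class ParseError(ValueError):
    """Malformed input line; carries the offending line number."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta_genome(path: str) -> GenomeSequence:
    chroms = {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
    if not chroms:
        raise ParseError(f"{path}: no FASTA records")
    return GenomeSequence(chroms)


def read_fasta_sequences(path: str) -> dict[str, str]:
    """Plain id -> uppercase sequence map (e.g. other-species transcript sets)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF


def _gffutils_db(path: str):
    import gffutils

    try:
        return gffutils.create_db(
            path,
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils wraps line context in the message
        raise ParseError(f"{path}: GTF parse failed: {exc}") from exc


def read_gtf_genes(path: str, keep_cds: bool = True) -> AnnotationSet:
    """Build an :class:`AnnotationSet` from a GTF gene annotation.

    A gene's exon set is the union of its transcripts' exons with overlapping
    exons merged, i.e. each gene is treated as a single locus. CDS records,
    when present, are kept with their phase.
    """
    db = _gffutils_db(path)
    exons: dict[str, list[Interval]] = {}
    cds: dict[str, list[tuple[int, int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # gene_id -> (symbol, chrom, strand)
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        if "gene_id" not in feat.attributes:
            raise ParseError(f"{path}: {feat.featuretype} without gene_id attribute")
        gid = feat.attributes["gene_id"][0]
        symbol = feat.attributes.get("gene_name", [gid])[0]
        if feat.end < feat.start:
            raise ValidationError(f"{path}: end < start for gene {gid}")
        start, end = feat.start - 1, feat.end  # GTF 1-based inclusive -> half-open
        prev = meta.setdefault(gid, (symbol, feat.seqid, feat.strand))
        if prev[1:] != (feat.seqid, feat.strand):
            raise ValidationError(f"{path}: gene {gid} spans chrom/strand records")
        if feat.featuretype == "exon":
            exons.setdefault(gid, []).append((start, end))
        elif keep_cds:
            phase = int(feat.frame) if feat.frame not in (None, ".") else 0
            cds.setdefault(gid, []).append((start, end, phase))
    genes = []
    for gid, ivs in exons.items():
        symbol, chrom, strand = meta[gid]
        merged = merge_intervals(ivs)
        gene_cds = None
        if gid in cds:
            merged_cds = merge_intervals([(s, e) for s, e, _ in cds[gid]])
            phase_by_start = {s: p for s, e, p in sorted(cds[gid])}
            gene_cds = [(s, e, phase_by_start.get(s, 0)) for s, e in merged_cds]
        genes.append(GeneModel(gid, symbol, chrom, strand, merged, gene_cds))
    return AnnotationSet(genes)


def write_gtf_genes(annotation: AnnotationSet, path: str, source: str = "conjoinscan") -> None:
    """Write each gene back out as one GTF transcript (exon + CDS rows)."""
    with open(path, "w") as fh:
        for gene in annotation:
            attrs = (
                f'gene_id "{gene.gene_id}"; transcript_id "{gene.gene_id}.t1"; '
                f'gene_name "{gene.symbol}";'
            )
            for s, e in gene.exons:
                fh.write(
                    f"{gene.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t{attrs}\n"
                )
            for s, e, phase in gene.cds or []:
                fh.write(
                    f"{gene.chrom}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{gene.strand}\t{phase}\t{attrs}\n"
                )


def _read_gtf_alignments(path: str) -> list[TranscriptAlignment]:
    db = _gffutils_db(path)
    blocks: dict[str, list[Interval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features(featuretype="exon"):
        tid = feat.attributes["transcript_id"][0]
        source = feat.attributes.get("source_type", ["mRNA"])[0]
        blocks.setdefault(tid, []).append((feat.start - 1, feat.end))
        meta.setdefault(tid, (feat.seqid, feat.strand, source))
    out = []
    for tid, bl in blocks.items():
        chrom, strand, source = meta[tid]
        out.append(TranscriptAlignment(tid, source, chrom, strand, sorted(bl)))
    return out


# ---------------------------------------------------------------------------
# BED12


def _parse_bed12_line(line: str, lineno: int, default_source: str) -> TranscriptAlignment:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 12:
        raise ParseError(f"line {lineno}: BED12 needs 12 columns, got {len(parts)}")
    chrom, chrom_start, _, name, _, strand = parts[0], int(parts[1]), parts[2], parts[3], parts[4], parts[5]
    n_blocks = int(parts[9])
    sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
    starts = [int(x) for x in parts[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise ParseError(f"line {lineno}: blockCount does not match blockSizes/blockStarts")
    blocks = [(chrom_start + st, chrom_start + st + sz) for st, sz in zip(starts, sizes)]
    return TranscriptAlignment(name, default_source, chrom, strand, blocks)


def read_alignments(
    path: str, format: str = "bed12", source: str = "EST"
) -> list[TranscriptAlignment]:
    """Read spliced transcript alignments from BED12 or GTF.

    ``source`` labels BED12 records (mRNA or EST); GTF records may carry a
    ``source_type`` attribute instead.
    """
    fmt = format.lower()
    if fmt == "gtf":
        return _read_gtf_alignments(path)
    if fmt != "bed12":
        raise ValueError(f"unknown alignment format {format!r}")
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            out.append(_parse_bed12_line(line, lineno, source))
    return out


def bed12_line(
    chrom: str,
    strand: str,
    blocks: Sequence[Interval],
    name: str,
    score: int = 0,
    rgb: str = "0",
) -> str:
    start, end = blocks[0][0], blocks[-1][1]
    sizes = ",".join(str(e - s) for s, e in blocks) + ","
    starts = ",".join(str(s - start) for s, _ in blocks) + ","
    return (
        f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\t{start}\t{end}\t{rgb}"
        f"\t{len(blocks)}\t{sizes}\t{starts}\n"
    )


def write_alignments_bed12(alignments: Iterable[TranscriptAlignment], path: str) -> None:
    with open(path, "w") as fh:
        for aln in alignments:
            fh.write(bed12_line(aln.chrom, aln.strand, aln.blocks, aln.transcript_id))


def write_bed12(calls, path: str) -> None:
    """Write conjoined-gene calls as BED12, one row per call transcript."""
    with open(path, "w") as fh:
        for call in calls:
            name = f"{call.transcript.transcript_id}|{'--'.join(p.symbol for p in call.parents)}"
            fh.write(
                bed12_line(call.transcript.chrom, call.transcript.strand, call.transcript.blocks, name)
            )


# ---------------------------------------------------------------------------
# Tabular/JSON reports


def write_report(records: list[dict], path: str, format: str = "tsv") -> None:
    """Write a list of flat dict records as TSV (stable column order) or JSON."""
    fmt = format.lower()
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
            fh.write("\n")
        return
    if fmt != "tsv":
        raise ValueError(f"unknown report format {format!r}")
    columns: list[str] = []
    for rec in records:
        for key in rec:
            if key not in columns:
                columns.append(key)
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for rec in records:
            fh.write("\t".join(str(rec.get(c, "")) for c in columns) + "\n")


def read_report(path: str, format: str = "tsv") -> list[dict]:
    if format.lower() == "json":
        with open(path) as fh:
            return json.load(fh)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        return []
    columns = lines[0].split("\t")
    return [dict(zip(columns, line.split("\t"))) for line in lines[1:]]
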