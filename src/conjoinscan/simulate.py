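"""Deterministic synthetic transcriptome scenes with planted conjoined genes.

The generator emulates the inputs the detector consumes in practice — a
genome, a gene annotation with CDSs, and spliced transcript alignments —
with complete control over the truth: every planted CG realises one class
of splicing/ORF/NMD/SHS behaviour exactly, every negative realises one
classic false-positive mode, and a truth table records the labels.

Parent genes carry canonical GT-AG introns and phase-annotated CDSs by
construction. Truth labels that depend on sequence (longest ORF, NMD
distance, maximal junction repeat) are re-derived from the emitted
sequences by small independent oracles inside the generator, never assumed,
so the truth table is consistent with the files by construction.

All randomness flows from the single config seed; the same seed produces
byte-identical files.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field
from typing import Optional

from .io import write_alignments_bed12, write_fasta, write_gtf_genes, write_report
from .models import (
    AnnotationSet,
    GeneModel,
    GenomeSequence,
    Interval,
    TranscriptAlignment,
    ValidationError,
    revcomp,
)

CG_CLASSES = (
    "junction_intron",
    "retained_terminal",
    "novel_exon_intergenic",
    "novel_exon_intronic",
    "chimeric_frame",
    "frameshift_similar_to_5p",
    "nmd_positive",
    "shs_positive",
)
NEG_CLASSES = (
    "antisense",
    "unspliced_est",
    "single_locus_multiname",
    "paralog_mimic",
    "monogenic_transcript",
)

STOPS = ("TAA", "TAG", "TGA")
NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOPS and a + b + c != "ATG"
)
ACG_CODONS = tuple(a + b + c for a in "ACG" for b in "ACG" for c in "ACG")


def _default_cg_counts() -> dict:
    return {
        "junction_intron": 8,
        "retained_terminal": 7,
        "novel_exon_intergenic": 7,
        "novel_exon_intronic": 7,
        "chimeric_frame": 7,
        "frameshift_similar_to_5p": 7,
        "nmd_positive": 4,
        "shs_positive": 3,
    }


def _default_neg_counts() -> dict:
    return {
        "antisense": 10,
        "unspliced_est": 10,
        "single_locus_multiname": 10,
        "paralog_mimic": 10,
        "monogenic_transcript": 10,
    }


@dataclass
class SimConfig:
    seed: int = 0
    chrom: str = "chrS"
    chrom_length: Optional[int] = None  # None = sized to fit the layout
    n_genes: int = 30  # background genes without transcripts
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_len: tuple[int, int] = (80, 300)
    intron_len: tuple[int, int] = (100, 2000)
    intergenic_gap: tuple[int, int] = (500, 15000)
    cg_counts: dict = field(default_factory=_default_cg_counts)
    neg_counts: dict = field(default_factory=_default_neg_counts)
    shs_len_range: tuple[int, int] = (4, 8)

    def __post_init__(self) -> None:
        for name in ("exons_per_gene", "exon_len", "intron_len", "intergenic_gap",
                     "shs_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ValidationError(f"invalid range for {name}: ({lo}, {hi})")
        if self.exons_per_gene[0] < 3:
            raise ValidationError("genes need >= 3 exons (UTR + coding + UTR layout)")
        unknown = set(self.cg_counts) - set(CG_CLASSES)
        unknown |= set(self.neg_counts) - set(NEG_CLASSES)
        if unknown:
            raise ValidationError(f"unknown planted classes: {sorted(unknown)}")
        if any(v < 0 for v in list(self.cg_counts.values()) + list(self.neg_counts.values())):
            raise ValidationError("planted class counts must be >= 0")


@dataclass
class TruthRecord:
    transcript_id: str
    is_cg: bool
    class_label: str
    parents: tuple[str, ...]
    junction_pattern: Optional[bool] = None
    novel_exons: tuple[tuple[Interval, str], ...] = ()
    orf_class: Optional[str] = None
    nmd: Optional[bool] = None
    shs_max_len: Optional[int] = None
    breakpoint: Optional[int] = None
    any_new_site: Optional[bool] = None

    def as_row(self) -> dict:
        return {
            "transcript_id": self.transcript_id,
            "is_cg": int(self.is_cg),
            "class": self.class_label,
            "parents": ",".join(self.parents),
            "junction_pattern": "" if self.junction_pattern is None else int(self.junction_pattern),
            "novel_exons": ";".join(f"{s}-{e}:{o}" for (s, e), o in self.novel_exons),
            "orf_class": self.orf_class or "",
            "nmd": "" if self.nmd is None else int(self.nmd),
            "shs_max_len": "" if self.shs_max_len is None else self.shs_max_len,
            "breakpoint": "" if self.breakpoint is None else self.breakpoint,
            "any_new_site": "" if self.any_new_site is None else int(self.any_new_site),
        }


@dataclass
class Scene:
    config: SimConfig
    genome: GenomeSequence
    annotation: AnnotationSet
    alignments: list[TranscriptAlignment]
    truth: list[TruthRecord]

    def write(self, outdir: str) -> dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "genome": os.path.join(outdir, "genome.fa"),
            "genes": os.path.join(outdir, "genes.gtf"),
            "alignments": os.path.join(outdir, "alignments.bed12"),
            "truth": os.path.join(outdir, "truth.tsv"),
        }
        chrom = self.config.chrom
        write_fasta({chrom: self.genome.sequence(chrom, 0, self.genome.chrom_length(chrom))},
                    paths["genome"])
        write_gtf_genes(self.annotation, paths["genes"])
        write_alignments_bed12(self.alignments, paths["alignments"])
        write_report([t.as_row() for t in self.truth], paths["truth"], "tsv")
        return paths


# ---------------------------------------------------------------------------
# independent mini-oracles used only to derive/verify truth labels


def _scan_longest_orf(seq: str) -> Optional[tuple[int, int, bool]]:
    """(start, end, complete) of the longest ATG-initiated reading frame."""
    best = None
    i = seq.find("ATG")
    while i != -1:
        j = i
        end, complete = None, False
        while j + 3 <= len(seq):
            if seq[j : j + 3] in STOPS:
                end, complete = j + 3, True
                break
            j += 3
        if end is None:
            end = i + (len(seq) - i) // 3 * 3
        length = end - i
        if length >= 3 and (best is None or length > best[1] - best[0]):
            best = (i, end, complete)
        i = seq.find("ATG", i + 1)
    return best


def _max_common_run(a: str, b: str) -> int:
    """Length of the longest exact common substring (simple DP)."""
    best = 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best


# ---------------------------------------------------------------------------
# sequence-level helpers


def _scrub_atg(chars: list[str]) -> None:
    for i in range(len(chars) - 2):
        if chars[i] == "A" and chars[i + 1] == "T" and chars[i + 2] == "G":
            chars[i + 1] = "C"


def _rand_utr(rng: random.Random, n: int) -> str:
    chars = [rng.choice("ACGT") for _ in range(n)]
    _scrub_atg(chars)
    return "".join(chars)


def _rand_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@dataclass
class _GeneMeta:
    model: GeneModel
    cds_start_g: int  # genomic index of the transcription-first CDS base
    cds_end_g: int  # genomic index of the transcription-last CDS base


class _SceneBuilder:
    def __init__(self, config: SimConfig):
        self.cfg = config
        self.rng = random.Random(config.seed)
        self.buf = bytearray()
        self.genes: list[GeneModel] = []
        self.transcripts: list[TranscriptAlignment] = []
        self.truth: list[TruthRecord] = []
        self._gid = 0
        self._tid = 0

    # -- low-level genome edits ---------------------------------------------

    def _append(self, seq: str) -> None:
        self.buf.extend(seq.encode())

    def _gap(self, at_least: int = 0) -> None:
        lo, hi = self.cfg.intergenic_gap
        n = max(self.rng.randint(lo, hi), at_least)
        self._append(_rand_seq(self.rng, n))

    def _write_g(self, pos: int, seq: str) -> None:
        self.buf[pos : pos + len(seq)] = seq.encode()

    def _tx_to_g(self, blocks: list[Interval], strand: str, pos: int) -> int:
        bl = blocks if strand == "+" else blocks[::-1]
        off = pos
        for s, e in bl:
            if off < e - s:
                return s + off if strand == "+" else e - 1 - off
            off -= e - s
        raise ValueError("tx position out of range")

    def _g_to_tx(self, blocks: list[Interval], strand: str, g: int) -> int:
        bl = blocks if strand == "+" else blocks[::-1]
        off = 0
        for s, e in bl:
            if s <= g < e:
                return off + (g - s if strand == "+" else e - 1 - g)
            off += e - s
        raise ValueError("genomic position not in blocks")

    def _write_tx(self, blocks: list[Interval], strand: str, pos: int, seq: str) -> None:
        for i, ch in enumerate(seq):
            g = self._tx_to_g(blocks, strand, pos + i)
            if strand == "+":
                self.buf[g] = ord(ch)
            else:
                self.buf[g] = ord(revcomp(ch))

    def _spliced(self, blocks: list[Interval], strand: str) -> str:
        seq = "".join(self.buf[s:e].decode() for s, e in blocks)
        return seq if strand == "+" else revcomp(seq)

    # -- gene construction ---------------------------------------------------

    def _next_gid(self) -> str:
        self._gid += 1
        return f"G{self._gid:04d}"

    def _next_tid(self, prefix: str) -> str:
        self._tid += 1
        return f"{prefix}{self._tid:05d}"

    def build_gene(
        self,
        strand: str,
        stop_exon: str = "terminal",  # terminal | penultimate
        cds_offset: int = 0,  # 5'UTR bases at the start of exon t2
        exon_len_overrides: Optional[dict[int, int]] = None,
        intron_len_overrides: Optional[dict[int, int]] = None,
        gene_id: Optional[str] = None,
        symbol: Optional[str] = None,
    ) -> _GeneMeta:
        """Append one gene at the current end of the genome buffer.

        Transcription-order layout: exon t1 is fully 5'UTR; the CDS starts at
        ``cds_offset`` into t2 and ends (stop codon included) either inside
        the terminal exon or inside the second-to-last exon, always leaving
        >= 20 nt of 3'UTR in that exon. Introns are canonical GT-AG on the
        transcribed strand.
        """
        rng = self.rng
        cfg = self.cfg
        start = len(self.buf)
        k = rng.randint(*cfg.exons_per_gene)
        lens = [rng.randint(*cfg.exon_len) for _ in range(k)]
        ilens = [rng.randint(*cfg.intron_len) for _ in range(k - 1)]
        lens[1] = max(lens[1], 120)  # the first coding exon anchors the CDS
        for i, v in (exon_len_overrides or {}).items():
            lens[i] = v
        for i, v in (intron_len_overrides or {}).items():
            ilens[i] = v

        tail = 0
        tk_coding = 0
        if stop_exon == "terminal":
            # coding length before the terminal exon must be codon-aligned so
            # read-through transcripts enter the next gene in frame
            pre = sum(lens[1 : k - 1]) - cds_offset
            lens[k - 2] += (-pre) % 3
            pre = sum(lens[1 : k - 1]) - cds_offset
            tk_coding = 3 * rng.randint(2, max(2, (lens[-1] - 21) // 3))
            total_cds = pre + tk_coding
        elif stop_exon == "penultimate":
            tail = rng.randint(25, 49)
            pre = sum(lens[1 : k - 1]) - cds_offset - tail
            tail += pre % 3
            total_cds = sum(lens[1 : k - 1]) - cds_offset - tail
        else:
            raise ValueError(stop_exon)

        n_mid = (total_cds - 6) // 3
        cds_seq = "ATG" + "".join(rng.choice(NONSTOP_CODONS) for _ in range(n_mid)) + rng.choice(STOPS)
        assert len(cds_seq) == total_cds

        def coding_in_exon(i: int) -> int:
            if i == 0:
                return 0
            coding_from = cds_offset if i == 1 else 0
            if stop_exon == "terminal":
                return tk_coding if i == k - 1 else lens[i] - coding_from
            if i == k - 1:
                return 0
            if i == k - 2:
                return lens[i] - coding_from - tail
            return lens[i] - coding_from

        # transcription-order exon contents
        exon_seqs = []
        cds_cursor = 0
        for i in range(k):
            L = lens[i]
            if i == 0:
                exon_seqs.append(_rand_utr(rng, L))
                continue
            coding_from = cds_offset if i == 1 else 0
            coding_in = coding_in_exon(i)
            part = (
                _rand_utr(rng, coding_from)
                + cds_seq[cds_cursor : cds_cursor + coding_in]
                + _rand_utr(rng, L - coding_from - coding_in)
            )
            cds_cursor += coding_in
            exon_seqs.append(part)
        assert cds_cursor == total_cds, (cds_cursor, total_cds)

        intron_seqs = [
            "GT" + _rand_seq(rng, ilens[i] - 4) + "AG" for i in range(k - 1)
        ]
        tx_seq_parts = []
        for i in range(k):
            tx_seq_parts.append(exon_seqs[i])
            if i < k - 1:
                tx_seq_parts.append(intron_seqs[i])
        genomic = "".join(tx_seq_parts)
        if strand == "-":
            genomic = revcomp(genomic)
        self._append(genomic)

        total = len(genomic)
        # genomic exon intervals from transcription-order offsets
        exons_g = []
        off = 0
        for i in range(k):
            if strand == "+":
                exons_g.append((start + off, start + off + lens[i]))
            else:
                exons_g.append((start + total - off - lens[i], start + total - off))
            off += lens[i] + (ilens[i] if i < k - 1 else 0)
        exons_sorted = sorted(exons_g)

        # CDS segments (transcription order), then genomic
        cds_segments = []
        cum = 0
        off = 0
        for i in range(k):
            coding_from = cds_offset if i == 1 else 0
            coding_in = coding_in_exon(i)
            if coding_in > 0:
                tx_lo = off + coding_from
                tx_hi = tx_lo + coding_in
                if strand == "+":
                    seg = (start + tx_lo, start + tx_hi)
                else:
                    seg = (start + total - tx_hi, start + total - tx_lo)
                phase = (3 - cum % 3) % 3
                cds_segments.append((seg[0], seg[1], phase))
                cum += coding_in
            off += lens[i] + (ilens[i] if i < k - 1 else 0)
        cds_segments.sort()

        gid = gene_id or self._next_gid()
        model = GeneModel(gid, symbol or gid, self.cfg.chrom, strand, exons_sorted, cds_segments)
        self.genes.append(model)
        # transcription-first/last CDS genomic base, from segments
        segs_tx = cds_segments if strand == "+" else cds_segments[::-1]
        cds_start_g = segs_tx[0][0] if strand == "+" else segs_tx[0][1] - 1
        cds_end_g = segs_tx[-1][1] - 1 if strand == "+" else segs_tx[-1][0]
        return _GeneMeta(model, cds_start_g, cds_end_g)

    # -- CG transcript assembly ---------------------------------------------

    def _plant_intron_sites(self, blocks: list[Interval], strand: str) -> None:
        """Force canonical dinucleotides at every transcript intron boundary."""
        for i in range(len(blocks) - 1):
            s, e = blocks[i][1], blocks[i + 1][0]
            if strand == "+":
                self._write_g(s, "GT")
                self._write_g(e - 2, "AG")
            else:
                self._write_g(s, "CT")
                self._write_g(e - 2, "AC")

    def _finalize_cg(
        self,
        class_label: str,
        blocks: list[Interval],
        strand: str,
        parents: tuple[str, ...],
        planted_start_g: int,
        planted_end_g: Optional[int],
        planted_end_tx: Optional[int],
        orf_class: str,
        junction_pattern: bool,
        novel: tuple[tuple[Interval, str], ...],
        any_new_site: bool,
        bp_tx: int,
        bp_junction: int,
        protected_tx: list[Interval],
        shs_len: Optional[int] = None,
    ) -> bool:
        """Scrub/repair the transcript so the planted ORF is the longest one,
        then derive and record the truth. Returns False if repair failed."""
        blocks = sorted(blocks)
        self._plant_intron_sites(blocks, strand)
        L = sum(e - s for s, e in blocks)
        p_start = self._g_to_tx(blocks, strand, planted_start_g)
        p_end = planted_end_tx if planted_end_tx is not None else (
            self._g_to_tx(blocks, strand, planted_end_g) + 1
        )

        def editable(pos: int) -> bool:
            if pos < p_end or pos + 3 > L:
                return False
            return not any(lo <= pos < hi or lo < pos + 3 <= hi for lo, hi in protected_tx)

        # no ATG outside the planted ORF: scrub the head and the tail
        # (downstream parent CDS content is positional only, so edits there
        # are free as long as splice sites and coordinates stand)
        seq = self._spliced(blocks, strand)
        head = list(seq[:p_start])
        _scrub_atg(head)
        self._write_tx(blocks, strand, 0, "".join(head))
        tail_from = max(p_end - 1, 0)
        tail = list(self._spliced(blocks, strand)[tail_from:])
        for i in range(len(tail) - 2):
            pos = tail_from + i
            if tail[i] == "A" and tail[i + 1] == "T" and tail[i + 2] == "G":
                if not any(lo <= pos + 1 < hi for lo, hi in protected_tx):
                    tail[i + 1] = "C"
        self._write_tx(blocks, strand, tail_from, "".join(tail))

        for _ in range(30):
            seq = self._spliced(blocks, strand)
            best = _scan_longest_orf(seq)
            if best is None:
                return False
            bs, be, _ = best
            if (bs, be) == (p_start, p_end):
                break
            # a shifted-frame competitor outgrew the planted ORF: truncate it
            # with a stop planted downstream of the planted ORF on its frame
            patched = False
            for pos in range(max(p_end, bs + 3), L - 2):
                if (pos - bs) % 3 == 0 and editable(pos):
                    self._write_tx(blocks, strand, pos, "TAA")
                    patched = True
                    break
            if not patched:
                return False
        else:
            return False

        seq = self._spliced(blocks, strand)
        last_junction = L - (blocks[-1][1] - blocks[-1][0] if strand == "+"
                            else blocks[0][1] - blocks[0][0])
        nmd = (last_junction - p_end) >= 50 and len(blocks) > 1
        w5 = seq[max(0, bp_tx - 20) : bp_tx]
        w3 = seq[bp_tx : bp_tx + 20]
        run = _max_common_run(w5, w3)
        shs_max = run if run >= 4 else 0
        if shs_len is not None and shs_max != shs_len:
            return False

        tid = self._next_tid("CGm")
        self.transcripts.append(
            TranscriptAlignment(tid, "mRNA", self.cfg.chrom, strand, blocks)
        )
        self.truth.append(
            TruthRecord(
                transcript_id=tid,
                is_cg=True,
                class_label=class_label,
                parents=parents,
                junction_pattern=junction_pattern,
                novel_exons=novel,
                orf_class=orf_class,
                nmd=nmd,
                shs_max_len=shs_max,
                breakpoint=bp_junction,
                any_new_site=any_new_site,
            )
        )
        return True

    # -- planted CG classes ---------------------------------------------------

    def add_cg(self, class_label: str) -> None:
        for _ in range(12):
            mark_buf = len(self.buf)
            mark = (len(self.genes), len(self.transcripts), len(self.truth),
                    self._gid, self._tid)
            if self._try_add_cg(class_label):
                return
            del self.buf[mark_buf:]
            del self.genes[mark[0]:]
            del self.transcripts[mark[1]:]
            del self.truth[mark[2]:]
            self._gid, self._tid = mark[3], mark[4]
        raise ValidationError(f"could not realise planted class {class_label}")

    def _try_add_cg(self, class_label: str) -> bool:
        rng = self.rng
        strand = rng.choice("+-")
        self._gap()

        stop_a = "terminal" if class_label in ("chimeric_frame", "frameshift_similar_to_5p",
                                               "retained_terminal") else "penultimate"
        cds_off_b = 20 if class_label == "shs_positive" else 0
        intron_over_a = {0: rng.randint(400, 900)} if class_label == "novel_exon_intronic" else None

        gap_between = max(
            self.rng.randint(*self.cfg.intergenic_gap),
            1500 if class_label in ("novel_exon_intergenic", "frameshift_similar_to_5p") else 500,
        )

        first_meta = None
        if strand == "+":
            a = self.build_gene(strand, stop_exon=stop_a, intron_len_overrides=intron_over_a)
            self._append(_rand_seq(rng, gap_between))
            b = self.build_gene(strand, cds_offset=cds_off_b)
        else:
            # upstream-in-transcription gene sits genomically right
            b = self.build_gene(strand, cds_offset=cds_off_b)
            self._append(_rand_seq(rng, gap_between))
            a = self.build_gene(strand, stop_exon=stop_a, intron_len_overrides=intron_over_a)

        A, B = a.model, b.model
        a_tx, b_tx = A.exons_tx, B.exons_tx
        parents = (A.gene_id, B.gene_id)

        novel: tuple = ()
        any_new = False
        blocks: list[Interval]
        junction_pattern: bool
        if class_label in ("junction_intron", "nmd_positive", "chimeric_frame", "shs_positive"):
            blocks = a_tx[:-1] + b_tx[1:]
            junction_pattern = True
            any_new = False
        elif class_label == "retained_terminal":
            blocks = a_tx[:] + b_tx[1:]
            junction_pattern = False
            any_new = True  # donor after the retained terminal exon is unannotated
        elif class_label in ("novel_exon_intergenic", "frameshift_similar_to_5p"):
            e_len = 120 if class_label == "novel_exon_intergenic" else 100
            gap_lo = min(A.span[1], B.span[1])
            gap_hi = max(A.span[0], B.span[0])
            margin = 60
            e_start = rng.randint(gap_lo + margin, gap_hi - margin - e_len)
            e_block = (e_start, e_start + e_len)
            self._write_g(e_start, _rand_utr(rng, e_len))
            blocks = a_tx[:-1] + [e_block] + b_tx[1:]
            junction_pattern = False
            novel = ((e_block, "intergenic"),)
            any_new = True
        elif class_label == "novel_exon_intronic":
            e_len = 120
            # transcription intron between t1 and t2, as a genomic interval
            if strand == "+":
                ilo, ihi = a_tx[0][1], a_tx[1][0]
            else:
                ilo, ihi = a_tx[1][1], a_tx[0][0]
            e_start = rng.randint(ilo + 60, ihi - 60 - e_len)
            e_block = (e_start, e_start + e_len)
            self._write_g(e_start, _rand_utr(rng, e_len))
            blocks = [a_tx[0], e_block] + a_tx[1:-1] + b_tx[1:]
            junction_pattern = True
            novel = ((e_block, "intronic"),)
            any_new = True
        else:
            raise ValueError(class_label)

        blocks = sorted(blocks)
        strand_blocks_tx = blocks if strand == "+" else blocks[::-1]

        # planted ORF bounds
        p_start_g = a.cds_start_g
        p_end_g: Optional[int] = None
        p_end_tx: Optional[int] = None
        protected: list[Interval] = []
        if class_label == "chimeric_frame":
            p_end_g = b.cds_end_g
            orf_class = "chimeric"
        elif class_label == "frameshift_similar_to_5p":
            # ORF reads the upstream CDS, crosses into the novel exon in
            # frame, and hits a stop planted 30 nt in
            e_block = novel[0][0]
            e_tx = self._g_to_tx(blocks, strand, e_block[0] if strand == "+" else e_block[1] - 1)
            prefix = "".join(rng.choice(ACG_CODONS) for _ in range(10))
            self._write_tx(blocks, strand, e_tx, prefix + "TAA")
            p_end_tx = e_tx + 33
            protected.append((e_tx, e_tx + 33))
            orf_class = "similar_to_5p"
        else:
            p_end_g = a.cds_end_g
            orf_class = "similar_to_5p"

        # breakpoint: end of the last upstream-parent block's contribution,
        # recorded relative to the junction region (which starts at that block)
        last_up_block = next(
            b_ for b_ in reversed(strand_blocks_tx)
            if any(min(b_[1], x[1]) > max(b_[0], x[0]) for x in A.exons)
        )
        bp_tx = self._g_to_tx(blocks, strand,
                              last_up_block[1] - 1 if strand == "+" else last_up_block[0]) + 1
        bp_junction = last_up_block[1] - last_up_block[0]

        shs_target = None
        if class_label == "shs_positive":
            shs_target = rng.randint(*self.cfg.shs_len_range)
            repeat = _rand_seq(rng, shs_target)
            while "ATG" in repeat:
                repeat = _rand_seq(rng, shs_target)
            self._write_tx(blocks, strand, bp_tx - shs_target, repeat)
            self._write_tx(blocks, strand, bp_tx, repeat)
            protected.append((bp_tx - 20, bp_tx + 20))
            # windows must not accidentally extend the repeat or seed an ORF
            seq = self._spliced(blocks, strand)
            if _max_common_run(seq[bp_tx - 20 : bp_tx], seq[bp_tx : bp_tx + 20]) != shs_target:
                return False
            if "ATG" in seq[bp_tx - 22 : bp_tx + 22]:
                return False
        return self._finalize_cg(
            class_label, blocks, strand, parents, p_start_g, p_end_g, p_end_tx,
            orf_class, junction_pattern, novel, any_new, bp_tx, bp_junction,
            protected, shs_len=shs_target,
        )

    # -- negatives ------------------------------------------------------------

    def add_negative(self, class_label: str) -> None:
        rng = self.rng
        strand = rng.choice("+-")
        self._gap()
        if class_label == "monogenic_transcript":
            g = self.build_gene(strand).model
            blocks = sorted(g.exons_tx[:-1]) if len(g.exons) > 2 else sorted(g.exons)
            tid = self._next_tid("NEG")
            self.transcripts.append(TranscriptAlignment(tid, "EST", self.cfg.chrom, strand, blocks))
            self.truth.append(TruthRecord(tid, False, class_label, (g.gene_id,)))
            return
        if class_label == "single_locus_multiname":
            g = self.build_gene(strand)
            g1 = g.model
            g2_id = self._next_gid()
            g2 = GeneModel(g2_id, g2_id, self.cfg.chrom, strand, list(g1.exons[1:]))
            self.genes.append(g2)
            blocks = sorted([g1.exons[0]] + list(g1.exons[2:]))
            tid = self._next_tid("NEG")
            self.transcripts.append(TranscriptAlignment(tid, "EST", self.cfg.chrom, strand, blocks))
            self.truth.append(TruthRecord(tid, False, class_label, (g1.gene_id, g2_id)))
            return

        gap = rng.randint(*self.cfg.intergenic_gap)
        if class_label == "paralog_mimic":
            c = self.build_gene(strand, exon_len_overrides={1: 150})
            self._append(_rand_seq(rng, gap))
            d = self.build_gene(strand, exon_len_overrides={1: 150})
            # copy C's first coding exon into D at ~97% identity
            c_exon = c.model.exons_tx[1]
            d_exon = d.model.exons_tx[1]
            # same strand, plus-strand copy => same transcribed orientation
            chars = list(self.buf[c_exon[0] : c_exon[1]].decode())
            for _ in range(5):
                i = rng.randrange(len(chars))
                chars[i] = rng.choice([x for x in "ACGT" if x != chars[i]])
            self._write_g(d_exon[0], "".join(chars))
            blocks = sorted([c_exon, d_exon])
            tid = self._next_tid("NEG")
            self.transcripts.append(TranscriptAlignment(tid, "EST", self.cfg.chrom, strand, blocks))
            self.truth.append(
                TruthRecord(tid, False, class_label, (c.model.gene_id, d.model.gene_id))
            )
            return

        # two-gene layouts: antisense / unspliced_est
        g1 = self.build_gene(strand).model
        self._append(_rand_seq(rng, gap))
        g2 = self.build_gene(strand).model
        left, right = (g1, g2) if g1.span[0] < g2.span[0] else (g2, g1)
        if class_label == "antisense":
            anti = "-" if strand == "+" else "+"
            blocks = sorted([left.exons[-2], left.exons[-1], right.exons[0], right.exons[1]])
            tid = self._next_tid("NEG")
            self.transcripts.append(TranscriptAlignment(tid, "EST", self.cfg.chrom, anti, blocks))
            self.truth.append(TruthRecord(tid, False, class_label, (g1.gene_id, g2.gene_id)))
            return
        if class_label == "unspliced_est":
            lx = left.exons[-1]
            rx = right.exons[0]
            block = (lx[0] + (lx[1] - lx[0]) // 2, rx[0] + (rx[1] - rx[0]) // 2 + 1)
            tid = self._next_tid("NEG")
            self.transcripts.append(
                TranscriptAlignment(tid, "EST", self.cfg.chrom, strand, [block])
            )
            self.truth.append(TruthRecord(tid, False, class_label, (g1.gene_id, g2.gene_id)))
            return
        raise ValueError(class_label)

    # -- scene ----------------------------------------------------------------

    def build(self) -> Scene:
        cfg = self.cfg
        self._append(_rand_seq(self.rng, 500))
        units: list[tuple[str, str]] = []
        for cls in CG_CLASSES:
            units += [("cg", cls)] * cfg.cg_counts.get(cls, 0)
        for cls in NEG_CLASSES:
            units += [("neg", cls)] * cfg.neg_counts.get(cls, 0)
        units += [("bg", "")] * cfg.n_genes
        self.rng.shuffle(units)
        for kind, cls in units:
            if kind == "cg":
                self.add_cg(cls)
            elif kind == "neg":
                self.add_negative(cls)
            else:
                self._gap()
                self.build_gene(self.rng.choice("+-"))
        self._gap()
        needed = len(self.buf)
        if cfg.chrom_length is not None:
            if cfg.chrom_length < needed:
                raise ValidationError(
                    f"chrom_length {cfg.chrom_length} too small for the layout; "
                    f"needs >= {needed} (or set chrom_length=None to auto-size)"
                )
            self._append(_rand_seq(self.rng, cfg.chrom_length - needed))
        genome = GenomeSequence({cfg.chrom: self.buf.decode()})
        return Scene(
            config=cfg,
            genome=genome,
            annotation=AnnotationSet(self.genes),
            alignments=list(self.transcripts),
            truth=list(self.truth),
        )


def simulate_scene(config: Optional[SimConfig] = None) -> Scene:
    """Generate a deterministic scene from a :class:`SimConfig`."""
    return _SceneBuilder(config or SimConfig()).build()


def mutate_targets(
    seqs: dict[str, str], substitution_rate: float, seed: int
) -> dict[str, str]:
    """Apply i.i.d. substitutions at the given per-base rate."""
    if not 0 <= substitution_rate <= 1:
        raise ValidationError("substitution_rate must be in [0, 1]")
    rng = random.Random(seed)
    out = {}
    for name, seq in seqs.items():
        chars = list(seq)
        for i, ch in enumerate(chars):
            if rng.random() < substitution_rate:
                chars[i] = rng.choice([x for x in "ACGT" if x != ch])
        out[name] = "".join(chars)
    return out
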