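"""End-to-end pipeline: detect -> curate -> group -> splice -> orf -> junction -> pairs.

One combined report row per CG group, carrying every classification, so a
single run yields the full characterization table. All thresholds used are
echoed into the report header block, making outputs self-describing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from . import io
from .detect import (
    CGGroup,
    DetectionParams,
    curate,
    detect_alternative_splicing,
    detect_conjoined,
    group_calls,
)
from .junction import ConservationParams, detect_shs, extract_junction_exon, search_conservation
from .models import AnnotationSet, GenomeSequence, TranscriptAlignment, ValidationError
from .orf import orf_report
from .pairs import enumerate_pairs, parent_distance_stats
from .splicing import splicing_report

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    detection: DetectionParams = field(default_factory=DetectionParams)
    conservation: ConservationParams = field(default_factory=ConservationParams)
    shs_window: int = 20
    shs_min_len: int = 4
    min_shared_coding_bp: int = 30
    nmd_distance: int = 50
    max_pair_gap: int = 10_000

    def as_header(self) -> dict:
        d = {f"detection.{k}": v for k, v in vars(self.detection).items()}
        d.update({f"conservation.{k}": v for k, v in vars(self.conservation).items()})
        for k in ("shs_window", "shs_min_len", "min_shared_coding_bp",
                  "nmd_distance", "max_pair_gap"):
            d[k] = getattr(self, k)
        return d


@dataclass
class PipelineResult:
    calls: list
    rejected: list
    groups: list[CGGroup]
    rows: list[dict]
    pair_count: int
    config: RunConfig


def run_all(
    alignments: list[TranscriptAlignment],
    annotation: AnnotationSet,
    genome: Optional[GenomeSequence],
    config: Optional[RunConfig] = None,
    targets: Optional[dict[str, str]] = None,
) -> PipelineResult:
    """Run every stage and build the combined per-CG-group report."""
    config = config or RunConfig()
    needs_genome = (
        config.detection.enable_paralog_filter or True
    )  # splice/orf/junction stages all read sequence
    if genome is None:
        raise ValidationError("pipeline requires a genome (sequence-level stages)")

    calls = detect_conjoined(alignments, annotation, config.detection)
    kept, rejected = curate(calls, genome, config.detection)
    groups = group_calls(kept)
    rows = []
    for grp in groups:
        call = grp.calls[0]
        srep = splicing_report(call, genome)
        orep = orf_report(call, genome, min_shared_bp=config.min_shared_coding_bp,
                          nmd_distance=config.nmd_distance)
        junc = extract_junction_exon(call, genome)
        shs = detect_shs(junc, window=config.shs_window, min_len=config.shs_min_len)
        cons = (
            search_conservation(junc, targets, config.conservation) if targets else []
        )
        rows.append(
            {
                "cg_id": "--".join(grp.parent_tuple),
                "parents": ",".join(grp.parent_tuple),
                "n_support": len(grp.calls),
                "alt_splicing": detect_alternative_splicing(grp),
                "junction_pattern": srep.junction_intron_pattern,
                "novel_exons": ";".join(
                    f"{s}-{e}:{o}" for (s, e), o in srep.novel_exons
                ),
                "any_new_site": srep.any_new_site,
                "n_new_sites": srep.n_new_sites,
                "all_canonical": all(s.canonical for s in srep.splice_sites),
                "orf_class": orep.product_class,
                "nmd": orep.nmd_candidate,
                "junction_mode": junc.mode,
                "breakpoint": junc.breakpoint,
                "shs_max_len": shs[0].length if shs else 0,
                "n_conserved_targets": len(cons),
            }
        )
    enum = enumerate_pairs(annotation, max_gap=config.max_pair_gap)
    return PipelineResult(kept, rejected, groups, rows, len(enum.pairs), config)


def write_combined_report(result: PipelineResult, path: str) -> None:
    with open(path, "w") as fh:
        for key, value in result.config.as_header().items():
            fh.write(f"# {key}={value}\n")
    # append the tabular body after the header block
    tmp = result.rows or [{}]
    body_cols: list[str] = []
    for rec in result.rows:
        for k in rec:
            if k not in body_cols:
                body_cols.append(k)
    with open(path, "a") as fh:
        fh.write("\t".join(body_cols) + "\n")
        for rec in result.rows:
            fh.write("\t".join(str(rec.get(c, "")) for c in body_cols) + "\n")
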