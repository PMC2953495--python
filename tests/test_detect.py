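import random

import pytest

from conjoinscan import (
    AnnotationSet,
    GeneModel,
    GenomeSequence,
    TranscriptAlignment,
    ValidationError,
    collapse_loci,
    curate,
    detect_alternative_splicing,
    detect_conjoined,
    group_calls,
)
from conjoinscan.detect import DetectionParams

from _oracles import brute_force_cg_parents
from conftest import random_annotation, random_transcripts


class TestDetect:
    def test_two_parent_call(self, toy_two_gene_scene):
        ann, tx = toy_two_gene_scene
        (call,) = detect_conjoined([tx], ann)
        assert call.parent_tuple == ("A", "B")
        assert call.overlap_bp == {"A": 100, "B": 100}

    def test_opposite_strand_no_call(self, toy_two_gene_scene):
        ann, tx = toy_two_gene_scene
        anti = TranscriptAlignment("t1", "mRNA", "c1", "-", tx.blocks)
        assert detect_conjoined([anti], ann) == []

    def test_single_parent_no_call(self, toy_two_gene_scene):
        ann, _ = toy_two_gene_scene
        tx = TranscriptAlignment("t2", "EST", "c1", "+", [(100, 200), (300, 400)])
        assert detect_conjoined([tx], ann) == []

    def test_minus_strand_parent_order(self):
        """Parents are ordered 5'->3' in transcription direction."""
        a = GeneModel("A", "A", "c1", "-", [(600, 700), (800, 900)])
        b = GeneModel("B", "B", "c1", "-", [(100, 200), (300, 400)])
        tx = TranscriptAlignment("t", "mRNA", "c1", "-", [(300, 400), (800, 900)])
        (call,) = detect_conjoined([tx], AnnotationSet([a, b]))
        assert call.parent_tuple == ("A", "B")  # A genomically right = 5'

    def test_bypassed_internal_gene_recorded(self):
        a = GeneModel("A", "A", "c1", "+", [(0, 100)])
        mid = GeneModel("M", "M", "c1", "+", [(200, 250), (300, 350)])
        b = GeneModel("B", "B", "c1", "+", [(500, 600)])
        tx = TranscriptAlignment("t", "mRNA", "c1", "+", [(0, 100), (500, 600)])
        (call,) = detect_conjoined([tx], AnnotationSet([a, mid, b]))
        assert call.parent_tuple == ("A", "B")
        assert call.bypassed_gene_ids == ["M"]

    def test_equivalence_with_brute_force(self):
        """Positional detection equals the double-loop overlap oracle."""
        rng = random.Random(3)
        for _ in range(20):
            ann = random_annotation(rng, rng.randint(5, 50))
            txs = random_transcripts(rng, rng.randint(10, 100))
            calls = detect_conjoined(txs, ann, collapse=False)
            got = {c.transcript.transcript_id: frozenset(c.parent_tuple) for c in calls}
            assert got == brute_force_cg_parents(txs, ann)

    def test_overlap_threshold_monotonic(self):
        """Raising min_exon_overlap_bp never increases the number of calls."""
        rng = random.Random(9)
        ann = random_annotation(rng, 40)
        txs = random_transcripts(rng, 120)
        counts = [
            len(detect_conjoined(txs, ann, DetectionParams(min_exon_overlap_bp=t)))
            for t in (1, 10, 30, 80)
        ]
        assert counts == sorted(counts, reverse=True)


class TestCollapse:
    def test_shared_exon_merged(self):
        g1 = GeneModel("G1", "NAME1", "c1", "+", [(100, 200), (300, 400)])
        g2 = GeneModel("G2", "NAME2", "c1", "+", [(100, 200)])
        merged = collapse_loci(AnnotationSet([g1, g2]))
        assert len(merged) == 1
        locus = merged.get("G1")
        assert "NAME1" in locus.symbol and "NAME2" in locus.symbol
        assert locus.exons == [(100, 200), (300, 400)]

    def test_opposite_strands_not_merged(self):
        g1 = GeneModel("G1", "G1", "c1", "+", [(100, 200)])
        g2 = GeneModel("G2", "G2", "c1", "-", [(100, 200)])
        assert len(collapse_loci(AnnotationSet([g1, g2]))) == 2

    def test_disjoint_unchanged(self):
        g1 = GeneModel("G1", "G1", "c1", "+", [(100, 200)])
        g2 = GeneModel("G2", "G2", "c1", "+", [(500, 600)])
        merged = collapse_loci(AnnotationSet([g1, g2]))
        assert {g.gene_id for g in merged} == {"G1", "G2"}

    def test_multiname_locus_never_a_cg(self):
        """Two names over one locus must not be called as two parents."""
        g1 = GeneModel("G1", "G1", "c1", "+", [(0, 100), (200, 300), (400, 500)])
        g2 = GeneModel("G2", "G2", "c1", "+", [(200, 300), (400, 500)])
        tx = TranscriptAlignment("t", "EST", "c1", "+", [(0, 100), (400, 500)])
        assert detect_conjoined([tx], AnnotationSet([g1, g2])) == []


class TestCurate:
    def _call(self, blocks, ann=None):
        ann = ann or AnnotationSet(
            [
                GeneModel("A", "A", "c1", "+", [(0, 100)]),
                GeneModel("B", "B", "c1", "+", [(1000, 1100)]),
            ]
        )
        tx = TranscriptAlignment("t", "EST", "c1", "+", blocks)
        (call,) = detect_conjoined([tx], ann)
        return call

    def test_short_alignment_rejected(self):
        call = self._call([(50, 100), (1000, 1080)])  # 130 bp aligned
        kept, rejected = curate([call], params=DetectionParams(enable_paralog_filter=False))
        assert kept == [] and rejected[0][1] == "short_alignment"

    def test_unspliced_rejected(self):
        call = self._call([(0, 1100)])  # single block across both genes
        kept, rejected = curate([call], params=DetectionParams(enable_paralog_filter=False))
        assert kept == [] and rejected[0][1] == "unspliced"

    def test_spliced_long_call_kept(self):
        call = self._call([(0, 100), (1000, 1100)])
        kept, rejected = curate([call], params=DetectionParams(enable_paralog_filter=False))
        assert rejected == [] and len(kept) == 1

    def test_paralog_filter_requires_genome(self):
        call = self._call([(0, 100), (1000, 1100)])
        with pytest.raises(ValidationError):
            curate([call], genome=None, params=DetectionParams())

    def test_engineered_paralogs_rejected(self):
        """Parents sharing a 95%-identical 150 bp exon are paralog suspects."""
        rng = random.Random(4)
        exon = "".join(rng.choice("ACGT") for _ in range(150))
        mutated = list(exon)
        for i in rng.sample(range(150), 7):
            mutated[i] = rng.choice([c for c in "ACGT" if c != mutated[i]])
        chrom = (
            "".join(rng.choice("ACGT") for _ in range(100))
            + exon
            + "".join(rng.choice("ACGT") for _ in range(750))
            + "".join(mutated)
            + "".join(rng.choice("ACGT") for _ in range(100))
        )
        genome = GenomeSequence({"c1": chrom})
        ann = AnnotationSet(
            [
                GeneModel("A", "A", "c1", "+", [(100, 250)]),
                GeneModel("B", "B", "c1", "+", [(1000, 1150)]),
            ]
        )
        tx = TranscriptAlignment("t", "EST", "c1", "+", [(100, 250), (1000, 1150)])
        (call,) = detect_conjoined([tx], ann)
        kept, rejected = curate([call], genome)
        assert kept == [] and rejected[0][1] == "paralog_suspect"


class TestGroups:
    def _calls(self, parent_lists, chains):
        genes = {}
        calls = []
        for i, (parents, chain) in enumerate(zip(parent_lists, chains)):
            for p in parents:
                genes.setdefault(p, GeneModel(p, p, "c1", "+", [(0, 10)]))
        from conjoinscan.detect import ConjoinedGeneCall

        for i, (parents, chain) in enumerate(zip(parent_lists, chains)):
            calls.append(
                ConjoinedGeneCall(
                    transcript=TranscriptAlignment(f"t{i}", "EST", "c1", "+", chain),
                    parents=[genes[p] for p in parents],
                    overlap_bp={p: 10 for p in parents},
                )
            )
        return calls

    def test_grouping_by_ordered_tuple(self):
        calls = self._calls(
            [["A", "B"], ["A", "B"], ["B", "C"], ["A", "B", "C"]],
            [[(0, 10), (20, 30)]] * 4,
        )
        groups = {g.parent_tuple: g for g in group_calls(calls)}
        assert set(groups) == {("A", "B"), ("B", "C"), ("A", "B", "C")}
        assert groups[("A", "B")].multi_support
        assert not groups[("B", "C")].multi_support

    def test_alternative_splicing(self):
        same = self._calls(
            [["A", "B"], ["A", "B"]],
            [[(0, 10), (20, 30)], [(0, 10), (20, 35)]],  # same intron chain
        )
        diff = self._calls(
            [["A", "B"], ["A", "B"]],
            [[(0, 10), (20, 30)], [(0, 10), (22, 30)]],  # different acceptor
        )
        (g_same,) = group_calls(same)
        (g_diff,) = group_calls(diff)
        assert detect_alternative_splicing(g_same) is False
        assert detect_alternative_splicing(g_diff) is True
        (single,) = group_calls(self._calls([["A", "B"]], [[(0, 10), (20, 30)]]))
        assert detect_alternative_splicing(single) is None
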