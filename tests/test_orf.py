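import random

import pytest
from hypothesis import given, settings, strategies as st

from conjoinscan import (
    AnnotationSet,
    GeneModel,
    GenomeSequence,
    TranscriptAlignment,
    ValidationError,
    detect_conjoined,
    detect_nmd,
    predict_orf,
)
from conjoinscan.orf import classify_frames, orf_report

from _oracles import brute_force_longest_orf


class TestPredictOrf:
    @pytest.mark.parametrize(
        "seq",
        [
            "ATGAAATGA",
            "CCCATGTTTTGAATGAAAAAATAG",
            "AAATTTCCC",  # no ATG
            "ATGAAA",  # incomplete, no stop
            "ATGTGA",  # minimal complete
        ],
    )
    def test_matches_brute_force(self, seq):
        expected = brute_force_longest_orf(seq)
        got = predict_orf(seq)
        if expected is None:
            assert got is None
        else:
            assert (got.start, got.end, got.complete) == expected

    def test_longest_wins_over_first(self):
        orf = predict_orf("CCCATGTTTTGAATGAAAAAATAG")
        assert (orf.start, orf.end) == (12, 24)

    def test_random_sequences_equal_oracle(self):
        rng = random.Random(17)
        for _ in range(300):
            n = rng.randint(10, 400)
            seq = "".join(rng.choice("ACGT") for _ in range(n))
            expected = brute_force_longest_orf(seq)
            got = predict_orf(seq)
            assert (got is None) == (expected is None)
            if got:
                assert (got.start, got.end, got.complete) == expected

    @settings(max_examples=200, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=3, max_size=200))
    def test_property_equals_oracle(self, seq):
        expected = brute_force_longest_orf(seq)
        got = predict_orf(seq)
        assert (got is None) == (expected is None)
        if got:
            assert (got.start, got.end, got.complete) == expected

    def test_bad_alphabet_rejected(self):
        with pytest.raises(ValidationError):
            predict_orf("ATGXXXTAA")

    def test_annotated_cds_used_verbatim(self):
        orf = predict_orf("AAATGAAATAGAA", annotated_cds=(2, 11))
        assert (orf.start, orf.end, orf.complete) == (2, 11, True)


class TestNmdRule:
    def test_flag_flips_exactly_at_50(self):
        blocks = [(0, 500), (600, 700)]  # last junction at transcript nt 500
        from conjoinscan.orf import Orf

        for stop_end, expected in [(430, True), (450, True), (451, False), (452, False)]:
            flag, dist = detect_nmd(Orf(0, stop_end, True), blocks)
            assert dist == 500 - stop_end
            assert flag is expected

    def test_single_exon_never_candidate(self):
        from conjoinscan.orf import Orf

        flag, _ = detect_nmd(Orf(0, 99, True), [(0, 600)])
        assert flag is False

    def test_incomplete_orf_not_applicable(self):
        from conjoinscan.orf import Orf

        assert detect_nmd(Orf(0, 99, False), [(0, 500), (600, 700)]) == (None, None)


def _codon_seq(rng, n, alphabet="ACG"):
    return "".join(
        rng.choice(alphabet) + rng.choice(alphabet) + rng.choice(alphabet)
        for _ in range(n)
    )


class TestClassifyFrames:
    """Hand-built two-parent fixtures with fully controlled frames."""

    def _fixture(self, insert_len=0, rng=None):
        rng = rng or random.Random(0)
        chrom = ["C"] * 2000
        a_cds = "ATG" + _codon_seq(rng, 9) + "C" * 0
        a_cds = a_cds + _codon_seq(rng, (84 - len(a_cds)) // 3)  # 84 nt, no stop
        chrom[130:160] = a_cds[:30]
        chrom[200:254] = a_cds[30:84]
        chrom[254:257] = _codon_seq(rng, 1)
        chrom[257:260] = "TGA"  # A's own stop, excluded from the transcript
        b_cds = "ATGC" + _codon_seq(rng, 28)[:83] + "TAA"
        assert len(b_cds) == 90
        chrom[530:560] = b_cds[:30]
        chrom[600:660] = b_cds[30:90]
        genome = GenomeSequence({"c1": "".join(chrom)})
        a = GeneModel(
            "A", "A", "c1", "+",
            [(100, 160), (200, 290)],
            [(130, 160, 0), (200, 260, 0)],
        )
        b = GeneModel(
            "B", "B", "c1", "+",
            [(500, 560), (600, 690)],
            [(530, 560, 0), (600, 660, 0)],
        )
        blocks = [(100, 160), (200, 254)]
        if insert_len:
            blocks.append((450, 450 + insert_len))
        blocks += [(530, 560), (600, 690)]
        tx = TranscriptAlignment("t", "mRNA", "c1", "+", blocks)
        (call,) = detect_conjoined([tx], AnnotationSet([a, b]))
        return call, genome

    def test_in_frame_junction_is_chimeric(self):
        call, genome = self._fixture(insert_len=0)
        rep = orf_report(call, genome)
        assert {s.gene_id: s.frame_status for s in rep.per_parent} == {
            "A": "conserved",
            "B": "conserved",
        }
        assert rep.product_class == "chimeric"

    @pytest.mark.parametrize("shift", [1, 2])
    def test_frameshift_gives_downstream_different(self, shift):
        """A novel exon of length not divisible by 3 between the parents
        always shifts the downstream parent out of frame."""
        for seed in range(10):
            call, genome = self._fixture(insert_len=shift, rng=random.Random(seed))
            rep = orf_report(call, genome)
            statuses = {s.gene_id: s.frame_status for s in rep.per_parent}
            assert statuses["A"] == "conserved"
            assert statuses["B"] == "different"
            assert rep.product_class == "similar_to_5p"

    def test_orf_in_novel_sequence_only_is_novel_class(self):
        call, genome = self._fixture(insert_len=0)
        # an ORF that never touches either parent CDS
        from conjoinscan.orf import Orf

        statuses, product = classify_frames(call, Orf(0, 12, True), genome)
        assert all(s.frame_status == "no_overlap" for s in statuses)
        assert product == "novel_or_noncoding"

    def test_synonymous_changes_do_not_matter(self):
        """Frame classification depends only on coordinates."""
        call, genome = self._fixture(insert_len=0)
        rep1 = orf_report(call, genome)
        chrom = genome.sequence("c1", 0, 2000)
        # replace A's middle codons with different non-stop codons
        mutated = chrom[:203] + "GCA GCC GCG".replace(" ", "") + chrom[212:]
        rep2 = orf_report(call, GenomeSequence({"c1": mutated}))
        assert rep1.product_class == rep2.product_class
        assert [s.frame_status for s in rep1.per_parent] == [
            s.frame_status for s in rep2.per_parent
        ]


class TestOnScene:
    def test_planted_orf_classes_and_nmd_recovered(
        self, default_scene, curated_calls, truth_by_tid
    ):
        kept, _ = curated_calls
        assert len(kept) == 50
        for call in kept:
            t = truth_by_tid[call.transcript.transcript_id]
            rep = orf_report(call, default_scene.genome)
            assert rep.product_class == t.orf_class, t.class_label
            assert rep.nmd_candidate == t.nmd, t.class_label
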