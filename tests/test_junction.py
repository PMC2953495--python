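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
    detect_shs,
    extract_junction_exon,
    mutate_targets,
    search_conservation,
)
from conjoinscan.align import affine_local_align, seeded_search
from conjoinscan.junction import ConservationParams, JunctionExon, find_common_substrings
from conjoinscan.models import revcomp

from _oracles import brute_force_common_substrings, dp_local_alignment


def rand_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestAligner:
    def test_scores_equal_full_dp(self):
        """The seeded extension scores match biopython's full DP on random
        and planted-homology sequence pairs."""
        rng = random.Random(21)
        for trial in range(150):
            a = rand_dna(rng, rng.randint(10, 150))
            b = rand_dna(rng, rng.randint(10, 150))
            if trial % 2:
                seg = list(a[: rng.randint(8, min(60, len(a)))])
                for i in range(len(seg)):
                    if rng.random() < 0.1:
                        seg[i] = rng.choice("ACGT")
                pos = rng.randrange(len(b) + 1)
                b = b[:pos] + "".join(seg) + b[pos:]
            mine = affine_local_align(a, b)
            score, _, _ = dp_local_alignment(a, b)
            assert (mine.score if mine else 0) == score

    def test_identity_of_exact_copy(self):
        rng = random.Random(3)
        q = rand_dna(rng, 80)
        hit = affine_local_align(q, rand_dna(rng, 40) + q + rand_dna(rng, 40))
        assert hit.identity == 1.0 and hit.coverage_of(len(q)) == 1.0

    def test_reverse_strand_search(self):
        rng = random.Random(5)
        q = rand_dna(rng, 60)
        target = rand_dna(rng, 30) + revcomp(q) + rand_dna(rng, 30)
        hit = seeded_search(q, target)
        assert hit is not None and hit.strand == "-"
        assert hit.identity == 1.0


class TestJunctionExtraction:
    def _pair(self, strand="+"):
        if strand == "+":
            a = GeneModel("A", "A", "c1", "+", [(100, 200), (300, 400)])
            b = GeneModel("B", "B", "c1", "+", [(600, 700), (800, 900)])
        else:
            a = GeneModel("A", "A", "c1", "-", [(600, 700), (800, 900)])
            b = GeneModel("B", "B", "c1", "-", [(100, 200), (300, 400)])
        return a, b

    def _genome(self):
        rng = random.Random(77)
        return GenomeSequence({"c1": rand_dna(rng, 1000)})

    def test_spanning_region(self):
        a, b = self._pair()
        tx = TranscriptAlignment("t", "mRNA", "c1", "+", [(300, 400), (800, 900)])
        (call,) = detect_conjoined([tx], AnnotationSet([a, b]))
        junc = extract_junction_exon(call, self._genome())
        assert junc.mode == "spanning_region"
        assert len(junc.spliced_seq) == 200
        assert junc.breakpoint == 100

    def test_single_exon_mode(self):
        """One block crossing both parents' exonic territory."""
        a = GeneModel("A", "A", "c1", "+", [(100, 200), (300, 400)])
        b = GeneModel("B", "B", "c1", "+", [(600, 700), (800, 900)])
        tx = TranscriptAlignment("t", "mRNA", "c1", "+", [(100, 200), (380, 650)])
        (call,) = detect_conjoined([tx], AnnotationSet([a, b]))
        junc = extract_junction_exon(call, self._genome())
        assert junc.mode == "single_exon"
        # upstream exonic overlap ends at 400; gap 400..600 is ambiguous,
        # so the cut falls at its midpoint (500), offset 120 in the block
        assert junc.breakpoint_ambiguous
        assert junc.breakpoint == 120

    def test_minus_strand_reverse_complement(self):
        genome = self._genome()
        a, b = self._pair("-")
        tx = TranscriptAlignment("t", "mRNA", "c1", "-", [(300, 400), (800, 900)])
        (call,) = detect_conjoined([tx], AnnotationSet([a, b]))
        junc = extract_junction_exon(call, genome)
        plus = genome.sequence("c1", 300, 400) + genome.sequence("c1", 800, 900)
        assert junc.spliced_seq == revcomp(plus)
        assert junc.breakpoint == 100  # A's block (800,900) contributes first


class TestSHS:
    def _junction(self, w5, w3):
        return JunctionExon("x", "spanning_region", (0, 1), w5 + w3, len(w5))

    def test_planted_repeat_found(self):
        hits = detect_shs(self._junction("C" * 16 + "ACGT", "ACGT" + "G" * 16))
        assert hits[0].sequence == "ACGT"
        assert hits[0].offset_5p == 16 and hits[0].offset_3p == 0

    def test_length_three_never_reported(self):
        """Repeats below the 4 bp floor are not SHS."""
        hits = detect_shs(self._junction("G" * 17 + "ACT", "ACT" + "G" * 17))
        assert all(h.length >= 4 for h in hits)
        assert not any("ACT" == h.sequence for h in hits)

    def test_equals_brute_force_enumeration(self):
        rng = random.Random(13)
        for _ in range(300):
            w5 = rand_dna(rng, 20)
            w3 = rand_dna(rng, 20)
            got = {h.sequence for h in find_common_substrings(w5, w3, 4)}
            assert got == brute_force_common_substrings(w5, w3, 4)

    @settings(max_examples=150, deadline=None)
    @given(
        st.text(alphabet="ACGT", min_size=4, max_size=20),
        st.text(alphabet="ACGT", min_size=4, max_size=20),
    )
    def test_property_equals_brute_force(self, w5, w3):
        got = {h.sequence for h in find_common_substrings(w5, w3, 4)}
        assert got == brute_force_common_substrings(w5, w3, 4)

    def test_on_scene_truth(self, default_scene, curated_calls, truth_by_tid):
        kept, _ = curated_calls
        for call in kept:
            t = truth_by_tid[call.transcript.transcript_id]
            junc = extract_junction_exon(call, default_scene.genome)
            assert junc.breakpoint == t.breakpoint
            hits = detect_shs(junc)
            assert (hits[0].length if hits else 0) == t.shs_max_len


class TestConservation:
    def _junction(self, seq):
        return JunctionExon("j", "spanning_region", (0, len(seq)), seq, len(seq) // 2)

    def test_verbatim_target_hits(self):
        rng = random.Random(31)
        seq = rand_dna(rng, 300)
        junc = self._junction(seq)
        (hit,) = search_conservation(junc, {"m1": rand_dna(rng, 50) + seq + rand_dna(rng, 50)})
        assert hit.coverage == 1.0 and hit.identity == 1.0

    def test_heavy_mutation_rejected(self):
        rng = random.Random(32)
        seq = rand_dna(rng, 300)
        junc = self._junction(seq)
        mutated = mutate_targets({"m": seq}, 0.15, seed=1)
        assert search_conservation(junc, mutated) == []

    def test_half_coverage_rejected(self):
        rng = random.Random(33)
        seq = rand_dna(rng, 300)
        junc = self._junction(seq)
        assert search_conservation(junc, {"m": seq[: len(seq) // 2]}) == []

    def test_reverse_complement_target_same_metrics(self):
        rng = random.Random(34)
        seq = rand_dna(rng, 240)
        junc = self._junction(seq)
        fwd = search_conservation(junc, {"m": seq})
        rev = search_conservation(junc, {"m": revcomp(seq)})
        assert fwd[0].coverage == rev[0].coverage
        assert fwd[0].identity == rev[0].identity
        assert (fwd[0].strand, rev[0].strand) == ("+", "-")

    def test_short_junction_raises(self):
        with pytest.raises(ValidationError):
            search_conservation(self._junction("ACGTACG"), {"m": "ACGT"})

    def test_empty_targets_raise(self):
        with pytest.raises(ValidationError):
            search_conservation(self._junction("ACGT" * 20), {})

    def test_mutation_rate_thresholds(self):
        """2%-mutated copies pass the 90/90 gate; 15%-mutated copies fail,
        in >= 95% of replicates each (binomial separation)."""
        rng = random.Random(40)
        n = 60
        seq = rand_dna(rng, 400)
        junc = self._junction(seq)
        lo = mutate_targets({f"t{i}": seq for i in range(n)}, 0.02, seed=2)
        hi = mutate_targets({f"t{i}": seq for i in range(n)}, 0.15, seed=3)
        n_lo = len(search_conservation(junc, lo))
        n_hi = len(search_conservation(junc, hi))
        assert n_lo >= 0.95 * n
        assert n_hi <= 0.05 * n
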