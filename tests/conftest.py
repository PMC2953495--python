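import random

import pytest

from conjoinscan import (
    AnnotationSet,
    GeneModel,
    GenomeSequence,
    TranscriptAlignment,
    curate,
    detect_conjoined,
)
from conjoinscan.simulate import SimConfig, simulate_scene


@pytest.fixture(scope="session")
def default_scene():
    """The default simulated study scene: 50 planted CGs, 50 negatives."""
    return simulate_scene(SimConfig(seed=1))


@pytest.fixture(scope="session")
def curated_calls(default_scene):
    scene = default_scene
    calls = detect_conjoined(scene.alignments, scene.annotation)
    kept, rejected = curate(calls, scene.genome)
    return kept, rejected


@pytest.fixture(scope="session")
def truth_by_tid(default_scene):
    return {t.transcript_id: t for t in default_scene.truth}


@pytest.fixture()
def toy_two_gene_scene():
    """Tiny hand-built fixture: genes A and B on '+' with a linking transcript."""
    a = GeneModel("A", "A", "c1", "+", [(100, 200), (300, 400)])
    b = GeneModel("B", "B", "c1", "+", [(600, 700), (800, 900)])
    ann = AnnotationSet([a, b])
    tx = TranscriptAlignment("t1", "mRNA", "c1", "+", [(300, 400), (600, 700)])
    return ann, tx


def random_annotation(rng: random.Random, n_genes: int, chrom_len: int = 50_000):
    """Random gene models for oracle-equivalence tests (no genome needed)."""
    genes = []
    for i in range(n_genes):
        strand = rng.choice("+-")
        pos = rng.randrange(0, chrom_len - 2000)
        exons = []
        for _ in range(rng.randint(1, 5)):
            length = rng.randint(30, 200)
            exons.append((pos, pos + length))
            pos += length + rng.randint(30, 500)
            if pos >= chrom_len:
                break
        genes.append(GeneModel(f"g{i:03d}", f"g{i:03d}", "c1", strand, exons))
    return AnnotationSet(genes)


def random_transcripts(rng: random.Random, n: int, chrom_len: int = 50_000):
    out = []
    for i in range(n):
        strand = rng.choice("+-")
        pos = rng.randrange(0, chrom_len - 3000)
        blocks = []
        for _ in range(rng.randint(1, 6)):
            length = rng.randint(30, 300)
            blocks.append((pos, pos + length))
            pos += length + rng.randint(40, 1500)
            if pos >= chrom_len:
                break
        out.append(TranscriptAlignment(f"t{i:03d}", "EST", "c1", strand, blocks))
    return out
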