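"""Independent brute-force oracles used to validate the implementation.

Every function here recomputes a quantity by the most direct method
available (exhaustive enumeration, full dynamic programming via biopython,
direct arithmetic) without sharing code paths with the package internals.
"""

from __future__ import annotations

from Bio import Align

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_cg_parents(alignments, annotation, min_overlap=1):
    """(transcript_id -> frozenset of parent gene_ids) by double loop."""
    out = {}
    for tx in alignments:
        parents = set()
        for gene in annotation:
            if gene.chrom != tx.chrom or gene.strand != tx.strand:
                continue
            total = 0
            for bs, be in tx.blocks:
                for xs, xe in gene.exons:
                    total += max(0, min(be, xe) - max(bs, xs))
            if total >= min_overlap:
                parents.add(gene.gene_id)
        if len(parents) >= 2:
            out[tx.transcript_id] = frozenset(parents)
    return out


def brute_force_orfs(seq):
    """All (start, end, complete) ATG-initiated reading frames, end included
    through the stop codon or truncated to a codon multiple at the 3' end."""
    seq = seq.upper()
    orfs = []
    for start in range(len(seq) - 2):
        if seq[start : start + 3] != "ATG":
            continue
        end, complete = None, False
        for p in range(start, len(seq) - 2, 3):
            if seq[p : p + 3] in STOPS:
                end, complete = p + 3, True
                break
        if end is None:
            end = start + (len(seq) - start) // 3 * 3
        if end - start >= 3:
            orfs.append((start, end, complete))
    return orfs


def brute_force_longest_orf(seq):
    orfs = brute_force_orfs(seq)
    if not orfs:
        return None
    best_len = max(e - s for s, e, _ in orfs)
    return min((o for o in orfs if o[1] - o[0] == best_len), key=lambda o: o[0])


def brute_force_common_substrings(a, b, min_len):
    """All maximal common substrings: common, >= min_len, and not a proper
    substring of another common substring."""
    common = set()
    for i in range(len(a)):
        for j in range(i + min_len, len(a) + 1):
            sub = a[i:j]
            if sub in b:
                common.add(sub)
    return {s for s in common if not any(s != t and s in t for t in common)}


def dp_local_alignment(query, target):
    """Full-DP local alignment via biopython, same scoring as the package
    aligner (match +1, mismatch -1, gap of length L costs 2 + L).

    Returns (score, coverage_of_query, identity) of the best alignment.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1
    alns = aligner.align(query, target)
    if len(alns) == 0 or alns.score <= 0:
        return 0, 0.0, 0.0
    aln = alns[0]
    qa, ta = aln.aligned
    matches = 0
    columns = 0
    for (qs, qe), (ts, te) in zip(qa, ta):
        for qi, ti in zip(range(qs, qe), range(ts, te)):
            columns += 1
            matches += query[qi] == target[ti]
    # count gap columns between aligned segments
    for k in range(1, len(qa)):
        columns += (qa[k][0] - qa[k - 1][1]) + (ta[k][0] - ta[k - 1][1])
    q_span = qa[-1][1] - qa[0][0]
    coverage = q_span / len(query) if query else 0.0
    identity = matches / columns if columns else 0.0
    return int(alns.score), coverage, identity
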