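"""Seed-and-extend local alignment.

A small BLAT-like engine: exact k-mer seeds decide whether (and on which
strand) a pair of sequences is worth aligning, and the extension is an
affine-gap Smith-Waterman computed column-wise with numpy. Scoring follows
match +1 / mismatch -1, and a gap of length L costs open + L * extend
(default 2 + L), i.e. the first gap base costs open + extend.

Used for the paralog curation filter and for junction-exon conservation
search; the 90/90 coverage/identity thresholds live with the callers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .models import revcomp

NEG_INF = np.int32(-(10**9))


@dataclass
class LocalAlignment:
    """One local alignment between a query and a target."""

    score: int
    q_start: int
    q_end: int  # half-open in query coordinates
    t_start: int
    t_end: int
    matches: int
    aligned_columns: int
    strand: str = "+"  # strand of the target relative to the query
    column_matches: Optional[list] = None  # per-column match flags, 5'->3'

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_columns if self.aligned_columns else 0.0

    def coverage_of(self, query_length: int) -> float:
        """Fraction of the query spanned by the alignment."""
        return (self.q_end - self.q_start) / query_length if query_length else 0.0

    def has_identity_window(self, min_len: int, min_identity: float) -> bool:
        """Is there a contiguous stretch of >= min_len alignment columns at
        >= min_identity? Robust to score-optimal extensions into noisy
        flanks diluting the whole-alignment identity."""
        flags = self.column_matches or []
        n = len(flags)
        if n < min_len:
            return False
        prefix = [0] * (n + 1)
        for i, f in enumerate(flags):
            prefix[i + 1] = prefix[i] + f
        for i in range(n - min_len + 1):
            # the longest qualifying window starting at i is found greedily;
            # checking all end points keeps it exact
            for j in range(i + min_len, n + 1):
                if prefix[j] - prefix[i] >= min_identity * (j - i):
                    return True
        return False


def has_shared_kmer(a: str, b: str, k: int = 11) -> bool:
    """Seed test: do the two sequences share any exact k-mer?"""
    if len(a) < k or len(b) < k:
        return False
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    return any(b[j : j + k] in kmers for j in range(len(b) - k + 1))


def affine_local_align(
    query: str,
    target: str,
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = 2,
    gap_extend: int = 1,
) -> Optional[LocalAlignment]:
    """Full affine-gap Smith-Waterman with traceback.

    Returns None when the best local score is 0 (no positive-scoring pair).
    Ties are broken toward diagonal moves, giving compact alignments.
    """
    n, m = len(query), len(target)
    if n == 0 or m == 0:
        return None
    if n * m > 40_000_000:
        raise ValueError("sequences too long for full DP; pre-filter with seeds")
    oe = gap_open + gap_extend
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)

    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)  # gap consuming target
    F = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)  # gap consuming query
    idx = np.arange(1, n + 1, dtype=np.int32)
    for j in range(1, m + 1):
        sub = np.where(q == t[j - 1], match, mismatch).astype(np.int32)
        diag = H[:-1, j - 1] + sub
        E[1:, j] = np.maximum(H[1:, j - 1] - oe, E[1:, j - 1] - gap_extend)
        cand = np.maximum.reduce([diag, E[1:, j], np.zeros(n, dtype=np.int32)])
        # vertical gaps via a decayed prefix max over candidate cell values:
        # F[i] = max_{k<i} cand[k] - gap_open - (i-k)*gap_extend
        a = np.empty(n + 1, dtype=np.int64)
        a[0] = 0  # k = 0 boundary (H[0][j] = 0)
        a[1:] = cand.astype(np.int64) + idx * gap_extend
        prefix = np.maximum.accumulate(a[:-1])
        F[1:, j] = (prefix - gap_open - idx * gap_extend).astype(np.int32)
        H[1:, j] = np.maximum(cand, F[1:, j])

    score = int(H.max())
    if score <= 0:
        return None
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    i, j = int(i), int(j)
    q_end, t_end = i, j
    flags: list = []
    state = "M"
    while i > 0 and j > 0:
        if state == "M":
            if H[i, j] == 0:
                break
            sub = match if query[i - 1] == target[j - 1] else mismatch
            if H[i, j] == H[i - 1, j - 1] + sub:
                flags.append(query[i - 1] == target[j - 1])
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            flags.append(False)
            nxt = "M" if E[i, j] == H[i, j - 1] - oe else "E"
            j -= 1
            state = nxt
        else:  # F
            flags.append(False)
            nxt = "M" if F[i, j] == H[i - 1, j] - oe else "F"
            i -= 1
            state = nxt
    flags.reverse()
    return LocalAlignment(
        score=score,
        q_start=i,
        q_end=q_end,
        t_start=j,
        t_end=t_end,
        matches=int(sum(flags)),
        aligned_columns=len(flags),
        column_matches=flags,
    )


def best_local_alignment(
    a: str, b: str, k: int = 11, **scoring
) -> Optional[LocalAlignment]:
    """Seeded best local alignment of two same-orientation sequences.

    Returns None immediately when no exact k-mer is shared (unrelated
    sequences), otherwise runs the full extension DP.
    """
    if not has_shared_kmer(a, b, k):
        return None
    return affine_local_align(a, b, **scoring)


def seeded_search(
    query: str, target: str, k: int = 11, **scoring
) -> Optional[LocalAlignment]:
    """Best seeded local alignment of query against either strand of target."""
    best: Optional[LocalAlignment] = None
    for strand, tseq in (("+", target), ("-", revcomp(target))):
        if not has_shared_kmer(query, tseq, k):
            continue
        hit = affine_local_align(query, tseq, **scoring)
        if hit is not None:
            hit.strand = strand
            if best is None or hit.score > best.score:
                best = hit
    return best
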