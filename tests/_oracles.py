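"""Independent oracles used to cross-check the package's aligners.

These are deliberately naive: a full three-matrix affine-gap Smith--Waterman
in pure Python, an exponential recursive alignment enumerator for very short
sequences, and an exhaustive ungapped evaluation of the identity/length
recruitment criterion.  None of them share code with the implementation.
"""

from __future__ import annotations

import math

import numpy as np
from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def sw_affine_score(q: str, s: str, gap_open: float = 11.0, gap_extend: float = 1.0,
                    matrix=BLOSUM62) -> float:
    """Optimal local alignment score, full 3-matrix Gotoh recurrence.

    A gap of length k costs gap_open + k * gap_extend.
    """
    n, m = len(q), len(s)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in query (consumes subject)
    F = np.full((n + 1, m + 1), NEG)  # gap in subject (consumes query)
    best = 0.0
    go = gap_open + gap_extend
    ge = gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] - ge, H[i][j - 1] - go)
            F[i][j] = max(F[i - 1][j] - ge, H[i - 1][j] - go)
            sub = matrix[q[i - 1], s[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def enumerate_local_score(q: str, s: str, gap_open: float = 11.0,
                          gap_extend: float = 1.0, matrix=BLOSUM62) -> float:
    """Best local score by explicit recursion over alignment extensions.

    Exponential; only usable for len <= ~8.  Cross-checks the DP oracle.
    """
    go = gap_open + gap_extend
    ge = gap_extend

    def extend(i: int, j: int, state: str) -> float:
        # best score of continuing an alignment at (i, j); may stop (0)
        best = 0.0
        if i < len(q) and j < len(s):
            best = max(best, matrix[q[i], s[j]] + extend(i + 1, j + 1, "M"))
        if j < len(s):
            cost = ge if state == "E" else go
            best = max(best, -cost + extend(i, j + 1, "E"))
        if i < len(q):
            cost = ge if state == "F" else go
            best = max(best, -cost + extend(i + 1, j, "F"))
        return best

    best = 0.0
    for i in range(len(q)):
        for j in range(len(s)):
            best = max(best, matrix[q[i], s[j]] + extend(i + 1, j + 1, "M"))
    return best


def verify_witness(read: str, candidate: str, witness, strand: str,
                   min_identity: float = 0.9,
                   min_length_fraction: float = 0.9) -> bool:
    """Independently verify a recruitment certificate against raw sequences.

    The witness is a list of (read index | None, candidate index | None)
    alignment columns; it must be a valid monotone alignment window covering
    at least min_length_fraction of the read at min_identity over its
    columns.
    """
    if not witness:
        return False
    seq = read if strand == "+" else read.translate(
        str.maketrans("ACGTN", "TGCAN"))[::-1]
    prev_q = prev_t = None
    matches = 0
    coverage = 0
    for q_i, t_i in witness:
        if q_i is None and t_i is None:
            return False
        if q_i is not None:
            if prev_q is not None and q_i != prev_q + 1:
                return False
            if not 0 <= q_i < len(seq):
                return False
            prev_q = q_i
            coverage += 1
        if t_i is not None:
            if prev_t is not None and t_i != prev_t + 1:
                return False
            if not 0 <= t_i < len(candidate):
                return False
            prev_t = t_i
        if q_i is not None and t_i is not None and seq[q_i] == candidate[t_i]:
            matches += 1
    if coverage < math.ceil(min_length_fraction * len(read)):
        return False
    return matches >= min_identity * len(witness) - 1e-9


def ungapped_criterion(read: str, candidate: str, min_identity: float = 0.9,
                       min_length_fraction: float = 0.9) -> bool:
    """Exhaustive ungapped evaluation of the recruitment criterion.

    Both read orientations, every diagonal placement of the read against the
    candidate, and every contiguous window covering at least
    min_length_fraction of the read are examined.
    """
    L = len(read)
    min_w = math.ceil(min_length_fraction * L)
    rc = read.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
    for seq in (read, rc):
        for offset in range(-(L - min_w), len(candidate) - min_w + 1):
            lo = max(0, -offset)
            hi = min(L, len(candidate) - offset)
            if hi - lo < min_w:
                continue
            mism = np.array(
                [seq[i] != candidate[i + offset] for i in range(lo, hi)]
            )
            cs = np.concatenate([[0], np.cumsum(mism)])
            n = len(mism)
            for w in range(n, min_w - 1, -1):
                # matches/w >= min_identity, guarded against float round-off
                allowed = (1.0 - min_identity) * w + 1e-9
                if (cs[w:] - cs[:-w]).min() <= allowed:
                    return True
    return False
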