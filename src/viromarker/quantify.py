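"""Read quality filtering, 90/90 recruitment, and abundance normalization.

Reads pass QC when their mean per-base probability of being correct
(1 - 10^(-Q/10), averaged over the read) reaches the floor (default 0.3).
A read is recruited to a candidate when some local alignment covers at least
the length fraction of the read (default 90%) at or above the identity
fraction (default 90%, identity counted over aligned columns including
gaps).  Raw counts are normalized per kb of extracted candidate per million
QC-passed reads, an RPKM-style unit whose global scale cancels in all
downstream correlation work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

__all__ = [
    "ReadRecruitmentParams",
    "AbundanceMatrix",
    "quality_filter",
    "read_score",
    "passes_9090",
    "recruit_reads",
    "normalize",
    "aggregate_by_type",
]


@dataclass
class ReadRecruitmentParams:
    min_identity: float = 0.90
    min_length_fraction: float = 0.90
    kmer_size: int = 15
    quality_floor: float = 0.3
    # blastn-like scoring used to propose local alignments
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1 and 0 < self.min_length_fraction <= 1):
            raise ValueError("identity and length fractions must be in (0, 1]")

    def make_aligner(self) -> Align.PairwiseAligner:
        cached = getattr(self, "_aligner", None)
        if cached is not None:
            return cached
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = self.match
        aligner.mismatch_score = self.mismatch
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        object.__setattr__(self, "_aligner", aligner)
        return aligner


def read_score(quals: Sequence[int]) -> float:
    """Mean per-base probability of correctness."""
    if len(quals) == 0:
        return 0.0
    q = np.asarray(quals, dtype=float)
    return float(np.mean(1.0 - 10.0 ** (-q / 10.0)))


def quality_filter(
    reads: Iterable[tuple[str, str, Sequence[int]]], floor: float = 0.3
) -> tuple[list[tuple[str, str, Sequence[int]]], int]:
    """Drop reads whose score falls below the floor; returns (passed, library size)."""
    passed = [r for r in reads if read_score(r[2]) >= floor]
    return passed, len(passed)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _alignment_path(aln) -> list[tuple[int | None, int | None]]:
    """Alignment path as (query index | None, target index | None) columns.

    Gap columns consume a position on exactly one side.  The path is extended
    outward along its end diagonals to cover the whole read (clipped at the
    target ends): the optimal-score path may trim a mismatch-dense read end
    that a qualifying lower-scoring window still needs.
    """
    q_blocks, t_blocks = aln.aligned
    query_len = len(aln.sequences[0])
    target_len = len(aln.sequences[1])
    cols: list[tuple[int | None, int | None]] = []
    qs0, ts0 = int(q_blocks[0][0]), int(t_blocks[0][0])
    lead = min(qs0, ts0)
    cols.extend(zip(range(qs0 - lead, qs0), range(ts0 - lead, ts0)))
    prev_q = prev_t = None
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        if prev_q is not None:
            cols.extend((q_i, None) for q_i in range(prev_q, qs))
            cols.extend((None, t_i) for t_i in range(prev_t, ts))
        cols.extend(zip(range(qs, qe), range(ts, te)))
        prev_q, prev_t = qe, te
    trail = min(query_len - prev_q, target_len - prev_t)
    cols.extend(zip(range(prev_q, prev_q + trail), range(prev_t, prev_t + trail)))
    return cols


def _cumulatives(
    cols: list[tuple[int | None, int | None]], query: str, target: str
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative (query positions consumed, matches) over path columns."""
    dq = np.zeros(len(cols) + 1, dtype=int)
    dm = np.zeros(len(cols) + 1, dtype=int)
    for k, (q_i, t_i) in enumerate(cols):
        dq[k + 1] = dq[k] + (q_i is not None)
        dm[k + 1] = dm[k] + (
            q_i is not None and t_i is not None and query[q_i] == target[t_i]
        )
    return dq, dm


@dataclass(frozen=True)
class RecruitmentDecision:
    """Accept/reject decision with its certificate.

    ``witness`` is the accepted window of the alignment path as
    (read index | None, candidate index | None) columns on the strand given
    by ``strand``, so the qualification can be re-verified from the raw
    sequences.
    """

    accepted: bool
    identity: float
    witness: list[tuple[int | None, int | None]] | None = None
    strand: str = "+"

    def __iter__(self):  # unpacks like (accepted, identity)
        return iter((self.accepted, self.identity))

    def __bool__(self) -> bool:
        return self.accepted

    def __getitem__(self, i):
        return (self.accepted, self.identity, self.witness, self.strand)[i]


def passes_9090(
    read_seq: str,
    candidate_seq: str,
    params: ReadRecruitmentParams | None = None,
) -> RecruitmentDecision:
    """Does some local alignment satisfy the identity/length-fraction rule?

    The best-scoring local alignment is computed (both read orientations),
    extended to full read span along its end diagonals, and every contiguous
    sub-alignment is examined: the read is recruited if a window exists that
    covers >= min_length_fraction of the read with identity >= min_identity
    over its columns (gap columns included in the denominator).  The
    accepting window is returned as a verifiable certificate.
    """
    params = params or ReadRecruitmentParams()
    aligner = params.make_aligner()
    best = RecruitmentDecision(False, 0.0)
    min_q = math.ceil(params.min_length_fraction * len(read_seq))
    for strand, seq in (("+", read_seq), ("-", _revcomp(read_seq))):
        score = aligner.score(seq, candidate_seq)
        if score <= 0:
            continue
        aln = aligner.align(seq, candidate_seq)[0]
        cols = _alignment_path(aln)
        if not cols:
            continue
        cq, cm = _cumulatives(cols, seq, candidate_seq)
        identity = cm[-1] / len(cols)
        # accept iff exists i<j with cq[j]-cq[i] >= min_q and
        # cm[j]-cm[i] >= min_identity*(j-i)
        g = cm - params.min_identity * np.arange(len(cm))
        j_first = np.searchsorted(cq, cq + min_q, side="left")
        suffix_max = np.maximum.accumulate(g[::-1])[::-1]
        witness = None
        valid = np.flatnonzero(j_first < len(g))
        for i in valid:
            j0 = j_first[i]
            if suffix_max[j0] >= g[i] - 1e-12:
                j = j0 + int(np.flatnonzero(g[j0:] >= g[i] - 1e-12)[0])
                witness = cols[i:j]
                break
        if witness is not None and (not best.accepted or identity > best.identity):
            best = RecruitmentDecision(True, float(identity), witness, strand)
        elif not best.accepted and identity > best.identity:
            best = RecruitmentDecision(False, float(identity))
    return best


class _KmerIndex:
    """Exact k-mer index over candidate sequences (both strands via read rc)."""

    def __init__(self, candidates: Mapping[str, str], k: int):
        self.k = k
        self.index: dict[str, set[str]] = {}
        for cand_id, seq in candidates.items():
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i : i + k], set()).add(cand_id)

    def candidates_for(self, read_seq: str) -> set[str]:
        k = self.k
        hits: set[str] = set()
        for seq in (read_seq, _revcomp(read_seq)):
            for i in range(len(seq) - k + 1):
                hits |= self.index.get(seq[i : i + k], set())
        return hits


def recruit_reads(
    reads_by_sample: Mapping[str, Iterable[tuple[str, str, Sequence[int]]]],
    candidates: Mapping[str, str],
    params: ReadRecruitmentParams | None = None,
    prefiltered: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Raw recruited-read counts per candidate per sample.

    Reads failing QC are removed first (unless ``prefiltered``); library sizes
    are QC-passed read counts.  Multi-mapping reads go to the candidate with
    the best alignment identity, exact ties to the lexicographically smallest
    candidate id.
    """
    if not candidates:
        raise ValueError("no candidate sequences to recruit against")
    params = params or ReadRecruitmentParams()
    index = _KmerIndex(candidates, params.kmer_size)
    samples = list(reads_by_sample)
    counts = pd.DataFrame(0, index=sorted(candidates), columns=samples, dtype=int)
    library_sizes = pd.Series(0, index=samples, dtype=int)
    for sample in samples:
        reads = list(reads_by_sample[sample])
        if not prefiltered:
            reads, libsize = quality_filter(reads, params.quality_floor)
        else:
            libsize = len(reads)
        library_sizes[sample] = libsize
        for _, seq, _quals in reads:
            hits = []
            for cand_id in sorted(index.candidates_for(seq)):
                ok, identity = passes_9090(seq, candidates[cand_id], params)
                if ok:
                    hits.append((-identity, cand_id))
            if hits:
                hits.sort()
                counts.at[hits[0][1], sample] += 1
    return counts, library_sizes


@dataclass
class AbundanceMatrix:
    """Normalized candidate x sample expression with its sidecars."""

    data: pd.DataFrame  # normalized (per kb per million QC-passed reads)
    raw: pd.DataFrame
    lengths: pd.Series  # candidate lengths, nt
    library_sizes: pd.Series
    meta: pd.DataFrame | None = None  # candidate -> category, role


def normalize(
    raw: pd.DataFrame, lengths: pd.Series, library_sizes: pd.Series
) -> AbundanceMatrix:
    """value = count / ((length/1000) * (library/1e6))."""
    lengths = lengths.reindex(raw.index)
    library_sizes = library_sizes.reindex(raw.columns)
    if (lengths <= 0).any():
        raise ValueError("candidate lengths must be positive")
    if (library_sizes <= 0).any():
        bad = library_sizes.index[library_sizes <= 0].tolist()
        raise ValueError(f"zero or negative library size for samples {bad}")
    denom = np.outer(lengths / 1000.0, library_sizes / 1e6)
    data = raw / denom
    return AbundanceMatrix(
        data=data, raw=raw, lengths=lengths, library_sizes=library_sizes
    )


def aggregate_by_type(
    matrix: pd.DataFrame, categories: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Sum normalized values per category per sample, plus per-candidate
    totals over samples (the per-candidate expression ring)."""
    missing = [c for c in matrix.index if c not in categories]
    if missing:
        raise ValueError(f"candidates without a category: {missing}")
    cats = pd.Series({c: categories[c] for c in matrix.index})
    type_matrix = matrix.groupby(cats).sum()
    per_candidate_totals = matrix.sum(axis=1)
    return type_matrix, per_candidate_totals
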