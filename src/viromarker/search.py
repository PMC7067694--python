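"""Translated homology search of marker proteins against nucleotide contigs.

Contigs are translated in all six frames and each frame is aligned locally
(Smith--Waterman, affine gaps, BLOSUM62 by default) against every protein in a
marker panel.  Significance is assessed with Karlin--Altschul statistics
(E = K*m*n*exp(-lambda*S)), mirroring what a translated BLAST search reports.
Externally produced 12-column tabular hits can be ingested into the same
record type, so downstream candidate extraction is agnostic to the search
engine that produced the hits.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "AlignmentHit",
    "SearchParams",
    "FrameTranslation",
    "translate_six_frames",
    "local_align_protein",
    "estimate_evalue",
    "bit_score",
    "search_contigs",
    "parse_tabular_hits",
    "write_tabular_hits",
]

_NUCLEOTIDES = set("ACGTN")


@functools.lru_cache(maxsize=None)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@dataclass(frozen=True)
class AlignmentHit:
    """A protein-vs-translated-nucleotide local alignment.

    Nucleotide coordinates are 0-based half-open on the forward strand of the
    query contig; subject coordinates are 0-based half-open amino-acid
    positions.  ``frame`` is 1..3 on the strand given by ``strand`` and is
    ``None`` for hits parsed from tabular files (the format does not carry it).
    """

    query_id: str
    subject_id: str
    bit_score: float
    evalue: float
    q_start_nt: int
    q_end_nt: int
    strand: str
    s_start_aa: int
    s_end_aa: int
    aligned_aa_length: int
    percent_identity: float
    mismatches: int = 0
    gap_opens: int = 0
    raw_score: float | None = None
    frame: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.q_start_nt < self.q_end_nt:
            raise ValueError(
                f"invalid query interval [{self.q_start_nt}, {self.q_end_nt})"
            )
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent identity outside [0, 100]")


@dataclass
class SearchParams:
    """Scoring and significance parameters for the translated search.

    Defaults are the standard gapped BLASTx constants: BLOSUM62 with gap open
    11 / extend 1 and lambda = 0.267, K = 0.041.  A gap of length k costs
    ``gap_open + k * gap_extend``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lam: float = 0.267
    karlin_k: float = 0.041
    max_evalue: float = 10.0

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lam <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")

    def make_aligner(self) -> Align.PairwiseAligner:
        cached = getattr(self, "_aligner", None)
        if cached is not None:
            return cached
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = _load_matrix(self.matrix_name)
        # Biopython charges open_gap_score for the first gap column and
        # extend_gap_score for each further column; BLAST's open/extend
        # convention (cost = open + k*extend) therefore maps as below.
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        object.__setattr__(self, "_aligner", aligner)
        return aligner


@dataclass(frozen=True)
class FrameTranslation:
    strand: str
    frame: int
    protein: str


def _validate_nucleotides(seq: str) -> None:
    for i, c in enumerate(seq):
        if c not in _NUCLEOTIDES:
            raise ValueError(f"invalid nucleotide {c!r} at position {i}")


def translate_six_frames(seq: str) -> list[FrameTranslation]:
    """Translate ``seq`` in all six frames with the standard genetic code.

    Stop codons are retained as ``*`` and codons containing ``N`` translate to
    ``X``.  Frame f on either strand has length ``(len(seq) - (f - 1)) // 3``.
    """
    seq = seq.upper()
    _validate_nucleotides(seq)
    out: list[FrameTranslation] = []
    for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        for frame in (1, 2, 3):
            sub = s[frame - 1 :]
            sub = sub[: len(sub) - len(sub) % 3]
            prot = str(Seq(sub).translate()) if sub else ""
            out.append(FrameTranslation(strand, frame, prot))
    return out


@dataclass(frozen=True)
class LocalAlignment:
    """Optimal local protein alignment with match statistics."""

    score: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    identities: int
    mismatches: int
    gap_columns: int
    gap_opens: int

    @property
    def n_columns(self) -> int:
        return self.identities + self.mismatches + self.gap_columns

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.identities / self.n_columns if self.n_columns else 0.0


_EMPTY_ALIGNMENT = LocalAlignment(0.0, 0, 0, 0, 0, 0, 0, 0, 0)


def local_align_protein(
    query_aa: str, subject_aa: str, params: SearchParams | None = None
) -> LocalAlignment:
    """Optimal Smith--Waterman local alignment of two protein strings.

    Returns the empty alignment (score 0) when no positive-scoring pair of
    residues exists, matching the Smith--Waterman floor.
    """
    if not query_aa or not subject_aa:
        raise ValueError("sequences must be non-empty")
    params = params or SearchParams()
    aligner = params.make_aligner()
    score = aligner.score(query_aa, subject_aa)
    if score <= 0:
        return _EMPTY_ALIGNMENT
    aln = aligner.align(query_aa, subject_aa)[0]
    q_blocks, s_blocks = aln.aligned
    identities = 0
    gap_columns = 0
    gap_opens = 0
    prev_q_end: int | None = None
    prev_s_end: int | None = None
    n_residue_cols = 0
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        if prev_q_end is not None:
            gq = qs - prev_q_end
            gs = ss - prev_s_end
            gap_columns += gq + gs
            gap_opens += (gq > 0) + (gs > 0)
        for a, b in zip(query_aa[qs:qe], subject_aa[ss:se]):
            identities += a == b
        n_residue_cols += qe - qs
        prev_q_end, prev_s_end = qe, se
    mismatches = n_residue_cols - identities
    return LocalAlignment(
        score=float(score),
        q_start=int(q_blocks[0][0]),
        q_end=int(q_blocks[-1][1]),
        s_start=int(s_blocks[0][0]),
        s_end=int(s_blocks[-1][1]),
        identities=identities,
        mismatches=mismatches,
        gap_columns=gap_columns,
        gap_opens=gap_opens,
    )


def estimate_evalue(
    raw_score: float, params: SearchParams, m: int, n: int
) -> float:
    """Karlin--Altschul expect value: E = K * m * n * exp(-lambda * S)."""
    if m <= 0 or n <= 0:
        raise ValueError("search-space sizes m and n must be positive")
    return params.karlin_k * m * n * math.exp(-params.lam * raw_score)


def bit_score(raw_score: float, params: SearchParams) -> float:
    """Normalized score: (lambda*S - ln K) / ln 2."""
    return (params.lam * raw_score - math.log(params.karlin_k)) / math.log(2.0)


def _aa_to_nt_interval(
    aa_start: int, aa_end: int, frame: int, strand: str, contig_len: int
) -> tuple[int, int]:
    """Map a frame-local amino-acid interval to forward-strand nt coordinates."""
    nt_start = (frame - 1) + 3 * aa_start
    nt_end = (frame - 1) + 3 * aa_end
    if strand == "+":
        return nt_start, nt_end
    return contig_len - nt_end, contig_len - nt_start


def search_contigs(
    contigs: Mapping[str, str],
    panel: Sequence,
    params: SearchParams | None = None,
) -> list[AlignmentHit]:
    """Search every contig against a marker panel, best hit per strand/frame.

    ``panel`` is a sequence of records with ``.id`` and ``.seq`` attributes
    (:class:`~viromarker.simulate.MarkerReference` or Biopython SeqRecords).
    The database size ``n`` for the E-value is the total residue count of the
    panel, so panels queried separately get their own statistics, as when each
    reference database is searched on its own.
    """
    params = params or SearchParams()
    refs = [(r.id, str(r.seq)) for r in panel]
    if not refs:
        raise ValueError("empty marker panel")
    n_db = sum(len(s) for _, s in refs)
    hits: list[AlignmentHit] = []
    for contig_id, seq in contigs.items():
        frames = translate_six_frames(seq)
        for ft in frames:
            if not ft.protein:
                continue
            m = len(ft.protein)
            for ref_id, ref_seq in refs:
                aln = local_align_protein(ft.protein, ref_seq, params)
                if aln.score <= 0:
                    continue
                ev = estimate_evalue(aln.score, params, m, n_db)
                if ev > params.max_evalue:
                    continue
                q_start_nt, q_end_nt = _aa_to_nt_interval(
                    aln.q_start, aln.q_end, ft.frame, ft.strand, len(seq)
                )
                hits.append(
                    AlignmentHit(
                        query_id=contig_id,
                        subject_id=ref_id,
                        bit_score=bit_score(aln.score, params),
                        evalue=ev,
                        q_start_nt=q_start_nt,
                        q_end_nt=q_end_nt,
                        strand=ft.strand,
                        s_start_aa=aln.s_start,
                        s_end_aa=aln.s_end,
                        aligned_aa_length=aln.n_columns,
                        percent_identity=aln.percent_identity,
                        mismatches=aln.mismatches,
                        gap_opens=aln.gap_opens,
                        raw_score=aln.score,
                        frame=ft.frame,
                    )
                )
    return hits


_TABULAR_COLUMNS = 12


def parse_tabular_hits(path) -> list[AlignmentHit]:
    """Parse 12-column tabular hits (qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore).

    Query coordinates are 1-based inclusive nucleotide positions; qstart >
    qend marks a minus-strand hit and is normalized so q_start_nt < q_end_nt.
    Lines starting with ``#`` are skipped.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _TABULAR_COLUMNS:
                raise ValueError(
                    f"line {lineno}: expected {_TABULAR_COLUMNS} tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                (qseqid, sseqid, pident, length, mismatch, gapopen,
                 qstart, qend, sstart, send, evalue, bitscore) = fields
                qstart_i, qend_i = int(qstart), int(qend)
                strand = "+" if qstart_i <= qend_i else "-"
                lo, hi = sorted((qstart_i, qend_i))
                hits.append(
                    AlignmentHit(
                        query_id=qseqid,
                        subject_id=sseqid,
                        bit_score=float(bitscore),
                        evalue=float(evalue),
                        q_start_nt=lo - 1,
                        q_end_nt=hi,
                        strand=strand,
                        s_start_aa=int(sstart) - 1,
                        s_end_aa=int(send),
                        aligned_aa_length=int(length),
                        percent_identity=float(pident),
                        mismatches=int(mismatch),
                        gap_opens=int(gapopen),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"line {lineno}: malformed row: {exc}") from None
    return hits


def write_tabular_hits(hits: Iterable[AlignmentHit], path) -> None:
    """Export hits in the 12-column tabular format (frame/raw score dropped)."""
    with open(path, "w") as fh:
        for h in hits:
            if h.strand == "+":
                qstart, qend = h.q_start_nt + 1, h.q_end_nt
            else:
                qstart, qend = h.q_end_nt, h.q_start_nt + 1
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.3f}",
                        str(h.aligned_aa_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(qstart),
                        str(qend),
                        str(h.s_start_aa + 1),
                        str(h.s_end_aa),
                        f"{h.evalue:.6g}",
                        f"{h.bit_score:.6g}",
                    ]
                )
                + "\n"
            )


def strip_to_tabular(hit: AlignmentHit) -> AlignmentHit:
    """Drop the fields the 12-column format cannot represent (round-trip form)."""
    return replace(hit, raw_score=None, frame=None,
                   percent_identity=round(hit.percent_identity, 3),
                   evalue=float(f"{hit.evalue:.6g}"),
                   bit_score=float(f"{hit.bit_score:.6g}"))
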