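"""From alignment hits to validated, classified candidates.

A candidate is the extracted aligned region of a contig matching a marker
panel.  The cascade applied here mirrors the discovery protocol: per-category
merging of overlapping hits, dual e-value stringency (1e-10 for viruses,
1e-30 for hosts), a >150 nt length floor, back-validation against a
comprehensive labelled panel to remove false positives, completeness
classification against the shortest panel protein, and the near-full-genome
call for RNA-virus contigs carrying both structural and non-structural
domains.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .search import AlignmentHit
from .simulate import ReferencePanel

__all__ = [
    "Candidate",
    "DomainHit",
    "StringencyParams",
    "extract_candidates",
    "apply_stringency",
    "back_validate",
    "classify_completeness",
    "call_near_full_genomes",
    "summarize_richness",
    "candidate_ledger",
    "write_ledger",
]

VIRUS_EVALUE_MAX = 1e-10
HOST_EVALUE_MAX = 1e-30
MIN_LENGTH_NT = 150


@dataclass(frozen=True)
class Candidate:
    candidate_id: str
    contig_id: str
    seq: str
    start: int
    end: int
    strand: str
    ref_id: str
    family_label: str
    category: str
    role: str
    evalue: float
    completeness: str | None = None  # near_complete | fragment
    validation: str | None = None  # passed | false_positive
    drop_reason: str | None = None

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def length_aa(self) -> int:
        return self.length_nt // 3


@dataclass(frozen=True)
class DomainHit:
    contig_id: str
    domain: str
    domain_class: str  # structural | non_structural
    start: int = 0
    end: int = 0


@dataclass
class StringencyParams:
    virus_evalue_max: float = VIRUS_EVALUE_MAX
    host_evalue_max: float = HOST_EVALUE_MAX
    min_length_nt: int = MIN_LENGTH_NT
    length_strict: bool = True  # strict "greater than 150"
    length_applies_to_hosts: bool = True


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def extract_candidates(
    hits: Sequence[AlignmentHit],
    contigs: Mapping[str, str],
    ref_meta: Mapping[str, tuple[str, str, str]],
) -> list[Candidate]:
    """Merge same-category hit intervals per contig and slice the contig.

    ``ref_meta`` maps reference id -> (category, role, family_label).  The
    merged region is the union of overlapping intervals; the lowest-e-value
    hit supplies the reference/family assignment and the strand.  One
    candidate per (contig, category).
    """
    by_key: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in hits:
        if h.query_id not in contigs:
            raise ValueError(f"hit references unknown contig {h.query_id}")
        if h.q_end_nt > len(contigs[h.query_id]):
            raise ValueError(
                f"hit interval [{h.q_start_nt}, {h.q_end_nt}) outside contig "
                f"{h.query_id} (corrupt hit)"
            )
        category = ref_meta[h.subject_id][0]
        by_key.setdefault((h.query_id, category), []).append(h)

    out: list[Candidate] = []
    for (contig_id, category), group in sorted(by_key.items()):
        intervals = sorted((h.q_start_nt, h.q_end_nt) for h in group)
        merged: list[list[int]] = []
        for s, e in intervals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        best = min(group, key=lambda h: (h.evalue, -h.bit_score, h.subject_id))
        # extract the merged block containing the best hit
        for s, e in merged:
            block = [h for h in group if h.q_start_nt >= s and h.q_end_nt <= e]
            block_best = min(block, key=lambda h: (h.evalue, -h.bit_score, h.subject_id))
            seq = contigs[contig_id][s:e]
            if block_best.strand == "-":
                seq = _revcomp(seq)
            _, role, family = ref_meta[block_best.subject_id]
            suffix = "" if len(merged) == 1 else f"_{s}"
            out.append(
                Candidate(
                    candidate_id=f"{contig_id}|{category}{suffix}",
                    contig_id=contig_id,
                    seq=seq,
                    start=s,
                    end=e,
                    strand=block_best.strand,
                    ref_id=block_best.subject_id,
                    family_label=family,
                    category=category,
                    role=role,
                    evalue=block_best.evalue,
                )
            )
    return out


def apply_stringency(
    cands: Iterable[Candidate],
    params: StringencyParams | None = None,
) -> tuple[list[Candidate], list[Candidate]]:
    """Dual-stringency e-value and length filter.

    Viral candidates must have e <= 1e-10, host candidates e <= 1e-30; both
    must exceed 150 nt (strict, configurable).  Returns (kept, dropped);
    dropped candidates carry a drop_reason.
    """
    params = params or StringencyParams()
    kept: list[Candidate] = []
    dropped: list[Candidate] = []
    for c in cands:
        ceiling = (
            params.virus_evalue_max if c.role == "virus" else params.host_evalue_max
        )
        if not (c.evalue <= ceiling):
            dropped.append(replace(c, drop_reason="evalue"))
            continue
        check_length = c.role == "virus" or params.length_applies_to_hosts
        if check_length:
            ok = (
                c.length_nt > params.min_length_nt
                if params.length_strict
                else c.length_nt >= params.min_length_nt
            )
            if not ok:
                dropped.append(replace(c, drop_reason="length"))
                continue
        kept.append(c)
    return kept, dropped


def back_validate(
    cands: Sequence[Candidate],
    validation_hits: Sequence[AlignmentHit],
    role_map: Mapping[str, str],
) -> tuple[list[Candidate], list[Candidate]]:
    """Mark candidates false-positive when their best comprehensive-panel hit
    is non-viral, or when they find no hit at all.

    ``validation_hits`` are candidate-vs-comprehensive-panel alignments (the
    query id is the candidate id); ``role_map`` labels every validation
    subject ``"viral"`` or ``"non_viral"``.  Ties at identical best e-value
    between viral and non-viral subjects are conservative: false positive.
    """
    best_by_cand: dict[str, list[AlignmentHit]] = {}
    for h in validation_hits:
        if h.subject_id not in role_map:
            raise ValueError(f"validation subject {h.subject_id} missing from role map")
        best_by_cand.setdefault(h.query_id, []).append(h)

    passed: list[Candidate] = []
    failed: list[Candidate] = []
    for c in cands:
        hits = best_by_cand.get(c.candidate_id, [])
        if not hits:
            failed.append(replace(c, validation="false_positive",
                                  drop_reason="validation_no_hit"))
            continue
        best_e = min(h.evalue for h in hits)
        best_labels = {role_map[h.subject_id] for h in hits if h.evalue == best_e}
        if best_labels == {"viral"}:
            passed.append(replace(c, validation="passed"))
        else:
            failed.append(replace(c, validation="false_positive",
                                  drop_reason="validation_nonviral"))
    return passed, failed


def classify_completeness(cand: Candidate, panel: ReferencePanel) -> Candidate:
    """Near-complete iff the candidate's aa length (floor nt/3) reaches the
    length of the panel's shortest reference protein."""
    status = (
        "near_complete" if cand.length_aa >= panel.min_aa_length else "fragment"
    )
    return replace(cand, completeness=status)


def call_near_full_genomes(
    rna_cands: Sequence[Candidate], domains: Sequence[DomainHit]
) -> set[str]:
    """RNA-virus contigs carrying both a structural and a non-structural
    domain hit are near-full-length genomes."""
    classes_by_contig: dict[str, set[str]] = {}
    for d in domains:
        if d.domain_class not in ("structural", "non_structural"):
            raise ValueError(f"unknown domain class {d.domain_class!r}")
        classes_by_contig.setdefault(d.contig_id, set()).add(d.domain_class)
    flagged = set()
    for c in rna_cands:
        cls = classes_by_contig.get(c.contig_id, set())
        if {"structural", "non_structural"} <= cls:
            flagged.add(c.contig_id)
    return flagged


def summarize_richness(
    cands: Sequence[Candidate],
    per_candidate_reads: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-category candidate counts and (optionally) viral read shares.

    Read shares are percentages of total viral reads per viral category and
    sum to 100 over viral categories (0 everywhere when no viral reads).
    """
    rows: dict[str, dict] = {}
    for c in cands:
        row = rows.setdefault(
            c.category, {"category": c.category, "role": c.role, "n_candidates": 0}
        )
        row["n_candidates"] += 1
    table = pd.DataFrame(rows.values())
    if table.empty:
        table = pd.DataFrame(columns=["category", "role", "n_candidates"])
    table = table.set_index("category").sort_index()
    if per_candidate_reads is not None:
        reads_by_cat = pd.Series(0.0, index=table.index)
        cand_cat = {c.candidate_id: c.category for c in cands}
        for cand_id, n in per_candidate_reads.items():
            if cand_id in cand_cat:
                reads_by_cat[cand_cat[cand_id]] += n
        table["reads"] = reads_by_cat
        viral = table["role"] == "virus"
        total_viral = table.loc[viral, "reads"].sum()
        shares = pd.Series(0.0, index=table.index)
        if total_viral > 0:
            shares[viral] = 100.0 * table.loc[viral, "reads"] / total_viral
        table["viral_read_share_pct"] = shares
    return table.reset_index()


def read_domain_table(path) -> list[DomainHit]:
    """Domain hits from TSV (contig_id, domain, domain_class[, start, end]).

    Domain classes must be ``structural`` or ``non_structural``; scanning
    itself is out of scope — this table is an input.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"contig_id", "domain", "domain_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"domain table missing columns: {sorted(missing)}")
    return [
        DomainHit(
            contig_id=row["contig_id"],
            domain=row["domain"],
            domain_class=row["domain_class"],
            start=int(row.get("start", 0) or 0),
            end=int(row.get("end", 0) or 0),
        )
        for _, row in df.iterrows()
    ]


def candidate_ledger(all_cands: Sequence[Candidate]) -> pd.DataFrame:
    """One row per candidate, dropped or kept, with the drop reason."""
    return pd.DataFrame(
        [
            {
                "candidate_id": c.candidate_id,
                "contig_id": c.contig_id,
                "category": c.category,
                "role": c.role,
                "start": c.start,
                "end": c.end,
                "strand": c.strand,
                "length_nt": c.length_nt,
                "ref_id": c.ref_id,
                "family_label": c.family_label,
                "evalue": c.evalue,
                "completeness": c.completeness or "",
                "validation": c.validation or "",
                "drop_reason": c.drop_reason or "",
            }
            for c in all_cands
        ]
    )


def write_ledger(all_cands: Sequence[Candidate], path) -> None:
    candidate_ledger(all_cands).to_csv(path, sep="\t", index=False)
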