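"""Reading and writing the pipeline's on-disk artifacts.

All artifacts are plain text: FASTA contigs and panels (with a sidecar TSV of
category/role metadata), Sanger Phred+33 FASTQ libraries, and TSV tables.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO

from .simulate import (
    MarkerReference,
    ReferencePanel,
    SimulatedRead,
    SyntheticDataset,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_fastq",
    "iter_fastq",
    "write_panels",
    "read_panels",
    "write_dataset",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: Iterable[SimulatedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.id} src={r.source}\n{r.seq}\n+\n{qual}\n")


def iter_fastq(path) -> Iterator[tuple[str, str, list[int]]]:
    """Yield (id, sequence, phred qualities) per record.

    Malformed records raise with the index of the offending record.
    """
    index = 0
    try:
        for rec in SeqIO.parse(path, "fastq"):
            yield rec.id, str(rec.seq).upper(), rec.letter_annotations[
                "phred_quality"
            ]
            index += 1
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record at index {index}: {exc}") from None


def write_panels(panels: Mapping[str, ReferencePanel], fasta_path, meta_path) -> None:
    """Panel FASTA plus a sidecar TSV (id, category, role, family_label)."""
    seqs = {}
    rows = []
    for panel in panels.values():
        for rec in panel.records:
            seqs[rec.id] = rec.seq
            rows.append(
                {
                    "id": rec.id,
                    "category": rec.category,
                    "role": rec.role,
                    "family_label": rec.family_label,
                }
            )
    write_fasta(seqs, fasta_path)
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)


def read_panels(fasta_path, meta_path) -> dict[str, ReferencePanel]:
    seqs = read_fasta(fasta_path)
    meta = pd.read_csv(meta_path, sep="\t")
    panels: dict[str, ReferencePanel] = {}
    for _, row in meta.iterrows():
        rec = MarkerReference(
            id=row["id"],
            seq=seqs[row["id"]],
            category=row["category"],
            role=row["role"],
            family_label=row["family_label"],
        )
        panels.setdefault(
            row["category"], ReferencePanel(row["category"], row["role"], [])
        ).records.append(rec)
    return panels


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write every artifact of a synthetic dataset under ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    join = lambda name: os.path.join(outdir, name)
    write_panels(ds.panels, join("panels.fasta"), join("panels.tsv"))
    write_fasta(ds.contigs, join("contigs.fasta"))
    readdir = join("reads")
    os.makedirs(readdir, exist_ok=True)
    for sample, reads in ds.reads.reads.items():
        write_fastq(reads, os.path.join(readdir, f"{sample}.fastq"))
    ds.truth.markers.to_csv(join("truth_markers.tsv"), sep="\t", index=False)
    ds.truth.expected_counts.to_csv(join("truth_expected_counts.tsv"), sep="\t")
    ds.truth.attribution.to_csv(join("truth_attribution.tsv"), sep="\t")
    ds.reads.library_sizes.rename("library_size").to_csv(
        join("library_sizes.tsv"), sep="\t"
    )
    ds.env.rename_axis("sample").to_csv(join("env.tsv"), sep="\t")
    pd.DataFrame(
        [
            {"virus_id": p.virus_id, "host_id": p.host_id, "correlation": p.correlation}
            for p in ds.truth.planted_pairs
        ]
    ).to_csv(join("truth_pairs.tsv"), sep="\t", index=False)
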