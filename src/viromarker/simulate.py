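"""Seeded synthetic datasets with the statistical structure the analysis assumes.

The generator emulates a multi-sample assembled metatranscriptome survey of a
cyanobacterial bloom: marker-protein reference panels for several viral
categories and two host categories, contigs that embed mutated
back-translations of panel proteins, per-sample read libraries with
sequencing error, planted virus--host abundance correlations, and
environmental covariates optionally linked to the dominant community axis.
A truth table records where every marker was planted and how many reads each
contig contributed to each library, so the whole pipeline can be scored
against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "CategorySpec",
    "PlantedPair",
    "EnvVariable",
    "SimulationConfig",
    "MarkerReference",
    "ReferencePanel",
    "TruthTable",
    "SimulatedRead",
    "ReadSet",
    "SyntheticDataset",
    "generate_reference_panel",
    "generate_contigs",
    "generate_abundance_profiles",
    "generate_reads",
    "generate_env_table",
    "simulate_dataset",
    "back_translate",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = np.array(list("ACGT"))

# standard genetic code, amino acid -> synonymous codons
_CODONS: dict[str, list[str]] = {}
for codon, aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()


@dataclass(frozen=True)
class CategorySpec:
    name: str
    role: str  # "virus" or "host"
    n_candidates: int
    n_references: int = 4


@dataclass(frozen=True)
class PlantedPair:
    virus_id: str
    host_id: str
    correlation: float


@dataclass(frozen=True)
class EnvVariable:
    name: str
    link: str = "none"  # "none" or "axis1"


def _default_categories() -> list[CategorySpec]:
    # viral marker classes and host classes surveyed by the marker-gene
    # approach, at desk scale
    return [
        CategorySpec("NCLDV", "virus", 6),
        CategorySpec("ssRNA", "virus", 5),
        CategorySpec("dsRNA", "virus", 3),
        CategorySpec("ssDNA", "virus", 2),
        CategorySpec("virophage", "virus", 2),
        CategorySpec("phage_microcystis_lytic", "virus", 2),
        CategorySpec("phage_microcystis_lysogenic", "virus", 2),
        CategorySpec("phage_other", "virus", 3),
        CategorySpec("host_bacteria", "host", 5),
        CategorySpec("host_eukaryote", "host", 5),
    ]


def _default_pairs() -> list[PlantedPair]:
    return [
        PlantedPair("ssRNA_cand00", "host_eukaryote_cand00", 0.9),
        PlantedPair("NCLDV_cand00", "host_eukaryote_cand01", 0.9),
        PlantedPair("dsRNA_cand00", "host_eukaryote_cand02", 0.9),
        PlantedPair("phage_microcystis_lytic_cand00", "host_bacteria_cand00", 0.9),
        PlantedPair("phage_other_cand00", "host_bacteria_cand01", 0.9),
    ]


def _default_env() -> list[EnvVariable]:
    return [
        EnvVariable("pH", "axis1"),
        EnvVariable("salinity", "axis1"),
        EnvVariable("temperature", "none"),
        EnvVariable("nitrate", "none"),
    ]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic community, with seeded determinism.

    ``n_samples`` defaults to the 35 libraries of a monthly multi-station
    bloom survey.  Library sizes are desk-scale (thousands of reads rather
    than millions); the abundance model and correlation structure, not raw
    throughput, are what the analysis consumes.
    """

    seed: int = 0
    n_samples: int = 35
    categories: list[CategorySpec] = field(default_factory=_default_categories)
    planted_pairs: list[PlantedPair] = field(default_factory=_default_pairs)
    env_vars: list[EnvVariable] = field(default_factory=_default_env)
    # reference panels
    ref_length_range: tuple[int, int] = (130, 190)
    ref_divergence: float = 0.12  # aa substitution rate within a panel
    # contigs
    contig_mutation_rate: float = 0.05  # nt substitutions in planted markers
    flank_length_range: tuple[int, int] = (120, 320)
    n_decoys: int = 10
    decoy_length_range: tuple[int, int] = (400, 1200)
    # abundance model (natural-log scale)
    lognormal_sigma: float = 1.0
    level_sigma: float = 0.8  # spread of per-candidate mean levels
    axis_loading_sigma: float = 0.5  # coupling to the latent community axis
    env_noise_sd: float = 0.3
    # reads
    read_length: int = 100
    error_rate: float = 0.005
    library_size_range: tuple[int, int] = (2000, 6000)

    def __post_init__(self) -> None:
        # accept plain dicts/tuples (e.g. from a YAML config)
        self.categories = [
            c if isinstance(c, CategorySpec) else CategorySpec(**c)
            for c in self.categories
        ]
        self.planted_pairs = [
            p if isinstance(p, PlantedPair)
            else PlantedPair(*p) if isinstance(p, (tuple, list))
            else PlantedPair(**p)
            for p in self.planted_pairs
        ]
        self.env_vars = [
            v if isinstance(v, EnvVariable)
            else EnvVariable(*v) if isinstance(v, (tuple, list))
            else EnvVariable(**v)
            for v in self.env_vars
        ]
        self.library_size_range = tuple(self.library_size_range)
        self.ref_length_range = tuple(self.ref_length_range)
        self.flank_length_range = tuple(self.flank_length_range)
        self.decoy_length_range = tuple(self.decoy_length_range)
        if self.n_samples < 3:
            raise ValueError("n_samples must be at least 3")
        if not self.categories:
            raise ValueError("at least one category is required")
        for p in self.planted_pairs:
            if abs(p.correlation) > 1:
                raise ValueError(
                    f"latent correlation magnitude > 1 for pair "
                    f"({p.virus_id}, {p.host_id})"
                )
        if not 0 <= self.error_rate < 1:
            raise ValueError("error rate must be in [0, 1)")
        if min(self.library_size_range) <= 0:
            raise ValueError("library sizes must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-keyed generator: each stage is deterministic on its own."""
        return np.random.default_rng([self.seed, stage])


@dataclass(frozen=True)
class MarkerReference:
    id: str
    seq: str
    category: str
    role: str
    family_label: str


@dataclass
class ReferencePanel:
    category: str
    role: str
    records: list[MarkerReference]

    @property
    def min_aa_length(self) -> int:
        return min(len(r.seq) for r in self.records)


@dataclass
class TruthTable:
    """Ground truth of the planted markers and expected read flow."""

    markers: pd.DataFrame  # candidate_id, contig_id, category, role, start, end, strand, ref_id
    planted_pairs: list[PlantedPair]
    expected_counts: pd.DataFrame | None = None  # contig x sample Poisson means
    attribution: pd.DataFrame | None = None  # contig x sample realized read counts
    latent_axis: pd.Series | None = None


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA), size=length))


def _mutate_protein(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = _AA.replace(out[i], "")
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def generate_reference_panel(
    config: SimulationConfig,
) -> dict[str, ReferencePanel]:
    """One protein panel per category; members share a category ancestor.

    Within-category similarity (~1 - 2*ref_divergence) is far higher than the
    between-category similarity of independent random proteins, so the
    category signal lives in protein space.
    """
    rng = config.rng(1)
    panels: dict[str, ReferencePanel] = {}
    for spec in config.categories:
        length = int(rng.integers(*config.ref_length_range))
        ancestor = _random_protein(rng, length)
        records = [
            MarkerReference(
                id=f"{spec.name}_ref{j:02d}",
                seq=_mutate_protein(rng, ancestor, config.ref_divergence),
                category=spec.name,
                role=spec.role,
                family_label=f"{spec.name}_family{j % 2}",
            )
            for j in range(spec.n_references)
        ]
        panels[spec.name] = ReferencePanel(spec.name, spec.role, records)
    return panels


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Back-translate with uniform-random synonymous codon choice."""
    try:
        return "".join(
            _CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein
        )
    except KeyError as exc:
        raise ValueError(f"cannot back-translate residue {exc}") from None


def _mutate_nt(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def generate_contigs(
    panels: Mapping[str, ReferencePanel], config: SimulationConfig
) -> tuple[dict[str, str], TruthTable]:
    """Candidate contigs embedding mutated marker back-translations + decoys.

    Each candidate contig carries exactly one marker region whose
    forward-strand coordinates and strand are recorded in the truth table.
    Decoy contigs are random-composition sequences with no planted marker.
    """
    if not panels:
        raise ValueError("no reference panels supplied")
    rng = config.rng(2)
    contigs: dict[str, str] = {}
    rows = []
    for spec in config.categories:
        panel = panels[spec.name]
        for i in range(spec.n_candidates):
            cand_id = f"{spec.name}_cand{i:02d}"
            contig_id = f"contig_{cand_id}"
            ref = panel.records[int(rng.integers(len(panel.records)))]
            marker = back_translate(ref.seq, rng)
            marker = _mutate_nt(rng, marker, config.contig_mutation_rate)
            left = int(rng.integers(*config.flank_length_range))
            right = int(rng.integers(*config.flank_length_range))
            strand = "+" if rng.random() < 0.5 else "-"
            insert = marker if strand == "+" else _revcomp(marker)
            contig = (
                "".join(rng.choice(_NT, size=left))
                + insert
                + "".join(rng.choice(_NT, size=right))
            )
            contigs[contig_id] = contig
            rows.append(
                {
                    "candidate_id": cand_id,
                    "contig_id": contig_id,
                    "category": spec.name,
                    "role": spec.role,
                    "start": left,
                    "end": left + len(insert),
                    "strand": strand,
                    "ref_id": ref.id,
                }
            )
    for d in range(config.n_decoys):
        length = int(rng.integers(*config.decoy_length_range))
        comp = rng.dirichlet(np.ones(4))
        contigs[f"decoy_{d:03d}"] = "".join(rng.choice(_NT, size=length, p=comp))
    markers = pd.DataFrame(rows)
    return contigs, TruthTable(markers=markers, planted_pairs=list(config.planted_pairs))


def generate_abundance_profiles(
    config: SimulationConfig, truth: TruthTable
) -> TruthTable:
    """Expected per-sample read counts with planted pair correlations.

    Log-scale model per contig i and sample s:

        x[i, s] = mu_i + l_i * t_s + sigma * eps[i, s]

    with t the latent community axis.  Members of a planted (virus, host)
    pair instead share a pair-specific factor with loading sqrt(|rho|), so
    their log-profiles correlate at rho (sign via the host loading).  Counts
    are exp(x) scaled so the mean library lands mid library_size_range.
    """
    rng = config.rng(3)
    markers = truth.markers
    cand_ids = list(markers["candidate_id"])
    contig_of = dict(zip(markers["candidate_id"], markers["contig_id"]))
    decoy_ids = [f"decoy_{d:03d}" for d in range(config.n_decoys)]
    n_s = config.n_samples

    known = set(cand_ids)
    for p in truth.planted_pairs:
        for cid in (p.virus_id, p.host_id):
            if cid not in known:
                raise ValueError(f"planted pair references unknown candidate {cid}")
        if abs(p.correlation) > 1:
            raise ValueError("latent correlation magnitude exceeds 1")

    t = rng.standard_normal(n_s)  # latent community axis
    paired = {p.virus_id: (k, +1.0, p.correlation)
              for k, p in enumerate(truth.planted_pairs)}
    paired.update({p.host_id: (k, np.sign(p.correlation) or 1.0, p.correlation)
                   for k, p in enumerate(truth.planted_pairs)})
    pair_factors = rng.standard_normal((len(truth.planted_pairs), n_s))

    contig_ids = [contig_of[c] for c in cand_ids] + decoy_ids
    x = np.empty((len(contig_ids), n_s))
    for row, cid in enumerate(cand_ids + decoy_ids):
        mu = config.level_sigma * rng.standard_normal()
        eps = rng.standard_normal(n_s)
        if cid in paired:
            k, sign, rho = paired[cid]
            a = np.sqrt(abs(rho))
            noise = np.sqrt(max(0.0, 1.0 - abs(rho)))
            x[row] = mu + config.lognormal_sigma * (
                sign * a * pair_factors[k] + noise * eps
            )
        else:
            loading = config.axis_loading_sigma * rng.standard_normal()
            x[row] = mu + loading * t + config.lognormal_sigma * eps
    rel = np.exp(x)
    target = 0.5 * sum(config.library_size_range)
    scale = target / rel.sum(axis=0).mean()
    expected = pd.DataFrame(
        rel * scale, index=contig_ids, columns=config.sample_ids
    )
    truth.expected_counts = expected
    truth.latent_axis = pd.Series(t, index=config.sample_ids, name="axis1")
    return truth


@dataclass(frozen=True)
class SimulatedRead:
    id: str
    seq: str
    quals: tuple[int, ...]
    source: str


@dataclass
class ReadSet:
    reads: dict[str, list[SimulatedRead]]  # sample -> reads
    library_sizes: pd.Series


def _draw_qualities(
    rng: np.random.Generator, n: int, error_rate: float
) -> np.ndarray:
    """Per-base Phred qualities consistent with the nominal error rate."""
    if error_rate <= 0:
        return np.full(n, 40, dtype=int)
    q_nom = -10.0 * np.log10(error_rate)
    q = np.clip(np.rint(q_nom + rng.uniform(-3, 3, size=n)), 2, 41)
    return q.astype(int)


def generate_reads(
    contigs: Mapping[str, str],
    truth: TruthTable,
    config: SimulationConfig,
) -> tuple[ReadSet, TruthTable]:
    """Sample reads uniformly along contigs with per-base errors.

    Per-contig counts are Poisson around the expected-count matrix; the
    recorded library size of a sample is the realized total, and every read's
    source contig is kept both in the read record and in the truth table's
    attribution matrix.
    """
    if truth.expected_counts is None:
        raise ValueError("run generate_abundance_profiles first")
    rng = config.rng(4)
    L = config.read_length
    for cid, seq in contigs.items():
        if L > len(seq):
            raise ValueError(f"read length {L} exceeds contig {cid} length {len(seq)}")
    expected = truth.expected_counts
    reads: dict[str, list[SimulatedRead]] = {}
    attribution = pd.DataFrame(
        0, index=expected.index, columns=expected.columns, dtype=int
    )
    for sample in expected.columns:
        sample_reads: list[SimulatedRead] = []
        n_read = 0
        for contig_id in expected.index:
            lam = expected.at[contig_id, sample]
            count = int(rng.poisson(lam))
            attribution.at[contig_id, sample] = count
            seq = contigs[contig_id]
            for _ in range(count):
                start = int(rng.integers(0, len(seq) - L + 1))
                frag = seq[start : start + L]
                if rng.random() < 0.5:
                    frag = _revcomp(frag)
                quals = _draw_qualities(rng, L, config.error_rate)
                if config.error_rate > 0:
                    p_err = 10.0 ** (-quals / 10.0)
                    flip = rng.random(L) < p_err
                    if flip.any():
                        arr = list(frag)
                        for i in np.flatnonzero(flip):
                            choices = [b for b in "ACGT" if b != arr[i]]
                            arr[i] = choices[rng.integers(3)]
                        frag = "".join(arr)
                sample_reads.append(
                    SimulatedRead(
                        id=f"{sample}_r{n_read:06d}",
                        seq=frag,
                        quals=tuple(int(q) for q in quals),
                        source=contig_id,
                    )
                )
                n_read += 1
        reads[sample] = sample_reads
    library_sizes = attribution.sum(axis=0).astype(int)
    truth.attribution = attribution
    return ReadSet(reads=reads, library_sizes=library_sizes), truth


def generate_env_table(config: SimulationConfig, truth: TruthTable) -> pd.DataFrame:
    """Environmental covariates; link=axis1 variables track the latent axis."""
    if truth.latent_axis is None:
        raise ValueError("run generate_abundance_profiles first")
    rng = config.rng(5)
    t = truth.latent_axis.to_numpy()
    data = {}
    for var in config.env_vars:
        if var.link == "axis1":
            data[var.name] = t + config.env_noise_sd * rng.standard_normal(len(t))
        elif var.link == "none":
            data[var.name] = rng.standard_normal(len(t))
        else:
            raise ValueError(f"unknown env link {var.link!r}")
    return pd.DataFrame(data, index=config.sample_ids)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    panels: dict[str, ReferencePanel]
    contigs: dict[str, str]
    truth: TruthTable
    reads: ReadSet
    env: pd.DataFrame


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run every generator stage in order and bundle the results."""
    panels = generate_reference_panel(config)
    contigs, truth = generate_contigs(panels, config)
    truth = generate_abundance_profiles(config, truth)
    readset, truth = generate_reads(contigs, truth, config)
    env = generate_env_table(config, truth)
    return SyntheticDataset(config, panels, contigs, truth, readset, env)
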