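"""End-to-end orchestration of the marker-gene analysis.

Each stage reads and writes plain-text artifacts under a run directory so
every summary number is recomputable from disk, and a JSON manifest records
every threshold with a provenance flag ("paper" for values taken from the
published protocol, "assumed" for gaps filled by this implementation).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, replace
import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .candidates import (
    Candidate,
    StringencyParams,
    apply_stringency,
    back_validate,
    classify_completeness,
    extract_candidates,
    summarize_richness,
    write_ledger,
)
from .cooccurrence import (
    build_network,
    cluster_table,
    descend_tree,
    linkage_to_newick,
    pearson_matrix,
    upgma_cluster,
)
from .io import iter_fastq, read_fasta, read_panels, write_dataset, write_fasta
from .ordination import bray_curtis, env_correlation, nmds, sqrt_transform
from .quantify import (
    ReadRecruitmentParams,
    aggregate_by_type,
    normalize,
    recruit_reads,
)
from .search import SearchParams, parse_tabular_hits, search_contigs, write_tabular_hits
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger("viromarker")

__all__ = [
    "RunConfig",
    "run_all",
    "report_filter_funnel",
    "export_heatmap_tables",
    "load_config",
]


@dataclass
class RunConfig:
    """Parameters for every pipeline stage plus stage toggles."""

    seed: int = 0
    outdir: str = "viromarker_run"
    simulate: dict = field(default_factory=dict)
    search: dict = field(default_factory=dict)
    candidates: dict = field(default_factory=dict)
    quantify: dict = field(default_factory=dict)
    ordinate: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)  # stage name -> bool

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _provenance() -> dict:
    """Threshold provenance: published value vs implementation choice."""
    return {
        "virus_evalue_max": "paper",
        "host_evalue_max": "paper",
        "min_length_nt": "paper",
        "length_strict": "assumed",
        "min_identity": "paper",
        "min_length_fraction": "paper",
        "quality_floor": "paper",
        "sqrt_transform": "paper",
        "r_threshold": "paper",
        "alpha": "assumed (printed value 0.5 available via config)",
        "n_permutations": "assumed",
        "linkage": "assumed (group average)",
        "scoring_matrix": "assumed (BLASTx defaults)",
        "n_samples": "paper",
    }


def _simulation_config(cfg: RunConfig) -> SimulationConfig:
    return SimulationConfig(seed=cfg.seed, **cfg.simulate)


def stage_simulate(cfg: RunConfig) -> None:
    ds = simulate_dataset(_simulation_config(cfg))
    write_dataset(ds, os.path.join(cfg.outdir, "data"))
    logger.info("[simulate] wrote %d contigs, %d samples",
                len(ds.contigs), ds.config.n_samples)


def stage_search(cfg: RunConfig) -> None:
    data = os.path.join(cfg.outdir, "data")
    contigs = read_fasta(os.path.join(data, "contigs.fasta"))
    panels = read_panels(
        os.path.join(data, "panels.fasta"), os.path.join(data, "panels.tsv")
    )
    # each panel is queried separately so the dual stringencies can differ by
    # role already at the search step (e-10 viral panels, e-30 host panels)
    opts = dict(cfg.search)
    virus_ceiling = float(opts.pop("virus_evalue_max", 1e-10))
    host_ceiling = float(opts.pop("host_evalue_max", 1e-30))
    hits = []
    for name in sorted(panels):
        ceiling = virus_ceiling if panels[name].role == "virus" else host_ceiling
        params = SearchParams(max_evalue=ceiling, **opts)
        hits.extend(search_contigs(contigs, panels[name].records, params))
    write_tabular_hits(hits, os.path.join(cfg.outdir, "hits.tsv"))
    logger.info("[search] %d hits across %d panels", len(hits), len(panels))


def _ref_meta(panels) -> dict[str, tuple[str, str, str]]:
    return {
        rec.id: (rec.category, rec.role, rec.family_label)
        for p in panels.values()
        for rec in p.records
    }


def stage_candidates(cfg: RunConfig) -> None:
    data = os.path.join(cfg.outdir, "data")
    contigs = read_fasta(os.path.join(data, "contigs.fasta"))
    panels = read_panels(
        os.path.join(data, "panels.fasta"), os.path.join(data, "panels.tsv")
    )
    hits = parse_tabular_hits(os.path.join(cfg.outdir, "hits.tsv"))
    meta = _ref_meta(panels)
    cands = extract_candidates(hits, contigs, meta)

    params = StringencyParams(
        **{k: v for k, v in cfg.candidates.items() if k != "validation_evalue_max"}
    )
    kept, dropped = apply_stringency(cands, params)

    # back-validation against the comprehensive panel (all references, both
    # roles); only viral candidates are subject to the non-viral check
    validation_refs = [rec for p in panels.values() for rec in p.records]
    role_map = {
        rec.id: ("viral" if rec.role == "virus" else "non_viral")
        for rec in validation_refs
    }
    viral = [c for c in kept if c.role == "virus"]
    hosts = [c for c in kept if c.role == "host"]
    val_params = SearchParams(
        max_evalue=float(cfg.candidates.get("validation_evalue_max", 1e-3))
    )
    val_hits = search_contigs(
        {c.candidate_id: c.seq for c in viral}, validation_refs, val_params
    )
    passed, failed = back_validate(viral, val_hits, role_map)
    hosts = [replace(c, validation="passed") for c in hosts]

    final = [
        classify_completeness(c, panels[c.category]) for c in passed + hosts
    ]
    all_cands = final + failed + dropped
    write_ledger(all_cands, os.path.join(cfg.outdir, "candidates.tsv"))
    write_fasta(
        {c.candidate_id: c.seq for c in final},
        os.path.join(cfg.outdir, "candidates.fasta"),
    )
    meta_rows = pd.DataFrame(
        [
            {
                "candidate_id": c.candidate_id,
                "category": c.category,
                "role": c.role,
                "length_nt": c.length_nt,
                "completeness": c.completeness,
            }
            for c in final
        ]
    )
    meta_rows.to_csv(
        os.path.join(cfg.outdir, "candidate_meta.tsv"), sep="\t", index=False
    )

    # near-full-length genome calls when a domain-hit table is provided
    domain_path = os.path.join(data, "domains.tsv")
    if os.path.exists(domain_path):
        from .candidates import call_near_full_genomes, read_domain_table

        rna = [c for c in final if c.category in ("ssRNA", "dsRNA")]
        flagged = call_near_full_genomes(rna, read_domain_table(domain_path))
        with open(os.path.join(cfg.outdir, "near_full_genomes.txt"), "w") as fh:
            for contig_id in sorted(flagged):
                fh.write(contig_id + "\n")
    logger.info(
        "[candidates] %d extracted, %d kept, %d dropped/failed",
        len(cands), len(final), len(all_cands) - len(final),
    )


def stage_quantify(cfg: RunConfig) -> None:
    data = os.path.join(cfg.outdir, "data")
    cand_seqs = read_fasta(os.path.join(cfg.outdir, "candidates.fasta"))
    meta = pd.read_csv(
        os.path.join(cfg.outdir, "candidate_meta.tsv"), sep="\t"
    ).set_index("candidate_id")
    params = ReadRecruitmentParams(**cfg.quantify)
    readdir = os.path.join(data, "reads")
    reads_by_sample = {
        fn[: -len(".fastq")]: list(iter_fastq(os.path.join(readdir, fn)))
        for fn in sorted(os.listdir(readdir))
        if fn.endswith(".fastq")
    }
    raw, library_sizes = recruit_reads(reads_by_sample, cand_seqs, params)
    lengths = meta["length_nt"].reindex(raw.index)
    am = normalize(raw, lengths, library_sizes)
    am.data.rename_axis("candidate_id").to_csv(
        os.path.join(cfg.outdir, "abundance_normalized.tsv"), sep="\t"
    )
    am.raw.rename_axis("candidate_id").to_csv(
        os.path.join(cfg.outdir, "abundance_raw.tsv"), sep="\t"
    )
    library_sizes.rename("library_size").rename_axis("sample").to_csv(
        os.path.join(cfg.outdir, "library_sizes_qc.tsv"), sep="\t"
    )
    categories = meta["category"].to_dict()
    type_matrix, totals = aggregate_by_type(am.data, categories)
    all_cats = sorted(set(categories.values()))
    type_matrix = type_matrix.reindex(all_cats, fill_value=0.0)
    export_heatmap_tables(type_matrix, totals, cfg.outdir)
    logger.info("[quantify] %d candidates x %d samples", *am.data.shape)


def stage_ordinate(cfg: RunConfig) -> None:
    data = os.path.join(cfg.outdir, "data")
    am = pd.read_csv(
        os.path.join(cfg.outdir, "abundance_normalized.tsv"),
        sep="\t", index_col=0,
    )
    sq = sqrt_transform(am)
    bc = bray_curtis(sq)
    bc.rename_axis("sample").to_csv(
        os.path.join(cfg.outdir, "bray_curtis.tsv"), sep="\t"
    )
    opts = dict(cfg.ordinate)
    res = nmds(bc, seed=cfg.seed, **opts)
    res.coords.rename_axis("sample").to_csv(
        os.path.join(cfg.outdir, "nmds_coords.tsv"), sep="\t"
    )
    with open(os.path.join(cfg.outdir, "nmds_stress.json"), "w") as fh:
        json.dump(
            {"stress": res.stress, "n_restarts": res.n_restarts, "seed": res.seed},
            fh, indent=2,
        )
    env_path = os.path.join(data, "env.tsv")
    if os.path.exists(env_path):
        env = pd.read_csv(env_path, sep="\t", index_col=0)
        type_matrix = pd.read_csv(
            os.path.join(cfg.outdir, "type_by_sample.tsv"), sep="\t", index_col=0
        )
        table = env_correlation(env, axes=res.coords, type_matrix=type_matrix)
        table.to_csv(
            os.path.join(cfg.outdir, "env_correlations.tsv"), sep="\t", index=False
        )
    logger.info("[ordinate] stress=%.4f", res.stress)


def stage_cluster(cfg: RunConfig) -> None:
    am = pd.read_csv(
        os.path.join(cfg.outdir, "abundance_normalized.tsv"),
        sep="\t", index_col=0,
    )
    sq = sqrt_transform(am)
    r = pearson_matrix(sq)
    Z, labels = upgma_cluster(r)
    with open(os.path.join(cfg.outdir, "dendrogram.nwk"), "w") as fh:
        fh.write(linkage_to_newick(Z, labels) + "\n")
    opts = dict(cfg.cluster)
    alpha = float(opts.pop("alpha", 0.05))
    root, clusters = descend_tree(
        Z, labels, sq.loc[labels], alpha=alpha, seed=cfg.seed, **opts
    )
    cluster_table(clusters).to_csv(
        os.path.join(cfg.outdir, "clusters.tsv"), sep="\t", index=False
    )
    r.rename_axis("candidate_id").to_csv(
        os.path.join(cfg.outdir, "pearson_r.tsv"), sep="\t"
    )
    logger.info("[cluster] %d clusters", len(clusters))


def stage_network(cfg: RunConfig) -> None:
    r = pd.read_csv(os.path.join(cfg.outdir, "pearson_r.tsv"), sep="\t", index_col=0)
    clusters_df = pd.read_csv(os.path.join(cfg.outdir, "clusters.tsv"), sep="\t")
    meta = pd.read_csv(
        os.path.join(cfg.outdir, "candidate_meta.tsv"), sep="\t"
    ).set_index("candidate_id")
    from .cooccurrence import SimprofNode, SimprofResult

    clusters = []
    for k, grp in clusters_df.groupby("cluster"):
        res = SimprofResult(None, None, False, False, len(grp))
        clusters.append(
            SimprofNode(members=sorted(grp["candidate_id"]), height=0.0, result=res,
                        is_cluster=True)
        )
    roles = meta["role"].to_dict()
    cats = meta["category"].to_dict()
    threshold = float(cfg.network.get("r_threshold", 0.8))
    G = build_network(clusters, r, roles, cats, r_threshold=threshold)
    nx.write_graphml(G, os.path.join(cfg.outdir, "network.graphml"))
    edges = pd.DataFrame(
        [
            {"source": a, "target": b, "weight": d["weight"]}
            for a, b, d in sorted(G.edges(data=True))
        ],
        columns=["source", "target", "weight"],
    )
    edges.to_csv(os.path.join(cfg.outdir, "network_edges.tsv"), sep="\t", index=False)
    nodes = pd.DataFrame(
        [
            {"candidate_id": n, **attrs}
            for n, attrs in sorted(G.nodes(data=True))
        ],
        columns=["candidate_id", "role", "category", "cluster"],
    )
    nodes.to_csv(os.path.join(cfg.outdir, "network_nodes.tsv"), sep="\t", index=False)
    logger.info("[network] %d nodes, %d edges", G.number_of_nodes(), G.number_of_edges())


def stage_summaries(cfg: RunConfig) -> None:
    ledger = pd.read_csv(os.path.join(cfg.outdir, "candidates.tsv"), sep="\t")
    funnel = report_filter_funnel(ledger)
    funnel.to_csv(os.path.join(cfg.outdir, "filter_funnel.tsv"), sep="\t", index=False)
    raw_path = os.path.join(cfg.outdir, "abundance_raw.tsv")
    per_cand_reads = None
    if os.path.exists(raw_path):
        raw = pd.read_csv(raw_path, sep="\t", index_col=0)
        per_cand_reads = raw.sum(axis=1)
    kept = ledger[ledger["drop_reason"].fillna("") == ""]
    cands = [
        Candidate(
            candidate_id=row.candidate_id,
            contig_id=row.contig_id,
            seq="",
            start=row.start,
            end=row.end,
            strand=row.strand,
            ref_id=row.ref_id,
            family_label=row.family_label,
            category=row.category,
            role=row.role,
            evalue=row.evalue,
        )
        for row in kept.itertuples()
    ]
    richness = summarize_richness(cands, per_cand_reads)
    richness.to_csv(os.path.join(cfg.outdir, "richness.tsv"), sep="\t", index=False)


def report_filter_funnel(ledger: pd.DataFrame) -> pd.DataFrame:
    """Candidates surviving each successive filter, per category."""
    reasons = ledger["drop_reason"].fillna("")
    rows = []
    for cat, grp in ledger.groupby("category"):
        r = grp["drop_reason"].fillna("")
        n0 = len(grp)
        n1 = n0 - (r == "evalue").sum()
        n2 = n1 - (r == "length").sum()
        n3 = n2 - r.str.startswith("validation").sum()
        rows.append(
            {
                "category": cat,
                "pre_filter": n0,
                "after_evalue": n1,
                "after_length": n2,
                "after_validation": n3,
            }
        )
    return pd.DataFrame(rows)


def export_heatmap_tables(
    type_matrix: pd.DataFrame, per_candidate_totals: pd.Series, outdir
) -> None:
    """Plotting-ready TSVs: sample x type matrix and per-candidate totals."""
    type_matrix.rename_axis("category").to_csv(
        os.path.join(outdir, "type_by_sample.tsv"), sep="\t"
    )
    type_matrix.T.rename_axis("sample").to_csv(
        os.path.join(outdir, "sample_by_type.tsv"), sep="\t"
    )
    per_candidate_totals.rename("total_normalized").rename_axis("candidate_id").to_csv(
        os.path.join(outdir, "candidate_totals.tsv"), sep="\t"
    )


_STAGES = [
    ("simulate", stage_simulate),
    ("search", stage_search),
    ("candidates", stage_candidates),
    ("quantify", stage_quantify),
    ("ordinate", stage_ordinate),
    ("cluster", stage_cluster),
    ("network", stage_network),
    ("summaries", stage_summaries),
]


def run_all(cfg: RunConfig) -> None:
    """Execute all enabled stages in order and write the run manifest."""
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "search": cfg.search,
            "candidates": cfg.candidates,
            "quantify": cfg.quantify,
            "ordinate": cfg.ordinate,
            "cluster": cfg.cluster,
            "network": cfg.network,
        },
        "provenance": _provenance(),
        "stages_run": [],
    }
    for name, fn in _STAGES:
        if not cfg.enabled(name):
            logger.info("[%s] skipped (disabled)", name)
            continue
        try:
            fn(cfg)
        except FileNotFoundError as exc:
            raise RuntimeError(f"stage '{name}': missing input: {exc}") from exc
        manifest["stages_run"].append(name)
    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
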