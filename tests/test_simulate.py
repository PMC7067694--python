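"""Synthetic community generator: determinism, truth structure, statistics."""

import hashlib
import os

import numpy as np
import pytest
from scipy import stats

from viromarker.io import read_fasta, write_dataset
from viromarker.search import translate_six_frames
from viromarker.simulate import (
    SimulationConfig,
    generate_abundance_profiles,
    generate_contigs,
    generate_env_table,
    generate_reads,
    generate_reference_panel,
    simulate_dataset,
)

from conftest import tiny_config


def _hash_tree(root) -> dict:
    out = {}
    for dirpath, _, files in os.walk(root):
        for fn in sorted(files):
            p = os.path.join(dirpath, fn)
            out[os.path.relpath(p, root)] = hashlib.sha256(
                open(p, "rb").read()
            ).hexdigest()
    return out


class TestReferencePanels:
    def test_counts_follow_config(self):
        cfg = tiny_config()
        panels = generate_reference_panel(cfg)
        assert len(panels) == 3
        assert sum(len(p.records) for p in panels.values()) == 6

    def test_same_seed_identical_panels(self):
        a = generate_reference_panel(tiny_config(seed=3))
        b = generate_reference_panel(tiny_config(seed=3))
        assert {r.id: r.seq for p in a.values() for r in p.records} == {
            r.id: r.seq for p in b.values() for r in p.records
        }

    def test_min_length_matches_shortest_member(self, tmp_path):
        cfg = tiny_config(seed=4)
        panels = generate_reference_panel(cfg)
        ds_fasta = tmp_path / "p.fasta"
        from viromarker.io import write_fasta

        for name, panel in panels.items():
            write_fasta({r.id: r.seq for r in panel.records}, ds_fasta)
            scanned = min(len(s) for s in read_fasta(ds_fasta).values())
            assert panel.min_aa_length == scanned

    def test_within_category_similarity_exceeds_between(self):
        panels = generate_reference_panel(tiny_config(seed=5))
        def ident(a, b):
            return np.mean([x == y for x, y in zip(a, b)])
        names = list(panels)
        within = [
            ident(panels[n].records[0].seq, panels[n].records[1].seq) for n in names
        ]
        between = [
            ident(panels[a].records[0].seq, panels[b].records[0].seq)
            for a in names for b in names if a < b
        ]
        assert min(within) > max(between)

    def test_empty_categories_rejected(self):
        with pytest.raises(ValueError):
            tiny_config(categories=[])


class TestContigs:
    def test_zero_mutation_back_translates_to_source(self):
        cfg = tiny_config(seed=6, contig_mutation_rate=0.0)
        panels = generate_reference_panel(cfg)
        contigs, truth = generate_contigs(panels, cfg)
        refs = {r.id: r.seq for p in panels.values() for r in p.records}
        for row in truth.markers.itertuples():
            region = contigs[row.contig_id][row.start : row.end]
            frames = translate_six_frames(region)
            strand = row.strand
            prot = next(f.protein for f in frames if f.strand == strand and f.frame == 1)
            assert prot == refs[row.ref_id]

    def test_truth_coordinates_within_bounds(self, tiny_dataset):
        for row in tiny_dataset.truth.markers.itertuples():
            assert 0 <= row.start < row.end <= len(tiny_dataset.contigs[row.contig_id])

    def test_decoys_emitted(self, tiny_dataset):
        assert sum(1 for c in tiny_dataset.contigs if c.startswith("decoy")) == 3


class TestAbundance:
    def test_perfect_pair_correlation_is_one(self):
        cfg = tiny_config(
            seed=7,
            planted_pairs=[("ssRNA_cand00", "host_bacteria_cand00", 1.0)],
        )
        panels = generate_reference_panel(cfg)
        contigs, truth = generate_contigs(panels, cfg)
        truth = generate_abundance_profiles(cfg, truth)
        logx = np.log(truth.expected_counts)
        r = np.corrcoef(
            logx.loc["contig_ssRNA_cand00"], logx.loc["contig_host_bacteria_cand00"]
        )[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_planted_correlation_recovered_over_seeds(self):
        """Mean empirical pair correlation within +-0.05 of 0.9 over 100 seeds
        at 35 samples (per-seed values within +-0.15)."""
        rs = []
        for seed in range(100):
            cfg = SimulationConfig(seed=seed)
            panels = generate_reference_panel(cfg)
            contigs, truth = generate_contigs(panels, cfg)
            truth = generate_abundance_profiles(cfg, truth)
            logx = np.log(truth.expected_counts)
            contig_of = dict(
                zip(truth.markers["candidate_id"], truth.markers["contig_id"])
            )
            p = truth.planted_pairs[0]
            rs.append(
                np.corrcoef(
                    logx.loc[contig_of[p.virus_id]], logx.loc[contig_of[p.host_id]]
                )[0, 1]
            )
        assert abs(np.mean(rs) - 0.9) <= 0.05
        assert np.percentile(np.abs(np.array(rs) - 0.9), 90) <= 0.15

    def test_background_pairs_nearly_uncorrelated(self):
        cfg = SimulationConfig(seed=42)
        panels = generate_reference_panel(cfg)
        contigs, truth = generate_contigs(panels, cfg)
        truth = generate_abundance_profiles(cfg, truth)
        logx = np.log(truth.expected_counts)
        contig_of = dict(zip(truth.markers["candidate_id"], truth.markers["contig_id"]))
        paired = {contig_of[p.virus_id] for p in truth.planted_pairs} | {
            contig_of[p.host_id] for p in truth.planted_pairs
        }
        bg = logx.drop(index=[c for c in logx.index if c in paired])
        R = np.corrcoef(bg)
        iu = np.triu_indices_from(R, k=1)
        assert np.abs(R[iu]).mean() <= 0.25

    def test_unknown_pair_member_rejected(self):
        cfg = tiny_config(seed=8, planted_pairs=[("nope", "host_bacteria_cand00", 0.5)])
        panels = generate_reference_panel(cfg)
        contigs, truth = generate_contigs(panels, cfg)
        with pytest.raises(ValueError, match="unknown candidate"):
            generate_abundance_profiles(cfg, truth)

    def test_correlation_magnitude_capped(self):
        with pytest.raises(ValueError):
            tiny_config(planted_pairs=[("a", "b", 1.2)])


class TestReads:
    def test_zero_error_reads_are_exact_substrings(self, zero_noise_dataset):
        ds = zero_noise_dataset
        def rc(s):
            return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        for sample, reads in list(ds.reads.reads.items())[:2]:
            for r in reads[:50]:
                src = ds.contigs[r.source]
                assert r.seq in src or rc(r.seq) in src

    def test_record_counts_equal_library_sizes(self, tiny_dataset):
        for sample, reads in tiny_dataset.reads.reads.items():
            assert len(reads) == tiny_dataset.reads.library_sizes[sample]

    def test_attribution_conserves_reads(self, tiny_dataset):
        truth = tiny_dataset.truth
        total_emitted = sum(len(v) for v in tiny_dataset.reads.reads.values())
        assert int(truth.attribution.to_numpy().sum()) == total_emitted
        # and every read's source is a known contig
        for reads in tiny_dataset.reads.reads.values():
            for r in reads[:20]:
                assert r.source in tiny_dataset.contigs

    def test_realized_counts_match_expectation_poisson(self, tiny_dataset):
        truth = tiny_dataset.truth
        E = truth.expected_counts.to_numpy().ravel()
        O = truth.attribution.to_numpy().ravel().astype(float)
        keep = E >= 5
        chi2 = float(np.sum((O[keep] - E[keep]) ** 2 / E[keep]))
        p = stats.chi2.sf(chi2, df=keep.sum())
        assert p > 1e-4

    def test_read_length_must_fit_contigs(self):
        cfg = tiny_config(seed=9, read_length=100000)
        panels = generate_reference_panel(cfg)
        contigs, truth = generate_contigs(panels, cfg)
        truth = generate_abundance_profiles(cfg, truth)
        with pytest.raises(ValueError, match="read length"):
            generate_reads(contigs, truth, cfg)


class TestEnv:
    def test_linked_variable_tracks_latent_axis(self, tiny_dataset):
        env = tiny_dataset.env
        t = tiny_dataset.truth.latent_axis
        r = np.corrcoef(env["pH"], t)[0, 1]
        assert abs(r) > 0.8

    def test_unknown_link_rejected(self):
        cfg = tiny_config(seed=10, env_vars=[("x", "axis7")])
        panels = generate_reference_panel(cfg)
        contigs, truth = generate_contigs(panels, cfg)
        truth = generate_abundance_profiles(cfg, truth)
        with pytest.raises(ValueError, match="env link"):
            generate_env_table(cfg, truth)


def test_same_seed_byte_identical_dataset(tmp_path):
    """Writing the same seeded dataset twice produces identical bytes."""
    a, b = tmp_path / "a", tmp_path / "b"
    write_dataset(simulate_dataset(tiny_config(seed=13)), a)
    write_dataset(simulate_dataset(tiny_config(seed=13)), b)
    ha, hb = _hash_tree(a), _hash_tree(b)
    assert ha == hb and len(ha) > 5
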