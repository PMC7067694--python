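"""Extraction, dual stringency, back-validation, completeness, richness."""

import pandas as pd
import pytest

from viromarker.candidates import (
    Candidate,
    DomainHit,
    StringencyParams,
    apply_stringency,
    back_validate,
    call_near_full_genomes,
    classify_completeness,
    extract_candidates,
    summarize_richness,
)
from viromarker.search import AlignmentHit
from viromarker.simulate import MarkerReference, ReferencePanel


def hit(contig="c1", ref="v_ref", s=300, e=600, ev=1e-20, strand="+", bits=100.0):
    return AlignmentHit(
        query_id=contig, subject_id=ref, bit_score=bits, evalue=ev,
        q_start_nt=s, q_end_nt=e, strand=strand, s_start_aa=0,
        s_end_aa=(e - s) // 3, aligned_aa_length=(e - s) // 3,
        percent_identity=95.0,
    )


REF_META = {
    "v_ref": ("NCLDV", "virus", "fam_a"),
    "v_ref2": ("NCLDV", "virus", "fam_b"),
    "r_ref": ("ssRNA", "virus", "fam_c"),
    "h_ref": ("host_bacteria", "host", "fam_h"),
}

CONTIGS = {"c1": "ACGT" * 300, "c2": "TGCA" * 300}


def cand(cid="x", role="virus", ev=1e-12, length=300, category="NCLDV"):
    return Candidate(
        candidate_id=cid, contig_id="c1", seq="A" * length, start=0, end=length,
        strand="+", ref_id="v_ref", family_label="fam_a", category=category,
        role=role, evalue=ev,
    )


class TestExtraction:
    def test_single_hit_slices_contig(self):
        (c,) = extract_candidates([hit()], CONTIGS, REF_META)
        assert c.seq == CONTIGS["c1"][300:600]
        assert (c.start, c.end, c.length_nt) == (300, 600, 300)

    def test_overlapping_same_category_hits_merge(self):
        cands = extract_candidates(
            [hit(s=300, e=600), hit(ref="v_ref2", s=550, e=700, ev=1e-10)],
            CONTIGS, REF_META,
        )
        assert len(cands) == 1
        assert (cands[0].start, cands[0].end) == (300, 700)
        # best e-value supplies the assignment
        assert cands[0].ref_id == "v_ref"

    def test_different_categories_stay_separate(self):
        cands = extract_candidates(
            [hit(), hit(ref="r_ref", s=700, e=900)], CONTIGS, REF_META
        )
        assert len(cands) == 2
        assert {c.category for c in cands} == {"NCLDV", "ssRNA"}

    def test_interval_outside_contig_rejected(self):
        with pytest.raises(ValueError, match="corrupt|outside"):
            extract_candidates([hit(s=1100, e=1300)], {"c1": "A" * 1200}, REF_META)

    def test_minus_strand_extracts_reverse_complement(self):
        contig = {"c1": "A" * 300 + "ACGTTT" * 50 + "G" * 300}
        (c,) = extract_candidates([hit(s=300, e=600, strand="-")], contig, REF_META)
        region = contig["c1"][300:600]
        rc = region.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert c.seq == rc


class TestStringency:
    def test_virus_within_threshold_kept(self):
        kept, dropped = apply_stringency([cand(ev=1e-12, length=300)])
        assert len(kept) == 1 and not dropped

    def test_length_exactly_150_removed(self):
        kept, dropped = apply_stringency([cand(ev=1e-12, length=150)])
        assert not kept and dropped[0].drop_reason == "length"

    def test_length_boundary_configurable(self):
        kept, _ = apply_stringency(
            [cand(ev=1e-12, length=150)], StringencyParams(length_strict=False)
        )
        assert len(kept) == 1

    def test_host_needs_stronger_evalue(self):
        kept, dropped = apply_stringency([cand(role="host", ev=1e-20)])
        assert not kept and dropped[0].drop_reason == "evalue"
        kept, _ = apply_stringency([cand(role="virus", ev=1e-20)])
        assert len(kept) == 1

    def test_filter_monotone_under_tightening(self):
        cands = [cand(cid=f"c{i}", ev=10.0 ** -(i + 8), length=140 + 20 * i)
                 for i in range(10)]
        base, _ = apply_stringency(cands)
        tighter_e, _ = apply_stringency(
            cands, StringencyParams(virus_evalue_max=1e-14)
        )
        longer, _ = apply_stringency(cands, StringencyParams(min_length_nt=250))
        base_ids = {c.candidate_id for c in base}
        assert {c.candidate_id for c in tighter_e} <= base_ids
        assert {c.candidate_id for c in longer} <= base_ids

    def test_cascade_idempotent(self):
        cands = [cand(cid=f"c{i}", ev=10.0 ** -(i + 8), length=140 + 20 * i)
                 for i in range(10)]
        once, _ = apply_stringency(cands)
        twice, dropped = apply_stringency(once)
        assert twice == once and not dropped


class TestBackValidation:
    ROLE_MAP = {"virus_poly": "viral", "bact_poly": "non_viral"}

    def vhit(self, cid, subject, ev):
        return AlignmentHit(
            query_id=cid, subject_id=subject, bit_score=50.0, evalue=ev,
            q_start_nt=0, q_end_nt=30, strand="+", s_start_aa=0, s_end_aa=10,
            aligned_aa_length=10, percent_identity=90.0,
        )

    def test_nonviral_best_hit_is_false_positive(self):
        c = cand(cid="q1")
        _, failed = back_validate(
            [c],
            [self.vhit("q1", "bact_poly", 1e-30), self.vhit("q1", "virus_poly", 1e-10)],
            self.ROLE_MAP,
        )
        assert failed and failed[0].validation == "false_positive"

    def test_viral_best_hit_passes(self):
        c = cand(cid="q1")
        passed, _ = back_validate([c], [self.vhit("q1", "virus_poly", 1e-30)],
                                  self.ROLE_MAP)
        assert passed and passed[0].validation == "passed"

    def test_no_hit_is_false_positive(self):
        _, failed = back_validate([cand(cid="q1")], [], self.ROLE_MAP)
        assert failed[0].drop_reason == "validation_no_hit"

    def test_tie_is_conservative(self):
        hits = [self.vhit("q1", "virus_poly", 1e-20),
                self.vhit("q1", "bact_poly", 1e-20)]
        _, failed = back_validate([cand(cid="q1")], hits, self.ROLE_MAP)
        assert failed and failed[0].validation == "false_positive"

    def test_unknown_subject_rejected(self):
        with pytest.raises(ValueError, match="role map"):
            back_validate([cand(cid="q1")], [self.vhit("q1", "mystery", 1e-20)],
                          self.ROLE_MAP)


class TestCompleteness:
    def panel(self, min_len):
        recs = [
            MarkerReference("r1", "M" * min_len, "NCLDV", "virus", "f"),
            MarkerReference("r2", "M" * (min_len + 30), "NCLDV", "virus", "f"),
        ]
        return ReferencePanel("NCLDV", "virus", recs)

    def test_long_candidate_near_complete(self):
        c = classify_completeness(cand(length=600), self.panel(180))
        assert c.completeness == "near_complete"

    def test_short_candidate_fragment(self):
        c = classify_completeness(cand(length=450), self.panel(180))
        assert c.completeness == "fragment"

    def test_boundary_counts_as_near_complete(self):
        c = classify_completeness(cand(length=540), self.panel(180))
        assert c.length_aa == 180
        assert c.completeness == "near_complete"


class TestNearFullGenomes:
    def test_both_components_flags_contig(self):
        c = cand(category="ssRNA")
        domains = [
            DomainHit("c1", "RdRp", "non_structural"),
            DomainHit("c1", "capsid", "structural"),
        ]
        assert call_near_full_genomes([c], domains) == {"c1"}

    def test_single_component_not_flagged(self):
        c = cand(category="ssRNA")
        assert call_near_full_genomes([c], [DomainHit("c1", "RdRp", "non_structural")]) == set()

    def test_empty_domain_table(self):
        assert call_near_full_genomes([cand()], []) == set()

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            call_near_full_genomes([cand()], [DomainHit("c1", "x", "other")])

    def test_domain_table_round_trip(self, tmp_path):
        from viromarker.candidates import read_domain_table

        p = tmp_path / "domains.tsv"
        p.write_text(
            "contig_id\tdomain\tdomain_class\n"
            "c1\tRdRp\tnon_structural\nc1\tcapsid\tstructural\n"
        )
        hits = read_domain_table(p)
        assert call_near_full_genomes([cand(category="ssRNA")], hits) == {"c1"}

    def test_domain_table_missing_column_rejected(self, tmp_path):
        from viromarker.candidates import read_domain_table

        p = tmp_path / "bad.tsv"
        p.write_text("contig_id\tdomain\nc1\tRdRp\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_domain_table(p)


class TestRichness:
    def test_counts_per_category(self):
        cands = [cand(cid=f"n{i}") for i in range(5)] + [
            cand(cid=f"r{i}", category="ssRNA") for i in range(3)
        ]
        table = summarize_richness(cands).set_index("category")
        assert table.loc["NCLDV", "n_candidates"] == 5
        assert table.loc["ssRNA", "n_candidates"] == 3

    def test_shares_sum_to_100_over_viral_categories(self):
        cands = [
            cand(cid="a"),
            cand(cid="b", category="ssRNA"),
            cand(cid="h", role="host", category="host_bacteria", ev=1e-40),
        ]
        reads = pd.Series({"a": 30.0, "b": 70.0, "h": 500.0})
        table = summarize_richness(cands, reads).set_index("category")
        viral = table[table["role"] == "virus"]
        assert viral["viral_read_share_pct"].sum() == pytest.approx(100.0, abs=1e-9)
        assert table.loc["ssRNA", "viral_read_share_pct"] == pytest.approx(70.0)
        assert table.loc["host_bacteria", "viral_read_share_pct"] == 0.0

    def test_zero_read_category(self):
        cands = [cand(cid="a"), cand(cid="b", category="ssRNA")]
        reads = pd.Series({"a": 10.0, "b": 0.0})
        table = summarize_richness(cands, reads).set_index("category")
        assert table.loc["ssRNA", "viral_read_share_pct"] == 0.0
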