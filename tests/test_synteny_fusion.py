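import pytest

from thiocomp.homology_search import ProteinDatabase
from thiocomp.io_formats import AlignmentHit, MembershipRow, OrfRecord, SeqRecord
from thiocomp.synteny_fusion import (
    Anchor,
    anchor_orfs,
    build_blocks,
    call_fusions,
    flag_discordant_orfs,
)


def _orf(contig, tag, start, end, strand="+", translation=""):
    return OrfRecord(contig_id=contig, locus_tag=tag, start=start, end=end,
                     strand=strand, translation=translation)


def _anchor(q, r, pid=70.0, e=1e-40):
    return Anchor(query_orf=q, reference_orf=r, percent_identity=pid,
                  alignment_length=200, e_value=e, bit_score=150.0)


def _pp_hit(q, s, e=1e-40, bits=150.0, s_start=1, s_end=200, q_start=1, q_end=200):
    return AlignmentHit(query_id=q, subject_id=s, percent_identity=70.0,
                        alignment_length=q_end - q_start + 1, mismatches=0,
                        gap_openings=0, q_start=q_start, q_end=q_end,
                        s_start=s_start, s_end=s_end, e_value=e, bit_score=bits)


def _ref_series(n, start=1, spacing=1500, length=900):
    return [
        _orf("REF", f"R{i:03d}", start + i * spacing, start + i * spacing + length - 1)
        for i in range(n)
    ]


def _query_series(refs, contig="Q1", spacing=1500, length=900):
    return [
        _orf(contig, f"Q{i:03d}", 1 + i * spacing, i * spacing + length)
        for i in range(len(refs))
    ]


class TestAnchorOrfs:
    def test_identical_orf_sets_anchor_one_to_one(self):
        refs = _ref_series(5)
        qs = _query_series(refs)
        hits = [_pp_hit(q.locus_tag, r.locus_tag, e=1e-80) for q, r in zip(qs, refs)]
        anchors, unanchored = anchor_orfs(qs, refs, hits)
        assert len(anchors) == 5 and unanchored == []
        assert [a.reference_orf.locus_tag for a in anchors] == [r.locus_tag for r in refs]

    def test_weak_hits_leave_orf_unanchored(self):
        refs = _ref_series(1)
        qs = _query_series(refs)
        anchors, unanchored = anchor_orfs(qs, refs, [_pp_hit("Q000", "R000", e=1e-3)])
        assert anchors == [] and [o.locus_tag for o in unanchored] == ["Q000"]

    def test_best_hit_wins_with_tiebreaks(self):
        refs = _ref_series(2)
        qs = _query_series(refs)[:1]
        hits = [
            _pp_hit("Q000", "R001", e=1e-40, bits=100.0),
            _pp_hit("Q000", "R000", e=1e-40, bits=200.0),
        ]
        anchors, _ = anchor_orfs(qs, refs, hits)
        assert anchors[0].reference_orf.locus_tag == "R000"

    def test_unknown_locus_raises(self):
        refs = _ref_series(1)
        qs = _query_series(refs)
        with pytest.raises(ValueError, match="unknown locus"):
            anchor_orfs(qs, refs, [_pp_hit("Q000", "MYSTERY", e=1e-40)])

    def test_synthetic_anchor_identities_track_ledger(self, small_sim):
        # anchoring the annotated query ORFs back onto the reference proteins
        # must reproduce the planted per-ORF amino-acid identities
        ref, qry = small_sim.reference, small_sim.query
        db = ProteinDatabase(ref.protein_records())
        hits = [h for p in qry.protein_records() if p.sequence for h in db.search(p)]
        anchors, _ = anchor_orfs(qry.orfs, ref.orfs, hits)
        planted = {
            r.note.split(";")[0].split("=")[0]: r.identity
            for r in small_sim.ledger.of_kind("orf-identity")
        }
        checked = 0
        for a in anchors:
            if a.query_orf.locus_tag in planted:
                expected = 100 * planted[a.query_orf.locus_tag]
                assert abs(a.percent_identity - expected) <= 5.0
                checked += 1
        assert checked >= 0.8 * len(planted)


class TestBuildBlocks:
    def test_colinear_anchors_form_one_block(self):
        refs = _ref_series(6)
        qs = _query_series(refs)
        anchors = [_anchor(q, r) for q, r in zip(qs, refs)]
        blocks, breaks, singles = build_blocks(anchors)
        assert len(blocks) == 1 and breaks == [] and singles == []
        assert blocks[0].sense == "colinear"

    def test_large_jump_breaks_block_and_records_distance(self):
        refs = _ref_series(3) + [
            _orf("REF", "Rfar", 60_001, 60_900),
            _orf("REF", "Rfar2", 61_501, 62_400),
        ]
        qs = _query_series(refs)
        anchors = [_anchor(q, r) for q, r in zip(qs, refs)]
        blocks, breaks, _ = build_blocks(anchors, max_reference_jump_bp=20_000)
        assert len(blocks) == 2
        assert len(breaks) == 1
        assert breaks[0].kind == "jump"
        assert breaks[0].reference_distance == pytest.approx(57_450, abs=1000)

    def test_sense_flip_closes_block(self):
        refs = _ref_series(5)
        qs = _query_series(refs)
        qs[2] = _orf("Q1", "Q002", qs[2].start, qs[2].end, strand="-")
        anchors = [_anchor(q, r) for q, r in zip(qs, refs)]
        blocks, breaks, singles = build_blocks(anchors)
        assert any(b.kind == "sense-flip" for b in breaks)
        # the lone inverted anchor cannot join either flanking block
        assert len(singles) == 1 and singles[0].query_orf.locus_tag == "Q002"

    def test_every_anchor_in_exactly_one_block_or_singleton(self, small_sim):
        ref, qry = small_sim.reference, small_sim.query
        db = ProteinDatabase(ref.protein_records())
        hits = [h for p in qry.protein_records() if p.sequence for h in db.search(p)]
        anchors, _ = anchor_orfs(qry.orfs, ref.orfs, hits)
        blocks, breaks, singles = build_blocks(anchors)
        placed = [a.query_orf.locus_tag for b in blocks for a in b.anchors] + [
            a.query_orf.locus_tag for a in singles
        ]
        assert sorted(placed) == sorted(a.query_orf.locus_tag for a in anchors)

    def test_reversing_the_contig_flips_sense_not_composition(self):
        refs = _ref_series(6)
        qs = _query_series(refs)
        anchors = [_anchor(q, r) for q, r in zip(qs, refs)]
        (fwd,), _, _ = build_blocks(anchors)
        contig_len = 20_000
        rev_qs = [
            _orf("Q1", q.locus_tag, contig_len - q.end + 1, contig_len - q.start + 1,
                 strand="-")
            for q in qs
        ]
        rev_anchors = [_anchor(q, r) for q, r in zip(rev_qs, refs)]
        (rev,), rev_breaks, _ = build_blocks(rev_anchors)
        assert rev_breaks == []
        assert fwd.sense == "colinear" and rev.sense == "inverted"
        assert {a.reference_orf.locus_tag for a in rev.anchors} == {
            a.reference_orf.locus_tag for a in fwd.anchors
        }


class TestCallFusions:
    def _setup(self, cov1=(1, 150), cov2=(160, 300), strand="+"):
        ref = _orf("REF", "Rfus", 1000, 1902, translation="M" * 300)
        q1 = _orf("Q1", "Qa", 100, 549, strand=strand)
        q2 = _orf("Q1", "Qb", 560, 1009, strand=strand)
        h1 = _pp_hit("Qa", "Rfus", s_start=cov1[0], s_end=cov1[1])
        h2 = _pp_hit("Qb", "Rfus", s_start=cov2[0], s_end=cov2[1])
        return ref, [q1, q2], [h1, h2]

    def test_clean_split_is_called(self):
        ref, qs, hits = self._setup()
        calls = call_fusions([], hits, [ref], qs)
        assert len(calls) == 1
        assert calls[0].reference_orf.locus_tag == "Rfus"
        assert calls[0].coverage_each == (0.5, 0.47)

    def test_same_half_twice_is_rejected(self):
        ref, qs, hits = self._setup(cov1=(1, 150), cov2=(1, 150))
        assert call_fusions([], hits, [ref], qs) == []

    def test_single_full_cover_is_not_a_fusion(self):
        ref = _orf("REF", "Rfus", 1000, 1902, translation="M" * 300)
        q1 = _orf("Q1", "Qa", 100, 1002)
        hits = [_pp_hit("Qa", "Rfus", s_start=1, s_end=300)]
        assert call_fusions([], hits, [ref], [q1]) == []

    def test_wrong_order_on_plus_strand_rejected(self):
        ref, qs, hits = self._setup(cov1=(160, 300), cov2=(1, 150))
        assert call_fusions([], hits, [ref], qs) == []

    def test_minus_strand_order_is_mirrored(self):
        ref, qs, hits = self._setup(cov1=(160, 300), cov2=(1, 150), strand="-")
        assert len(call_fusions([], hits, [ref], qs)) == 1

    def test_low_coverage_rejected(self):
        ref, qs, hits = self._setup(cov1=(1, 50), cov2=(160, 300))
        assert call_fusions([], hits, [ref], qs) == []


class TestDiscordantOrfs:
    def _frame(self):
        refs = _ref_series(3)
        qs = _query_series(refs)
        anchors = [_anchor(q, r) for q, r in zip(qs, refs)]
        alien = _orf("Q1", "Alien", 3100, 3699, strand="-")
        orfs = qs[:2] + [alien] + qs[2:]
        return anchors, orfs

    def test_reverse_oriented_unanchored_orf_flagged(self):
        anchors, orfs = self._frame()
        flags = flag_discordant_orfs(anchors, orfs)
        assert [f.orf.locus_tag for f in flags] == ["Alien"]
        assert flags[0].reason == "unanchored"

    def test_native_colinear_orf_not_flagged(self):
        refs = _ref_series(3)
        qs = _query_series(refs)
        anchors = [_anchor(q, r) for q, r in zip(qs, refs)]
        assert flag_discordant_orfs(anchors, qs) == []

    def test_same_strand_neighbour_blocks_flag(self):
        anchors, orfs = self._frame()
        orfs = [
            _orf(o.contig_id, o.locus_tag, o.start, o.end, strand="-")
            if o.locus_tag == "Q001"
            else o
            for o in orfs
        ]
        assert flag_discordant_orfs(anchors, orfs) == []

    def test_spanning_reads_mark_assembly_support(self):
        anchors, orfs = self._frame()
        rows = [
            MembershipRow(f"r{i}", "Q1", 800, 2800, 3599) for i in range(3)
        ] + [MembershipRow("far", "Q1", 800, 100, 899)]
        flags = flag_discordant_orfs(anchors, orfs, membership=rows)
        assert flags[0].n_spanning_reads == 3
        assert flags[0].assembly_supported is True

    def test_secondary_hits_can_flag_anchored_orfs(self):
        refs = _ref_series(3)
        qs = _query_series(refs)
        qs[1] = _orf("Q1", "Q001", qs[1].start, qs[1].end, strand="-")
        anchors = [_anchor(q, r, e=1e-20) for q, r in zip(qs, refs)]
        sec = [_pp_hit("Q001", "OTHER_TAXON", e=1e-60)]
        flags = flag_discordant_orfs(anchors, qs, secondary_hits=sec)
        assert [f.orf.locus_tag for f in flags] == ["Q001"]
        assert flags[0].reason == "better-secondary-hit"

    def test_planted_foreign_orfs_all_flagged(self, small_sim):
        ref, qry = small_sim.reference, small_sim.query
        db = ProteinDatabase(ref.protein_records())
        hits = [h for p in qry.protein_records() if p.sequence for h in db.search(p)]
        anchors, _ = anchor_orfs(qry.orfs, ref.orfs, hits)
        flags = flag_discordant_orfs(anchors, qry.orfs)
        flagged_spans = {(f.orf.start - 1, f.orf.end) for f in flags}
        for r in small_sim.ledger.of_kind("foreign-orf"):
            assert (r.query_start, r.query_end) in flagged_spans
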