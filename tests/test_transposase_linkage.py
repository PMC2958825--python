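import pytest

from thiocomp.contig_stats import ContigStat
from thiocomp.io_formats import AlignmentHit, ClonePair, MembershipRow
from thiocomp.transposase_linkage import (
    ContigLinkage,
    LinkageReport,
    classify_transposase_sequences,
    density_estimate,
    link_contigs,
    reference_density,
)


def _tp_hit(subject, e):
    return AlignmentHit(query_id="TPASE_1", subject_id=subject, percent_identity=90.0,
                        alignment_length=150, mismatches=0, gap_openings=0,
                        q_start=1, q_end=150, s_start=1, s_end=450, e_value=e,
                        bit_score=200.0, frame=1)


class TestClassify:
    def test_cutoff_excludes_weak_hits(self):
        hits = [_tp_hit("r1", 1e-5), _tp_hit("r2", 1e-12)]
        assert classify_transposase_sequences(hits) == {"r2"}

    def test_empty_hit_table(self):
        assert classify_transposase_sequences([]) == set()

    def test_planted_copies_flag_their_reads(self, small_sim):
        from thiocomp.homology_search import TranslatedDatabase

        tp = small_sim.transposase_protein
        db = TranslatedDatabase(small_sim.reads)
        flagged = classify_transposase_sequences(db.search(tp))
        spans = [
            (r.query_start, r.query_end)
            for r in small_sim.ledger.of_kind("transposase-copy")
        ]
        expected = set()
        for read in small_sim.reads:
            s, e, _ = small_sim.read_truth[read.id]
            if any(min(e, b) - max(s, a) >= 150 for a, b in spans):
                expected.add(read.id)
        assert expected <= flagged  # every >=150 bp overlap is found


def _frame(n_contigs=2, reads_per=4, flagged_mates=1, length=12_000):
    membership, pairs, flagged = [], [], set()
    stats = []
    k = 0
    for ci in range(n_contigs):
        cid = f"C{ci}"
        stats.append(ContigStat(cid, length, None, 0.4, None, "none", 0))
        for ri in range(reads_per):
            stem = f"P{k:04d}"
            k += 1
            membership.append(MembershipRow(f"{stem}.b1", cid, 750, 1, 750))
            membership.append(MembershipRow(f"{stem}.g1", "", 750))
            pairs.append(ClonePair(stem, f"{stem}.b1", f"{stem}.g1"))
            if ri < flagged_mates:
                flagged.add(f"{stem}.g1")
    return membership, pairs, flagged, stats


class TestLinkContigs:
    def test_printed_tally_arithmetic(self):
        # 1294 member reads across large contigs, 49 with transposase mates
        membership, pairs, flagged, stats = [], [], set(), []
        for ci in range(17):
            cid = f"C{ci}"
            stats.append(ContigStat(cid, 14_000, None, 0.4, None, "none", 0))
        k = 0
        for i in range(1294):
            cid = f"C{i % 17}"
            stem = f"P{k:05d}"
            k += 1
            membership.append(MembershipRow(f"{stem}.b1", cid, 750, 1, 750))
            membership.append(MembershipRow(f"{stem}.g1", "", 750))
            pairs.append(ClonePair(stem, f"{stem}.b1", f"{stem}.g1"))
            if i < 49:
                flagged.add(f"{stem}.g1")
        report = link_contigs(membership, pairs, flagged, stats)
        assert report.n_member_reads_total == 1294
        assert report.n_linked_reads_total == 49
        assert report.linked_read_percent == 3.8

    def test_no_flags_means_no_linked_contigs(self):
        membership, pairs, _, stats = _frame()
        report = link_contigs(membership, pairs, set(), stats)
        assert report.n_linked_contigs == 0

    def test_small_contigs_are_excluded(self):
        membership, pairs, flagged, stats = _frame(length=9_000)
        report = link_contigs(membership, pairs, flagged, stats)
        assert report.n_large_contigs == 0

    def test_pair_role_swap_changes_nothing(self):
        membership, pairs, flagged, stats = _frame()
        swapped = [ClonePair(p.stem, p.reverse_read_id, p.forward_read_id) for p in pairs]
        a = link_contigs(membership, pairs, flagged, stats)
        b = link_contigs(membership, swapped, flagged, stats)
        assert a.linked_read_percent == b.linked_read_percent
        assert a.n_linked_contigs == b.n_linked_contigs

    def test_renaming_preserving_pairing_changes_nothing(self):
        membership, pairs, flagged, stats = _frame()
        ren = lambda x: "X" + x
        membership2 = [
            MembershipRow(ren(r.read_id), r.contig_id, r.read_bp, r.start, r.end)
            for r in membership
        ]
        pairs2 = [ClonePair(ren(p.stem), ren(p.forward_read_id), ren(p.reverse_read_id)) for p in pairs]
        flagged2 = {ren(f) for f in flagged}
        a = link_contigs(membership, pairs, flagged, stats)
        b = link_contigs(membership2, pairs2, flagged2, stats)
        assert a.linked_read_percent == b.linked_read_percent

    def test_missing_mate_counts_unlinked(self, caplog):
        import logging

        membership = [MembershipRow("A.b1", "C0", 750, 1, 750)]
        pairs = [ClonePair("A", "A.b1", "A.g1")]
        stats = [ContigStat("C0", 12_000, None, 0.4, None, "none", 0)]
        with caplog.at_level(logging.WARNING, logger="thiocomp.transposase_linkage"):
            report = link_contigs(membership, pairs, {"A.g1"}, stats)
        assert report.n_linked_reads_total == 0
        assert "missing" in caplog.text

    def test_same_contig_mates_can_be_excluded(self):
        membership = [
            MembershipRow("A.b1", "C0", 750, 1, 750),
            MembershipRow("A.g1", "C0", 750, 3000, 3750),
        ]
        pairs = [ClonePair("A", "A.b1", "A.g1")]
        stats = [ContigStat("C0", 12_000, None, 0.4, None, "none", 0)]
        inc = link_contigs(membership, pairs, {"A.g1"}, stats)
        exc = link_contigs(membership, pairs, {"A.g1"}, stats, count_same_contig_mates=False)
        assert inc.n_linked_reads_total == 1
        assert exc.n_linked_reads_total == 0

    def test_contig_can_both_encode_and_link(self):
        membership, pairs, flagged, stats = _frame(n_contigs=1)
        flagged.add("C0")
        report = link_contigs(membership, pairs, flagged, stats)
        assert report.contigs[0].encodes_transposase
        assert report.contigs[0].linked


class TestDensity:
    def test_sixteen_contigs_totalling_244kb(self):
        contigs = [
            ContigLinkage(f"C{i}", 15_250, 10, 1, False) for i in range(16)
        ]
        report = LinkageReport(10_000, contigs)
        kb, raw = density_estimate(report)
        assert kb == 15
        assert raw == pytest.approx(244 / 16)

    def test_single_linked_contig(self):
        report = LinkageReport(10_000, [ContigLinkage("C0", 15_000, 5, 2, False)])
        assert density_estimate(report)[0] == 15

    def test_reference_density_120kb(self):
        kb, raw = reference_density(2_400_000, 20)
        assert kb == 120 and raw == pytest.approx(120.0)

    def test_zero_linked_contigs_is_undefined(self):
        report = LinkageReport(10_000, [ContigLinkage("C0", 15_000, 5, 0, False)])
        with pytest.raises(ValueError, match="undefined"):
            density_estimate(report)
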