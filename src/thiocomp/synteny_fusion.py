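"""Synteny mapping between query-contig ORFs and a reference annotation.

Query ORFs are anchored to reference ORFs by best protein-protein hit; walks
along each contig segment the anchors into collinear blocks, recording
rearrangement breaks (large reference jumps or sense flips), gene fusions
(one reference ORF covered piecewise by two adjacent query ORFs), and
reverse-orientation query ORFs without reference homologs (putative lateral
acquisitions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import AlignmentHit, MembershipRow, OrfRecord

logger = logging.getLogger(__name__)

__all__ = [
    "Anchor",
    "SyntenyBlock",
    "SyntenyBreak",
    "FusionCall",
    "DiscordantOrf",
    "anchor_orfs",
    "build_blocks",
    "call_fusions",
    "flag_discordant_orfs",
]


@dataclass(frozen=True)
class Anchor:
    """Best-hit correspondence between one query ORF and one reference ORF."""

    query_orf: OrfRecord
    reference_orf: OrfRecord
    percent_identity: float
    alignment_length: int
    e_value: float
    bit_score: float

    @property
    def strands_equal(self) -> bool:
        return self.query_orf.strand == self.reference_orf.strand

    @property
    def orient(self) -> int:
        return 1 if self.strands_equal else -1

    @property
    def ref_mid(self) -> float:
        return self.reference_orf.midpoint

    @property
    def query_mid(self) -> float:
        return self.query_orf.midpoint


@dataclass
class SyntenyBlock:
    anchors: list[Anchor]
    sense: str  # "colinear" | "inverted"

    @property
    def contig_id(self) -> str:
        return self.anchors[0].query_orf.contig_id

    @property
    def reference_span(self) -> tuple[int, int]:
        starts = [a.reference_orf.start for a in self.anchors]
        ends = [a.reference_orf.end for a in self.anchors]
        return (min(starts), max(ends))

    @property
    def query_span(self) -> tuple[int, int]:
        starts = [a.query_orf.start for a in self.anchors]
        ends = [a.query_orf.end for a in self.anchors]
        return (min(starts), max(ends))


@dataclass(frozen=True)
class SyntenyBreak:
    left: Anchor
    right: Anchor
    reference_distance: int  # |ref jump| between the flanking anchors, bp
    kind: str  # "jump" | "sense-flip"

    @property
    def contig_id(self) -> str:
        return self.left.query_orf.contig_id


@dataclass(frozen=True)
class FusionCall:
    """One reference ORF matched piecewise by two adjacent query ORFs."""

    reference_orf: OrfRecord
    query_orf_pair: tuple[OrfRecord, OrfRecord]
    coverage_each: tuple[float, float]  # fraction of the reference protein
    overlap_residues: int  # overlap (+) or gap (-) between covered spans


@dataclass
class DiscordantOrf:
    orf: OrfRecord
    reason: str  # "unanchored" | "better-secondary-hit"
    n_spanning_reads: int | None = None

    @property
    def assembly_supported(self) -> bool | None:
        if self.n_spanning_reads is None:
            return None
        return self.n_spanning_reads >= 3


# ---------------------------------------------------------------------------

def anchor_orfs(
    query_orfs: Sequence[OrfRecord],
    reference_orfs: Sequence[OrfRecord],
    hits: Iterable[AlignmentHit],
    evalue_cutoff: float = 1e-5,
) -> tuple[list[Anchor], list[OrfRecord]]:
    """Anchor each query ORF to its best reference hit.

    Best = lowest E-value, tie broken by highest bit score, then lowest
    reference coordinate.  Query ORFs with no hit at or below the cutoff are
    returned separately as unanchored.
    """
    ref_by_tag = {o.locus_tag: o for o in reference_orfs}
    q_by_tag = {o.locus_tag: o for o in query_orfs}
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        if h.e_value > evalue_cutoff:
            continue
        if h.query_id not in q_by_tag or h.subject_id not in ref_by_tag:
            raise ValueError(
                f"hit names unknown locus: {h.query_id} vs {h.subject_id}"
            )
        key = (h.e_value, -h.bit_score, ref_by_tag[h.subject_id].start)
        cur = best.get(h.query_id)
        if cur is None or key < (
            cur.e_value,
            -cur.bit_score,
            ref_by_tag[cur.subject_id].start,
        ):
            best[h.query_id] = h
    anchors = []
    unanchored = []
    for orf in query_orfs:
        h = best.get(orf.locus_tag)
        if h is None:
            unanchored.append(orf)
            continue
        anchors.append(
            Anchor(
                query_orf=orf,
                reference_orf=ref_by_tag[h.subject_id],
                percent_identity=h.percent_identity,
                alignment_length=h.alignment_length,
                e_value=h.e_value,
                bit_score=h.bit_score,
            )
        )
    anchors.sort(key=lambda a: (a.query_orf.contig_id, a.query_mid))
    return anchors, unanchored


def build_blocks(
    anchors: Sequence[Anchor],
    max_reference_jump_bp: int = 20_000,
) -> tuple[list[SyntenyBlock], list[SyntenyBreak], list[Anchor]]:
    """Segment anchors (sorted by query position) into collinear blocks.

    Within a block, consecutive anchors advance along the reference by at
    most ``max_reference_jump_bp`` in the direction set by the block's sense
    (colinear blocks walk the reference forward, inverted blocks backward).
    A larger jump, a direction reversal, or a sense flip closes the block and
    records a break carrying the reference distance between the flanking
    anchors.  Blocks need >= 2 anchors; leftovers are reported as singletons.
    """
    blocks: list[SyntenyBlock] = []
    breaks: list[SyntenyBreak] = []
    singletons: list[Anchor] = []

    def close(run: list[Anchor]) -> None:
        if len(run) >= 2:
            sense = "colinear" if run[0].orient == 1 else "inverted"
            blocks.append(SyntenyBlock(anchors=list(run), sense=sense))
        else:
            singletons.extend(run)

    by_contig: dict[str, list[Anchor]] = {}
    for a in anchors:
        by_contig.setdefault(a.query_orf.contig_id, []).append(a)

    for contig in sorted(by_contig):
        contig_anchors = sorted(by_contig[contig], key=lambda a: a.query_mid)
        run: list[Anchor] = [contig_anchors[0]]
        for a in contig_anchors[1:]:
            prev = run[-1]
            delta = a.ref_mid - prev.ref_mid
            direction = prev.orient  # +1 colinear, -1 inverted
            if a.orient != prev.orient:
                breaks.append(
                    SyntenyBreak(prev, a, int(abs(delta)), kind="sense-flip")
                )
                close(run)
                run = [a]
            elif not (0 <= delta * direction <= max_reference_jump_bp):
                # delta == 0 (two query ORFs on one reference ORF, e.g. the
                # two halves of a fusion) continues the block
                breaks.append(SyntenyBreak(prev, a, int(abs(delta)), kind="jump"))
                close(run)
                run = [a]
            else:
                run.append(a)
        close(run)
    return blocks, breaks, singletons


def call_fusions(
    anchors: Sequence[Anchor],
    hits: Iterable[AlignmentHit],
    reference_orfs: Sequence[OrfRecord],
    query_orfs: Sequence[OrfRecord],
    min_cov_each: float = 0.25,
    max_overlap_res: int = 30,
    evalue_cutoff: float = 1e-5,
) -> list[FusionCall]:
    """Call reference ORFs that are fusions of two adjacent query ORFs.

    Two query ORFs consecutive in query coordinate order (same contig, same
    strand) each covering >= ``min_cov_each`` of one reference protein, with
    covered reference spans overlapping at most ``max_overlap_res`` residues
    and appearing in strand-consistent order, yield one call.
    """
    ref_by_tag = {o.locus_tag: o for o in reference_orfs}
    # best hit per (query ORF, reference ORF) pair
    pair_best: dict[tuple[str, str], AlignmentHit] = {}
    for h in hits:
        if h.e_value > evalue_cutoff:
            continue
        key = (h.query_id, h.subject_id)
        cur = pair_best.get(key)
        if cur is None or (h.e_value, -h.bit_score) < (cur.e_value, -cur.bit_score):
            pair_best[key] = h

    calls: list[FusionCall] = []
    by_contig: dict[str, list[OrfRecord]] = {}
    for o in query_orfs:
        by_contig.setdefault(o.contig_id, []).append(o)
    for contig in sorted(by_contig):
        orfs = sorted(by_contig[contig], key=lambda o: o.midpoint)
        for q1, q2 in zip(orfs, orfs[1:]):
            if q1.strand != q2.strand:
                continue
            refs = {
                r
                for (q, r) in pair_best
                if q == q1.locus_tag and (q2.locus_tag, r) in pair_best
            }
            for r in sorted(refs):
                ro = ref_by_tag[r]
                rlen = len(ro.translation) or (ro.length_bp // 3 - 1)
                h1 = pair_best[(q1.locus_tag, r)]
                h2 = pair_best[(q2.locus_tag, r)]
                s1 = (min(h1.s_start, h1.s_end), max(h1.s_start, h1.s_end))
                s2 = (min(h2.s_start, h2.s_end), max(h2.s_start, h2.s_end))
                cov1 = (s1[1] - s1[0] + 1) / rlen
                cov2 = (s2[1] - s2[0] + 1) / rlen
                if cov1 < min_cov_each or cov2 < min_cov_each:
                    continue
                overlap = min(s1[1], s2[1]) - max(s1[0], s2[0]) + 1
                if overlap > max_overlap_res:
                    continue
                # order consistency: on '+' the first query ORF covers the
                # upstream part of the reference protein, on '-' the downstream
                if q1.strand == "+" and not s1[0] <= s2[0]:
                    continue
                if q1.strand == "-" and not s2[0] <= s1[0]:
                    continue
                calls.append(
                    FusionCall(
                        reference_orf=ro,
                        query_orf_pair=(q1, q2),
                        coverage_each=(round(cov1, 3), round(cov2, 3)),
                        overlap_residues=overlap,
                    )
                )
    return calls


def flag_discordant_orfs(
    anchors: Sequence[Anchor],
    query_orfs: Sequence[OrfRecord],
    secondary_hits: Iterable[AlignmentHit] | None = None,
    membership: Sequence[MembershipRow] | None = None,
    min_read_overlap_bp: int = 100,
) -> list[DiscordantOrf]:
    """Flag query ORFs that look laterally acquired.

    A flag requires (a) no reference anchor, or a better best hit against the
    secondary ("other taxa") protein set than against the reference, AND (b)
    strand discordance with every neighbouring ORF on the contig.  With read
    membership supplied, each flag reports how many reads span both the
    flagged ORF and an anchored neighbour -- the read-level check that the
    arrangement is not an assembly artifact.
    """
    anchored = {a.query_orf.locus_tag: a for a in anchors}
    sec_best: dict[str, float] = {}
    if secondary_hits is None:
        logger.warning(
            "no secondary protein set supplied; discordance flags rest on "
            "orientation and missing anchors only"
        )
    else:
        for h in secondary_hits:
            cur = sec_best.get(h.query_id)
            if cur is None or h.e_value < cur:
                sec_best[h.query_id] = h.e_value

    reads_by_contig: dict[str, list[MembershipRow]] = {}
    if membership is not None:
        for row in membership:
            if not row.unassembled:
                reads_by_contig.setdefault(row.contig_id, []).append(row)

    by_contig: dict[str, list[OrfRecord]] = {}
    for o in query_orfs:
        by_contig.setdefault(o.contig_id, []).append(o)

    flags: list[DiscordantOrf] = []
    for contig in sorted(by_contig):
        orfs = sorted(by_contig[contig], key=lambda o: o.midpoint)
        for i, orf in enumerate(orfs):
            a = anchored.get(orf.locus_tag)
            if a is None:
                reason = "unanchored"
            elif (
                orf.locus_tag in sec_best
                and sec_best[orf.locus_tag] < a.e_value
            ):
                reason = "better-secondary-hit"
            else:
                continue
            neighbours = [o for o in (orfs[i - 1] if i > 0 else None, orfs[i + 1] if i + 1 < len(orfs) else None) if o]
            if not neighbours or any(n.strand == orf.strand for n in neighbours):
                continue
            n_span: int | None = None
            if membership is not None:
                anchored_neigh = [n for n in neighbours if n.locus_tag in anchored]
                n_span = 0
                for row in reads_by_contig.get(contig, []):
                    def ov(o2: OrfRecord) -> int:
                        return min(row.end, o2.end) - max(row.start, o2.start) + 1

                    if ov(orf) >= min_read_overlap_bp and any(
                        ov(n) >= min_read_overlap_bp for n in anchored_neigh
                    ):
                        n_span += 1
            flags.append(DiscordantOrf(orf=orf, reason=reason, n_spanning_reads=n_span))
    return flags
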