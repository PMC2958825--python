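"""Reference-lineage insertion detection and direct-repeat testing.

An element present in the reference but absent from the query (e.g. an
integrated prophage) shows up as a pair of anchors that are adjacent on the
query contig yet flank a large reference interval containing no anchored
query ORF.  The direct repeat expected from integrative insertion then
separates two histories: if the repeat flanks the element in the reference
but no copy exists at the query junction, the element was inserted into the
reference lineage after divergence; if a copy remains in the query, the
element was present in the common ancestor and deleted from the query.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

from .homology_search import ScoringScheme, smith_waterman
from .synteny_fusion import Anchor

logger = logging.getLogger(__name__)

__all__ = ["RepeatMatch", "InsertionCall", "find_insertions", "repeat_test"]

VERDICT_INSERTED = "inserted-after-divergence"
VERDICT_DELETED = "deleted-from-query"
VERDICT_INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class RepeatMatch:
    """One copy of a direct repeat, with its similarity to the partner copy.

    Coordinates are 1-based inclusive on the sequence that was searched.
    """

    sequence: str
    start: int
    end: int
    partner_start: int
    partner_end: int
    percent_identity: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class InsertionCall:
    """A candidate reference-only insertion with its flanking evidence."""

    element_start: int  # 0-based half-open on the reference
    element_end: int
    left_anchor: Anchor | None
    right_anchor: Anchor | None
    contig_id: str
    query_junction: int | None  # 0-based query/contig coordinate
    repeat_in_reference: RepeatMatch | None = None
    repeat_in_query: RepeatMatch | None = None
    verdict: str = VERDICT_INDETERMINATE


def find_insertions(
    anchors: Sequence[Anchor],
    element_annotations: Sequence[tuple[int, int]] | None = None,
    min_gap: int = 5000,
    max_junction_gap: int = 2000,
) -> list[InsertionCall]:
    """Locate reference intervals absent from the query.

    Candidates come from ``element_annotations`` (0-based half-open reference
    intervals, e.g. an annotated prophage span) or, when none are given, from
    de novo scanning for reference gaps >= ``min_gap`` between anchors that
    are adjacent on the query.  A call requires flanking anchors on the same
    contig whose query gap is <= ``max_junction_gap`` and no anchor inside
    the element interval; otherwise the verdict stays indeterminate.
    """
    calls: list[InsertionCall] = []
    by_contig: dict[str, list[Anchor]] = {}
    for a in anchors:
        by_contig.setdefault(a.query_orf.contig_id, []).append(a)
    for contig_anchors in by_contig.values():
        contig_anchors.sort(key=lambda a: a.query_mid)

    if element_annotations is not None:
        for es, ee in element_annotations:
            best: InsertionCall | None = None
            for contig, contig_anchors in sorted(by_contig.items()):
                lefts = [a for a in contig_anchors if a.reference_orf.end <= es]
                rights = [a for a in contig_anchors if a.reference_orf.start - 1 >= ee]
                inside = [
                    a
                    for a in contig_anchors
                    if a.reference_orf.start - 1 >= es and a.reference_orf.end <= ee
                ]
                if inside or not lefts or not rights:
                    continue
                left = max(lefts, key=lambda a: a.reference_orf.end)
                right = min(rights, key=lambda a: a.reference_orf.start)
                lo = min(left.query_orf.end, right.query_orf.end)
                hi = max(left.query_orf.start, right.query_orf.start)
                gap_q = max(hi - 1 - lo, 0)
                if gap_q > max_junction_gap:
                    continue
                junction = (lo + hi - 1) // 2
                best = InsertionCall(
                    element_start=es,
                    element_end=ee,
                    left_anchor=left,
                    right_anchor=right,
                    contig_id=contig,
                    query_junction=junction,
                )
                break
            if best is None:
                best = InsertionCall(
                    element_start=es,
                    element_end=ee,
                    left_anchor=None,
                    right_anchor=None,
                    contig_id="",
                    query_junction=None,
                    verdict=VERDICT_INDETERMINATE,
                )
            calls.append(best)
        return calls

    # de novo: reference gaps between query-adjacent anchors
    for contig, contig_anchors in sorted(by_contig.items()):
        for left, right in zip(contig_anchors, contig_anchors[1:]):
            if left.orient != right.orient:
                continue
            if left.orient == 1:
                ref_gap = (right.reference_orf.start - 1) - left.reference_orf.end
                es, ee = left.reference_orf.end, right.reference_orf.start - 1
            else:
                ref_gap = (left.reference_orf.start - 1) - right.reference_orf.end
                es, ee = right.reference_orf.end, left.reference_orf.start - 1
            query_gap = (right.query_orf.start - 1) - left.query_orf.end
            if ref_gap < min_gap or query_gap > max_junction_gap:
                continue
            junction = (left.query_orf.end + right.query_orf.start - 1) // 2
            calls.append(
                InsertionCall(
                    element_start=es,
                    element_end=ee,
                    left_anchor=left,
                    right_anchor=right,
                    contig_id=contig,
                    query_junction=junction,
                )
            )
    return calls


def _window(seq: str, lo: int, hi: int, label: str) -> tuple[str, int]:
    clipped_lo, clipped_hi = max(lo, 0), min(hi, len(seq))
    if (clipped_lo, clipped_hi) != (lo, hi):
        logger.warning("%s window [%d,%d) clipped to [%d,%d)", label, lo, hi, clipped_lo, clipped_hi)
    return seq[clipped_lo:clipped_hi], clipped_lo


# +1/-3 keeps single-mismatch extensions strictly unprofitable, so an exact
# planted repeat is recovered at its exact boundaries; 80-90%-identity repeats
# still score positively (E-values are not used here)
_REPEAT_SCHEME = ScoringScheme.nucleotide(match=1, mismatch=-3)


def repeat_test(
    call: InsertionCall,
    reference_seq: str,
    query_seq: str,
    window: int = 500,
    min_len: int = 20,
    min_identity: float = 80.0,
) -> InsertionCall:
    """Search for the element's direct repeat and assign the verdict.

    Local alignment of the reference windows around the two element
    boundaries finds the repeat pair; the query junction window is then
    searched for a copy.  Verdict: repeat in reference and absent from the
    query -> inserted after divergence; repeat also in the query -> deleted
    from the query; no reference repeat -> indeterminate.
    """
    es, ee = call.element_start, call.element_end
    left_win, left_off = _window(reference_seq, es - window, es + window, "left boundary")
    right_win, right_off = _window(reference_seq, ee - window, ee + window, "right boundary")
    aln = smith_waterman(left_win, right_win, _REPEAT_SCHEME)
    ref_repeat: RepeatMatch | None = None
    if (
        aln is not None
        and aln.alignment_length >= min_len
        and aln.percent_identity >= min_identity
    ):
        ref_repeat = RepeatMatch(
            sequence=left_win[aln.q_start : aln.q_end],
            start=left_off + aln.q_start + 1,
            end=left_off + aln.q_end,
            partner_start=right_off + aln.s_start + 1,
            partner_end=right_off + aln.s_end,
            percent_identity=round(aln.percent_identity, 2),
        )

    query_repeat: RepeatMatch | None = None
    if ref_repeat is not None and call.query_junction is not None:
        j = call.query_junction
        q_win, q_off = _window(query_seq, j - window, j + window, "query junction")
        q_aln = smith_waterman(ref_repeat.sequence, q_win, _REPEAT_SCHEME)
        if (
            q_aln is not None
            and q_aln.alignment_length >= min(min_len, ref_repeat.length)
            and q_aln.percent_identity >= min_identity
        ):
            query_repeat = RepeatMatch(
                sequence=q_win[q_aln.s_start : q_aln.s_end],
                start=q_off + q_aln.s_start + 1,
                end=q_off + q_aln.s_end,
                partner_start=ref_repeat.start,
                partner_end=ref_repeat.end,
                percent_identity=round(q_aln.percent_identity, 2),
            )

    if ref_repeat is None:
        verdict = VERDICT_INDETERMINATE
    elif query_repeat is None:
        verdict = VERDICT_INSERTED
    else:
        verdict = VERDICT_DELETED
    return replace(
        call,
        repeat_in_reference=ref_repeat,
        repeat_in_query=query_repeat,
        verdict=verdict,
    )
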