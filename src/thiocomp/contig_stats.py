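"""Per-contig characterization: length, fold coverage, GC, best-hit class.

Coverage comes from assembly read membership (total member-read bp divided by
contig length), not alignment depth.  The best-hit class tiers a contig by
the strongest translated-search hit from any reference protein, using strict
"better than" thresholds at 1e-100, 1e-50 and 1e-10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import AlignmentHit, MembershipRow, SeqRecord
from .seq_core import gc_content

__all__ = ["ContigStat", "contig_table", "size_filter_report", "EVALUE_TIERS"]

EVALUE_TIERS = (1e-100, 1e-50, 1e-10)


def evalue_class(e: float | None) -> str:
    if e is None:
        return "none"
    for t in EVALUE_TIERS:
        if e < t:
            return f"<{t:g}"
    return "none"


@dataclass
class ContigStat:
    contig_id: str
    length: int
    coverage: float | None  # None when no membership data was supplied
    gc: float
    best_evalue: float | None
    evalue_class: str
    n_member_reads: int


def contig_table(
    contigs: Sequence[SeqRecord],
    membership: Sequence[MembershipRow] | None,
    hits: Iterable[AlignmentHit],
) -> list[ContigStat]:
    """One row per contig.

    ``hits`` are reference-protein-vs-contig alignments (subject = contig).
    ``membership`` maps reads to contigs with their lengths; a missing table
    leaves coverage undefined.
    """
    best: dict[str, float] = {}
    for h in hits:
        cur = best.get(h.subject_id)
        if cur is None or h.e_value < cur:
            best[h.subject_id] = h.e_value

    member_bp: dict[str, int] = {}
    member_n: dict[str, int] = {}
    known = {c.id for c in contigs}
    if membership is not None:
        for row in membership:
            if row.unassembled:
                continue
            if row.read_bp <= 0:
                raise ValueError(f"member read {row.read_id} lacks a length")
            member_bp[row.contig_id] = member_bp.get(row.contig_id, 0) + row.read_bp
            member_n[row.contig_id] = member_n.get(row.contig_id, 0) + 1

    out: list[ContigStat] = []
    for c in contigs:
        e = best.get(c.id)
        cov = None
        if membership is not None:
            cov = member_bp.get(c.id, 0) / len(c.sequence)
        out.append(
            ContigStat(
                contig_id=c.id,
                length=len(c.sequence),
                coverage=cov,
                gc=gc_content(c.sequence).gc_fraction,
                best_evalue=e,
                evalue_class=evalue_class(e),
                n_member_reads=member_n.get(c.id, 0),
            )
        )
    return out


def size_filter_report(
    stats: Sequence[ContigStat], thresholds: Sequence[int] = (7000, 10000)
) -> dict[int, int]:
    """Count contigs strictly longer than each threshold."""
    return {t: sum(1 for s in stats if s.length > t) for t in thresholds}


def write_contig_table(stats: Sequence[ContigStat], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("contig_id\tlength\tcoverage\tgc\tbest_evalue\tevalue_class\tn_member_reads\n")
        for s in stats:
            cov = "-" if s.coverage is None else f"{s.coverage:.3f}"
            e = "-" if s.best_evalue is None else f"{s.best_evalue:.2e}"
            fh.write(
                f"{s.contig_id}\t{s.length}\t{cov}\t{s.gc:.4f}\t{e}\t{s.evalue_class}\t{s.n_member_reads}\n"
            )
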