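"""Mate-pair linkage of large contigs to transposase-bearing sequences.

Clone mate pairs physically connect the two loci their reads derive from, so
a large contig whose member read is paired with a transposase-containing
read is physically linked to a mobile element even when the element itself
failed to assemble.  The report derives the linked-read percentage and a
conservative genome-wide transposase density (one element per linked contig),
comparable against the reference genome's annotated transposase density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .contig_stats import ContigStat
from .io_formats import AlignmentHit, ClonePair, MembershipRow, mate_map

logger = logging.getLogger(__name__)

__all__ = [
    "ContigLinkage",
    "LinkageReport",
    "classify_transposase_sequences",
    "link_contigs",
    "density_estimate",
    "reference_density",
]


def classify_transposase_sequences(
    transposase_hits: Iterable[AlignmentHit],
    evalue_cutoff: float = 1e-10,
) -> set[str]:
    """Ids of sequences with a transposase hit at or below the E-value cutoff.

    ``transposase_hits`` are translated-search hits of a transposase protein
    set (query) against the reads or contigs (subjects).
    """
    return {
        h.subject_id for h in transposase_hits if h.e_value <= evalue_cutoff
    }


@dataclass
class ContigLinkage:
    contig_id: str
    length: int
    n_member_reads: int
    n_linked_reads: int
    encodes_transposase: bool

    @property
    def linked(self) -> bool:
        return self.n_linked_reads >= 1


@dataclass
class LinkageReport:
    large_contig_threshold: int
    contigs: list[ContigLinkage]

    @property
    def n_large_contigs(self) -> int:
        return len(self.contigs)

    @property
    def linked_contigs(self) -> list[ContigLinkage]:
        return [c for c in self.contigs if c.linked]

    @property
    def n_linked_contigs(self) -> int:
        return len(self.linked_contigs)

    @property
    def n_member_reads_total(self) -> int:
        return sum(c.n_member_reads for c in self.contigs)

    @property
    def n_linked_reads_total(self) -> int:
        return sum(c.n_linked_reads for c in self.contigs)

    @property
    def linked_read_percent(self) -> float:
        """Percentage of large-contig member reads paired with a transposase
        sequence, rounded to one decimal."""
        total = self.n_member_reads_total
        if total == 0:
            raise ValueError("linked read percent undefined: no member reads")
        return round(100.0 * self.n_linked_reads_total / total, 1)


def link_contigs(
    membership: Sequence[MembershipRow],
    clone_pairs: Sequence[ClonePair],
    flagged_ids: set[str],
    stats: Sequence[ContigStat],
    threshold: int = 10_000,
    count_same_contig_mates: bool = True,
) -> LinkageReport:
    """Connect large contigs to transposase sequences through clone pairs.

    A member read of a contig longer than ``threshold`` (strict) is linked
    when its mate is a flagged transposase sequence; the mate may be
    unassembled or sit in any contig (including the same one unless
    ``count_same_contig_mates`` is off).  A contig is linked when it has at
    least one linked member read; it may additionally itself encode a
    transposase (both facts are reported independently).
    """
    mates = mate_map(clone_pairs)
    contig_of: dict[str, str] = {
        r.read_id: r.contig_id for r in membership if not r.unassembled
    }
    by_contig: dict[str, list[str]] = {}
    for r in membership:
        if not r.unassembled:
            by_contig.setdefault(r.contig_id, []).append(r.read_id)

    known_reads = {r.read_id for r in membership}
    contigs: list[ContigLinkage] = []
    for s in sorted(stats, key=lambda s: s.contig_id):
        if s.length <= threshold:
            continue
        members = by_contig.get(s.contig_id, [])
        n_linked = 0
        for rid in members:
            mate = mates.get(rid)
            if mate is None:
                continue
            if mate not in known_reads:
                logger.warning("mate %s of %s missing from read universe", mate, rid)
                continue
            if not count_same_contig_mates and contig_of.get(mate) == s.contig_id:
                continue
            if mate in flagged_ids:
                n_linked += 1
        contigs.append(
            ContigLinkage(
                contig_id=s.contig_id,
                length=s.length,
                n_member_reads=len(members),
                n_linked_reads=n_linked,
                encodes_transposase=s.contig_id in flagged_ids,
            )
        )
    return LinkageReport(large_contig_threshold=threshold, contigs=contigs)


def density_estimate(
    report: LinkageReport, assumption: str = "one-per-linked-contig"
) -> tuple[int, float]:
    """Conservative transposase density from the linkage report.

    Under the one-element-per-linked-contig assumption the density is the
    summed length of the linked contigs divided by their count.  Returns
    (kb per transposase rounded to the nearest integer, unrounded kb).
    """
    if assumption != "one-per-linked-contig":
        raise ValueError(f"unknown assumption {assumption!r}")
    linked = report.linked_contigs
    if not linked:
        raise ValueError("density undefined: no linked contigs")
    kb = sum(c.length for c in linked) / 1000.0 / len(linked)
    return round(kb), kb


def reference_density(
    reference_length_bp: int, n_transposases: int
) -> tuple[int, float]:
    """Reference-genome spacing: kb of genome per annotated transposase."""
    if n_transposases <= 0:
        raise ValueError("reference transposase count must be positive")
    kb = reference_length_bp / 1000.0 / n_transposases
    return round(kb), kb


def write_linkage_report(report: LinkageReport, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(
            "contig_id\tlength\tn_member_reads\tn_linked_reads\tencodes_transposase\tlinked\n"
        )
        for c in report.contigs:
            fh.write(
                f"{c.contig_id}\t{c.length}\t{c.n_member_reads}\t{c.n_linked_reads}"
                f"\t{int(c.encodes_transposase)}\t{int(c.linked)}\n"
            )
        fh.write(
            f"# totals: large={report.n_large_contigs} linked={report.n_linked_contigs} "
            f"member_reads={report.n_member_reads_total} "
            f"linked_reads={report.n_linked_reads_total}\n"
        )
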