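"""Tiered homolog census: one row per reference protein.

Each reference protein is summarized by its best translated-search hit
against the assembled contigs and against the unassembled reads (singlets),
tiered by strict "better than" E-value thresholds (1e-100, 1e-50, 1e-10).
Tier counts are cumulative: a protein with a 1e-100 hit counts in all three
tiers, so the counts nest monotonically.  Proteins without any hit better
than the loosest tier form the missing-gene report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import AlignmentHit, SeqRecord

__all__ = [
    "CensusRow",
    "BestHit",
    "census",
    "tier_counts",
    "validate_tier_nesting",
    "missing_gene_report",
    "MissingGeneReport",
]

TIERS = (1e-100, 1e-50, 1e-10)


@dataclass(frozen=True)
class BestHit:
    subject_id: str
    e_value: float
    bit_score: float
    percent_identity: float


@dataclass
class CensusRow:
    reference_protein: str
    best_contig_hit: BestHit | None
    best_singlet_hit: BestHit | None
    annotation_is_hypothetical: bool = False

    @property
    def best_evalue_overall(self) -> float | None:
        es = [
            h.e_value
            for h in (self.best_contig_hit, self.best_singlet_hit)
            if h is not None
        ]
        return min(es) if es else None

    @property
    def tier(self) -> str:
        e = self.best_evalue_overall
        if e is not None:
            for t in TIERS:
                if e < t:
                    return f"{t:g}"
        return "none"


def _best_by_query(hits: Iterable[AlignmentHit]) -> dict[str, BestHit]:
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (h.e_value, -h.bit_score) < (cur.e_value, -cur.bit_score):
            best[h.query_id] = h
    return {
        q: BestHit(h.subject_id, h.e_value, h.bit_score, h.percent_identity)
        for q, h in best.items()
    }


def census(
    reference_proteins: Sequence[SeqRecord],
    hits_vs_contigs: Iterable[AlignmentHit],
    hits_vs_singlets: Iterable[AlignmentHit],
    annotations: dict[str, str] | None = None,
) -> list[CensusRow]:
    """One row per reference protein with its best contig and singlet hits."""
    bc = _best_by_query(hits_vs_contigs)
    bs = _best_by_query(hits_vs_singlets)
    annotations = annotations or {}
    rows = []
    for prot in reference_proteins:
        product = annotations.get(prot.id, prot.description)
        rows.append(
            CensusRow(
                reference_protein=prot.id,
                best_contig_hit=bc.get(prot.id),
                best_singlet_hit=bs.get(prot.id),
                annotation_is_hypothetical="hypothetical" in product.lower(),
            )
        )
    return rows


def tier_counts(rows: Sequence[CensusRow]) -> dict[str, int]:
    """Cumulative tier tallies: every stricter tier is included in the looser
    ones, so counts nest (n(1e-100) <= n(1e-50) <= n(1e-10))."""
    counts = {f"{t:g}": 0 for t in TIERS}
    none_count = 0
    for row in rows:
        e = row.best_evalue_overall
        hit_any = False
        for t in TIERS:
            if e is not None and e < t:
                counts[f"{t:g}"] += 1
                hit_any = True
        if not hit_any:
            none_count += 1
    counts["none"] = none_count
    counts["total"] = len(rows)
    return counts


def validate_tier_nesting(counts: dict[str, int]) -> None:
    """Monotone nesting: n(1e-100) <= n(1e-50) <= n(1e-10) <= total, and the
    tier-none count is exactly total - n(1e-10)."""
    seq = [counts[f"{t:g}"] for t in TIERS] + [counts["total"]]
    if any(a > b for a, b in zip(seq, seq[1:])):
        raise ValueError(f"tier counts are not nested: {counts}")
    if counts["none"] != counts["total"] - counts[f"{TIERS[-1]:g}"]:
        raise ValueError(f"tier-none count inconsistent: {counts}")


@dataclass
class MissingGeneReport:
    """Reference proteins with no hit better than the loosest tier."""

    missing: list[str]
    n_hypothetical: int
    by_keyword: dict[str, list[str]]

    @property
    def n_missing(self) -> int:
        return len(self.missing)


def missing_gene_report(
    rows: Sequence[CensusRow], annotations: dict[str, str]
) -> MissingGeneReport:
    """Summarize tier-none proteins: hypothetical count plus a grouping of
    the annotated remainder by product keyword."""
    missing = [r.reference_protein for r in rows if r.tier == "none"]
    n_hypo = 0
    by_keyword: dict[str, list[str]] = {}
    for locus in missing:
        product = annotations.get(locus, "")
        if "hypothetical" in product.lower():
            n_hypo += 1
        else:
            key = product if product else "(unannotated)"
            by_keyword.setdefault(key, []).append(locus)
    return MissingGeneReport(missing=missing, n_hypothetical=n_hypo, by_keyword=by_keyword)


def write_census(rows: Sequence[CensusRow], path) -> None:
    def fmt(h: BestHit | None) -> str:
        if h is None:
            return "-\t-\t-\t-"
        return f"{h.subject_id}\t{h.e_value:.2e}\t{h.bit_score:.1f}\t{h.percent_identity:.1f}"

    with open(path, "w", newline="\n") as fh:
        fh.write(
            "reference_protein\tcontig\tcontig_e\tcontig_bits\tcontig_pid"
            "\tsinglet\tsinglet_e\tsinglet_bits\tsinglet_pid\ttier\thypothetical\n"
        )
        for r in rows:
            fh.write(
                f"{r.reference_protein}\t{fmt(r.best_contig_hit)}\t{fmt(r.best_singlet_hit)}"
                f"\t{r.tier}\t{int(r.annotation_is_hypothetical)}\n"
            )
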