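"""Fragment-recruitment profiling of a read set against a reference genome.

Each read is represented by its single best alignment (lowest E-value, ties
broken by bit score); alignments longer than a strict minimum (default
>500 bp) are binned by percent identity, and each bin's coverage is the total
aligned base pairs in the bin divided by the reference length.  The resulting
identity-vs-coverage profile summarizes how similar the dominant sequenced
population is to the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import AlignmentHit

__all__ = ["RecruitmentProfile", "recruit", "recruited_fraction", "best_hit_per_read"]


@dataclass
class RecruitmentProfile:
    """Per-identity-bin aligned-bp coverage of a reference genome."""

    bin_edges: np.ndarray  # length n_bins + 1, percent identity
    aligned_bp: np.ndarray  # per bin
    reference_length: int
    min_alignment_length: int
    n_reads_recruited: int
    n_reads_total: int
    n_reads_below_range: int = 0

    @property
    def coverage(self) -> np.ndarray:
        return self.aligned_bp / self.reference_length

    @property
    def modal_bin(self) -> tuple[float, float]:
        """(low, high) edges of the bin with the most aligned bp."""
        i = int(np.argmax(self.aligned_bp))
        return (float(self.bin_edges[i]), float(self.bin_edges[i + 1]))

    def to_rows(self) -> list[tuple[float, float, int, float]]:
        return [
            (
                float(self.bin_edges[i]),
                float(self.bin_edges[i + 1]),
                int(self.aligned_bp[i]),
                float(self.coverage[i]),
            )
            for i in range(len(self.aligned_bp))
        ]


def best_hit_per_read(hits: Iterable[AlignmentHit]) -> dict[str, AlignmentHit]:
    """Best hit per query: lowest E-value, tie broken by highest bit score,
    then by subject and query start for stability."""
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        key = (h.e_value, -h.bit_score, h.s_start, h.q_start)
        cur_key = (cur.e_value, -cur.bit_score, cur.s_start, cur.q_start)
        if key < cur_key:
            best[h.query_id] = h
    return best


def recruit(
    hits: Sequence[AlignmentHit],
    reference_length: int,
    min_alignment_length: int = 500,
    n_reads_total: int | None = None,
    bin_range: tuple[float, float] = (50.0, 100.0),
    bin_width: float = 1.0,
    read_ids: set[str] | None = None,
) -> RecruitmentProfile:
    """Build the recruitment profile from read-vs-reference hits.

    Only alignments strictly longer than ``min_alignment_length`` recruit a
    read.  A read falls in bin ``[k, k+1)`` by its best hit's percent
    identity; 100% goes in the top bin.  When ``read_ids`` is supplied, hits
    naming unknown reads raise a consistency error.
    """
    if reference_length <= 0:
        raise ValueError("reference_length must be positive")
    if read_ids is not None:
        unknown = {h.query_id for h in hits} - read_ids
        if unknown:
            raise ValueError(
                f"hits reference {len(unknown)} read ids absent from the read "
                f"manifest, e.g. {sorted(unknown)[:3]}"
            )
    lo, hi = bin_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    aligned = np.zeros(len(edges) - 1, dtype=np.int64)
    best = best_hit_per_read(hits)
    recruited = 0
    below = 0
    for h in best.values():
        if h.alignment_length <= min_alignment_length:
            continue
        pid = h.percent_identity
        if pid < lo:
            below += 1
            continue
        idx = min(int((pid - lo) // bin_width), len(aligned) - 1)
        aligned[idx] += h.alignment_length
        recruited += 1
    total = n_reads_total if n_reads_total is not None else len(best)
    return RecruitmentProfile(
        bin_edges=edges,
        aligned_bp=aligned,
        reference_length=reference_length,
        min_alignment_length=min_alignment_length,
        n_reads_recruited=recruited,
        n_reads_total=total,
        n_reads_below_range=below,
    )


def recruited_fraction(profile: RecruitmentProfile) -> float:
    """Percentage of all reads recruited (best alignment passed the length
    filter)."""
    if profile.n_reads_total == 0:
        raise ValueError("recruited fraction undefined: no reads in the manifest")
    return 100.0 * profile.n_reads_recruited / profile.n_reads_total


def write_profile(profile: RecruitmentProfile, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("bin_low\tbin_high\taligned_bp\tcoverage\n")
        for lo, hi, bp, cov in profile.to_rows():
            fh.write(f"{lo:g}\t{hi:g}\t{bp}\t{cov:.6g}\n")
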