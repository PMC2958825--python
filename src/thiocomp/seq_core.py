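"""Elementary sequence computations shared by all pipeline stages.

GC content, reverse complement, six-frame translation, and a deliberately
simple maximal-ORF finder (ATG-to-stop on both strands).  The ORF finder uses
no coding-statistics model: gene calls only anchor downstream comparisons, so
a trained gene finder would add a dependency without changing any comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .io_formats import OrfRecord

__all__ = [
    "GcResult",
    "gc_content",
    "reverse_complement",
    "translate",
    "find_orfs",
    "STOP_CODONS",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class GcResult:
    """GC fraction over unambiguous bases; ambiguity codes are excluded from
    the denominator.  ``defined`` is False when no unambiguous base exists."""

    gc_fraction: float
    counted_bases: int

    @property
    def defined(self) -> bool:
        return self.counted_bases > 0


def gc_content(seq: str) -> GcResult:
    """GC fraction (#G+#C)/(#A+#C+#G+#T); N etc. excluded from the count."""
    seq = seq.upper()
    if set(seq) - set("ACGTURYSWKMBDHVN"):
        raise ValueError("gc_content requires a nucleotide sequence")
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T") + seq.count("U")
    counted = gc + at
    if counted == 0:
        return GcResult(gc_fraction=float("nan"), counted_bases=0)
    return GcResult(gc_fraction=gc / counted, counted_bases=counted)


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def translate(seq: str, frame: int = 1) -> str:
    """Translate one frame with the standard genetic code.

    ``frame`` is 1..3 on the forward strand, -1..-3 on the reverse complement.
    ATG is the only codon translated as M (no alternative-start special case);
    stops are '*'; a trailing partial codon is dropped.
    """
    if frame not in (-3, -2, -1, 1, 2, 3):
        raise ValueError(f"frame must be in -3..-1, 1..3, got {frame}")
    seq = seq.upper()
    if frame < 0:
        seq = reverse_complement(seq)
    offset = abs(frame) - 1
    coding = seq[offset : offset + 3 * ((len(seq) - offset) // 3)]
    if not coding:
        return ""
    return str(Seq(coding).translate())


def _scan_strand(seq: str, min_length_bp: int) -> list[tuple[int, int]]:
    """Maximal ATG-to-stop spans on the forward strand of ``seq``.

    Returns 0-based half-open (start, end) including the stop codon.  Maximal
    means the first ATG after the previous in-frame stop, extended to the next
    in-frame stop.
    """
    n = len(seq)
    spans: list[tuple[int, int]] = []
    for offset in range(3):
        start: int | None = None
        for pos in range(offset, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if start is not None and (pos + 3 - start) >= min_length_bp:
                    spans.append((start, pos + 3))
                start = None
            elif start is None and codon == "ATG":
                start = pos
    return spans


def find_orfs(
    seq: str,
    min_length_bp: int = 300,
    contig_id: str = "contig",
    locus_prefix: str = "ORF",
) -> list[OrfRecord]:
    """Find maximal ATG-to-stop ORFs >= ``min_length_bp`` on both strands.

    Overlapping calls on the same strand are resolved by keeping the longer
    (tie: leftmost start).  Output coordinates are 1-based inclusive and
    include the stop codon; translations omit the stop.
    """
    seq = seq.upper()
    n = len(seq)
    candidates: list[tuple[int, int, str]] = []  # (start0, end0, strand)
    for s0, e0 in _scan_strand(seq, min_length_bp):
        candidates.append((s0, e0, "+"))
    rc = reverse_complement(seq)
    for s0, e0 in _scan_strand(rc, min_length_bp):
        # map back to forward coordinates
        candidates.append((n - e0, n - s0, "-"))

    # resolve same-strand overlaps: keep longer, tie -> leftmost start
    kept: list[tuple[int, int, str]] = []
    for strand in "+-":
        strand_c = [c for c in candidates if c[2] == strand]
        strand_c.sort(key=lambda c: (-(c[1] - c[0]), c[0]))
        chosen: list[tuple[int, int, str]] = []
        for c in strand_c:
            if all(c[1] <= k[0] or c[0] >= k[1] for k in chosen):
                chosen.append(c)
        kept.extend(chosen)

    kept.sort(key=lambda c: (c[0], c[1]))
    orfs: list[OrfRecord] = []
    for i, (s0, e0, strand) in enumerate(kept, start=1):
        subseq = seq[s0:e0]
        if strand == "-":
            subseq = reverse_complement(subseq)
        orfs.append(
            OrfRecord(
                contig_id=contig_id,
                locus_tag=f"{locus_prefix}_{i:04d}",
                start=s0 + 1,
                end=e0,
                strand=strand,
                translation=str(Seq(subseq).translate())[:-1],
            )
        )
    return orfs


def extract_orf_sequence(genome: str, orf: OrfRecord) -> str:
    """Coding-strand nucleotide sequence of an ORF (stop codon included)."""
    sub = genome[orf.start - 1 : orf.end]
    return reverse_complement(sub) if orf.strand == "-" else sub
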