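"""Readers and writers for every file the pipeline touches.

All coordinates in files are 1-based inclusive (GenBank convention); internal
arithmetic elsewhere in the package is 0-based half-open.  Alignment hit tables
use the 12-column tab-separated dialect standard for BLAST ``-outfmt 6`` (an
optional 13th column carries the translation frame), so externally produced hit
tables drop in unchanged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SeqRecord",
    "ClonePair",
    "AlignmentHit",
    "OrfRecord",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_hits_tabular",
    "write_hits_tabular",
    "pair_reads",
    "read_orf_table",
    "write_orf_table",
    "read_annotations",
    "write_annotations",
    "read_membership",
    "write_membership",
]

_NUC_ALPHABET = set("ACGTURYSWKMBDHVN")
_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBJZXUO*")

#: Mate suffix dialects: forward suffix -> reverse suffix.
DEFAULT_SUFFIX_TABLE = {".b1": ".g1", ".x1": ".y1"}


class FormatError(ValueError):
    """Malformed input file; message carries file name and line number."""


@dataclass(frozen=True)
class SeqRecord:
    """One sequence with its identifier and free-text description."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ClonePair:
    """The two Sanger reads sequenced from opposite ends of one clone insert."""

    stem: str
    forward_read_id: str
    reverse_read_id: str


@dataclass
class AlignmentHit:
    """One local alignment in the 12/13-column tabular dialect.

    ``s_start > s_end`` encodes a minus-strand subject span.  ``frame`` is only
    present for translated searches (-3..-1, 1..3 relative to the subject).
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_openings: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float
    frame: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError(f"percent identity out of range: {self.percent_identity}")
        if self.alignment_length < 1:
            raise ValueError("alignment length must be >= 1")
        if self.e_value < 0:
            raise ValueError("E-value must be non-negative")

    @property
    def subject_on_minus_strand(self) -> bool:
        return self.s_start > self.s_end

    def subject_span(self) -> tuple[int, int]:
        """Subject span as (low, high), 1-based inclusive, strand-agnostic."""
        return (min(self.s_start, self.s_end), max(self.s_start, self.s_end))


@dataclass(frozen=True)
class OrfRecord:
    """A called open reading frame, 1-based inclusive, stop codon included."""

    contig_id: str
    locus_tag: str
    start: int
    end: int
    strand: str
    translation: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -: {self.strand!r}")
        if (self.end - self.start + 1) % 3 != 0:
            raise ValueError(
                f"ORF span {self.locus_tag} not divisible by 3: {self.start}-{self.end}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _validate_alphabet(seq: str, record_id: str, path: str) -> None:
    letters = set(seq)
    if letters <= _NUC_ALPHABET or letters <= _AA_ALPHABET:
        return
    bad = "".join(sorted(letters - (_NUC_ALPHABET | _AA_ALPHABET)))
    raise FormatError(f"{path}: record {record_id!r} has illegal characters {bad!r}")


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file; sequences are uppercased and alphabet-validated."""
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            _validate_alphabet(seq, rec.id, str(path))
            if rec.id in seen:
                raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            desc = rec.description[len(rec.id) :].strip() if rec.description else ""
            records.append(SeqRecord(id=rec.id, sequence=seq, description=desc))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, wrap: int = 60) -> None:
    """Write FASTA with fixed line wrapping; deterministic byte stream."""
    with open(path, "w", newline="\n") as handle:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            handle.write(header + "\n")
            seq = rec.sequence
            for i in range(0, len(seq), wrap):
                handle.write(seq[i : i + wrap] + "\n")


def to_biopython(rec: SeqRecord) -> _BioSeqRecord:
    return _BioSeqRecord(Seq(rec.sequence), id=rec.id, description=rec.description)


# ---------------------------------------------------------------------------
# Tabular alignment hits
# ---------------------------------------------------------------------------

def _parse_evalue(token: str) -> float:
    # BLAST tabular output writes very small expectations as a bare "e-100".
    if token.startswith(("e-", "e+", "E-", "E+")):
        token = "1" + token
    return float(token)


def _format_evalue(e: float) -> str:
    if e == 0.0:
        return "0.0"
    if e >= 0.001:
        return f"{e:.2g}"
    # two significant digits, exponent form
    return f"{e:.1e}"


def read_hits_tabular(path: str | Path) -> list[AlignmentHit]:
    """Parse a 12/13-column tabular hit file (13th column = frame)."""
    path = Path(path)
    hits: list[AlignmentHit] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) not in (12, 13):
                raise FormatError(
                    f"{path}:{lineno}: expected 12 or 13 tab-separated columns, "
                    f"got {len(cols)}"
                )
            try:
                hit = AlignmentHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    percent_identity=float(cols[2]),
                    alignment_length=int(cols[3]),
                    mismatches=int(cols[4]),
                    gap_openings=int(cols[5]),
                    q_start=int(cols[6]),
                    q_end=int(cols[7]),
                    s_start=int(cols[8]),
                    s_end=int(cols[9]),
                    e_value=_parse_evalue(cols[10]),
                    bit_score=float(cols[11]),
                    frame=int(cols[12]) if len(cols) == 13 else None,
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_hits_tabular(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    with open(path, "w", newline="\n") as handle:
        for h in hits:
            cols = [
                h.query_id,
                h.subject_id,
                f"{h.percent_identity:.2f}",
                str(h.alignment_length),
                str(h.mismatches),
                str(h.gap_openings),
                str(h.q_start),
                str(h.q_end),
                str(h.s_start),
                str(h.s_end),
                _format_evalue(h.e_value),
                f"{h.bit_score:.1f}",
            ]
            if h.frame is not None:
                cols.append(str(h.frame))
            handle.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Clone-pair naming
# ---------------------------------------------------------------------------

def pair_reads(
    read_ids: Iterable[str],
    suffix_table: dict[str, str] | None = None,
) -> tuple[list[ClonePair], list[str]]:
    """Group read ids into clone mate pairs by their naming suffix.

    Reads named ``STEM.b1`` / ``STEM.g1`` (or ``STEM.x1`` / ``STEM.y1``) are the
    two ends of one cloned insert.  Ids with unknown suffixes, or stems whose
    mate is missing, are returned unpaired.  Three or more ids sharing one stem
    is an ambiguity error.
    """
    if suffix_table is None:
        suffix_table = DEFAULT_SUFFIX_TABLE
    known = set(suffix_table) | set(suffix_table.values())
    by_stem: dict[str, list[str]] = {}
    unpaired: list[str] = []
    for rid in read_ids:
        for suf in known:
            if rid.endswith(suf):
                by_stem.setdefault(rid[: -len(suf)], []).append(rid)
                break
        else:
            unpaired.append(rid)

    pairs: list[ClonePair] = []
    for stem in sorted(by_stem):
        ids = by_stem[stem]
        if len(ids) > 2:
            raise FormatError(
                f"ambiguous clone naming: stem {stem!r} has {len(ids)} reads: "
                + ", ".join(sorted(ids))
            )
        if len(ids) == 1:
            unpaired.append(ids[0])
            continue
        a, b = sorted(ids)
        matched = False
        for fwd_suf, rev_suf in suffix_table.items():
            cand = {stem + fwd_suf, stem + rev_suf}
            if {a, b} == cand:
                pairs.append(
                    ClonePair(
                        stem=stem,
                        forward_read_id=stem + fwd_suf,
                        reverse_read_id=stem + rev_suf,
                    )
                )
                matched = True
                break
        if not matched:
            # e.g. STEM.b1 together with STEM.y1: suffix families must agree
            unpaired.extend([a, b])
    return pairs, unpaired


def mate_map(pairs: Iterable[ClonePair]) -> dict[str, str]:
    """Read id -> mate read id, both directions."""
    mates: dict[str, str] = {}
    for p in pairs:
        mates[p.forward_read_id] = p.reverse_read_id
        mates[p.reverse_read_id] = p.forward_read_id
    return mates


# ---------------------------------------------------------------------------
# GFF-like ORF tables
# ---------------------------------------------------------------------------

_LOCUS_RE = re.compile(r"locus_tag=([^;]+)")


def write_orf_table(
    orfs: Iterable[OrfRecord],
    path: str | Path,
    source: str = "thiocomp",
    products: dict[str, str] | None = None,
) -> None:
    """Write ORFs as GFF-like TSV: seqid, source, type, start, end, score,
    strand, frame, attributes (``locus_tag=``; optionally ``product=``)."""
    with open(path, "w", newline="\n") as handle:
        for orf in orfs:
            attrs = f"locus_tag={orf.locus_tag}"
            if products and orf.locus_tag in products:
                attrs += f";product={products[orf.locus_tag]}"
            handle.write(
                "\t".join(
                    [
                        orf.contig_id,
                        source,
                        "CDS",
                        str(orf.start),
                        str(orf.end),
                        ".",
                        orf.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_orf_table(path: str | Path) -> list[OrfRecord]:
    """Read a GFF-like ORF TSV.  Only the ``locus_tag=`` attribute is parsed."""
    path = Path(path)
    orfs: list[OrfRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            m = _LOCUS_RE.search(cols[8])
            if not m:
                raise FormatError(f"{path}:{lineno}: attributes lack locus_tag=")
            try:
                orfs.append(
                    OrfRecord(
                        contig_id=cols[0],
                        locus_tag=m.group(1),
                        start=int(cols[3]),
                        end=int(cols[4]),
                        strand=cols[6],
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return orfs


# ---------------------------------------------------------------------------
# Annotation (locus -> product) tables
# ---------------------------------------------------------------------------

def write_annotations(products: dict[str, str], path: str | Path) -> None:
    with open(path, "w", newline="\n") as handle:
        handle.write("locus_tag\tproduct\n")
        for locus in products:
            handle.write(f"{locus}\t{products[locus]}\n")


def read_annotations(path: str | Path) -> dict[str, str]:
    path = Path(path)
    products: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("locus_tag\t"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
            products[cols[0]] = cols[1]
    return products


# ---------------------------------------------------------------------------
# Read-membership tables (read -> contig, with contig-local span)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MembershipRow:
    """Assignment of one read to one contig (or unassembled).

    ``start``/``end`` are 1-based inclusive contig-local coordinates of the
    read's source span, clipped to the contig; both 0 for unassembled reads.
    """

    read_id: str
    contig_id: str  # "" for unassembled (singlet) reads
    read_bp: int
    start: int = 0
    end: int = 0

    @property
    def unassembled(self) -> bool:
        return self.contig_id == ""


def write_membership(rows: Iterable[MembershipRow], path: str | Path) -> None:
    with open(path, "w", newline="\n") as handle:
        handle.write("read_id\tcontig_id\tread_bp\tstart\tend\n")
        for r in rows:
            cid = r.contig_id if r.contig_id else "-"
            handle.write(f"{r.read_id}\t{cid}\t{r.read_bp}\t{r.start}\t{r.end}\n")


def read_membership(path: str | Path) -> list[MembershipRow]:
    path = Path(path)
    rows: list[MembershipRow] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("read_id\t"):
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns, got {len(cols)}")
            rows.append(
                MembershipRow(
                    read_id=cols[0],
                    contig_id="" if cols[1] == "-" else cols[1],
                    read_bp=int(cols[2]),
                    start=int(cols[3]),
                    end=int(cols[4]),
                )
            )
    return rows
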