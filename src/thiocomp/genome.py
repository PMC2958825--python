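"""The annotated-genome container: a sequence plus ordered ORF records.

This is the reference frame for every comparison in the pipeline, standing in
for a finished genome with its gene annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .io_formats import OrfRecord, SeqRecord, write_annotations, write_fasta, write_orf_table
from .seq_core import extract_orf_sequence

__all__ = ["AnnotatedGenome"]


@dataclass
class AnnotatedGenome:
    """A genome sequence with its ordered ORF annotation.

    ``prophage`` (optional) is the 0-based half-open span of an annotated
    inserted element, including both copies of its flanking direct repeat,
    plus the repeat length: ``(start, end, repeat_length)``.
    """

    record: SeqRecord
    orfs: list[OrfRecord] = field(default_factory=list)
    products: dict[str, str] = field(default_factory=dict)
    prophage: tuple[int, int, int] | None = None

    @property
    def sequence(self) -> str:
        return self.record.sequence

    def __len__(self) -> int:
        return len(self.record.sequence)

    def orf_by_tag(self, locus_tag: str) -> OrfRecord:
        for orf in self.orfs:
            if orf.locus_tag == locus_tag:
                return orf
        raise KeyError(locus_tag)

    def orf_nucleotides(self, orf: OrfRecord) -> str:
        return extract_orf_sequence(self.record.sequence, orf)

    def protein_records(self) -> list[SeqRecord]:
        """Translations of all ORFs as FASTA-ready records (no stop symbol)."""
        out = []
        for orf in self.orfs:
            out.append(
                SeqRecord(
                    id=orf.locus_tag,
                    sequence=orf.translation,
                    description=self.products.get(orf.locus_tag, ""),
                )
            )
        return out

    def write(self, outdir: str | Path, prefix: str) -> None:
        """Write <prefix>.fasta, <prefix>.orfs.tsv, <prefix>.annotations.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta([self.record], outdir / f"{prefix}.fasta")
        write_orf_table(
            self.orfs, outdir / f"{prefix}.orfs.tsv", products=self.products
        )
        write_annotations(self.products, outdir / f"{prefix}.annotations.tsv")
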