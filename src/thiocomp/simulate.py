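"""Synthetic genome evolution and shotgun-read simulation with planted truth.

The simulator emulates the study design the rest of the package analyses: a
finished reference genome (43% GC, annotated ORFs, a prophage flanked by a
direct repeat) and a diverged sister lineage sampled as a metagenome
population (~70% nucleotide identity, GC drifted to 38%, a large
translocation, gene fusions, multi-copy transposases, reverse-orientation
foreign ORFs).  Sanger-style paired-end reads are drawn from the diverged
lineage and grouped into contig fixtures; every planted event is recorded in
a machine-readable truth ledger so downstream detectors can be scored
exactly.

Assembly is simulated, not performed: contigs are windows of the query
genome, which makes read membership and event coordinates exact.

Substitutions are codon-aware: synonymous third positions are mutated at a
higher rate than nonsynonymous positions (ratio configurable, default 3x), so
~30% nucleotide divergence coexists with per-protein amino-acid identities of
roughly 60-95%, as observed between moderately diverged bacterial lineages.
Substituted bases are drawn from a composition solved so the query genome
lands on its GC target; a final divergence top-up and a divergence-preserving
GC swap pass pin both quantities to their targets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .genome import AnnotatedGenome
from .io_formats import MembershipRow, OrfRecord, SeqRecord
from .seq_core import STOP_CODONS, gc_content, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "ProphageSpec",
    "TranslocationSpec",
    "TruthLedger",
    "LedgerRecord",
    "PlacementError",
    "build_reference",
    "evolve_query",
    "simulate_reads",
    "make_contig_fixtures",
    "simulate_all",
    "SimResult",
]

_BASES = "ACGT"

# standard genetic code, codon -> amino acid ('*' for stops)
GENETIC_CODE: dict[str, str] = {
    "".join(c): str(Seq("".join(c)).translate()) for c in itertools.product(_BASES, repeat=3)
}
# synonymous third-position alternatives per codon
_SYN3: dict[str, str] = {
    codon: "".join(
        b
        for b in _BASES
        if b != codon[2] and GENETIC_CODE[codon[:2] + b] == GENETIC_CODE[codon]
    )
    for codon in GENETIC_CODE
    if GENETIC_CODE[codon] != "*"
}


class PlacementError(RuntimeError):
    """Requested features cannot be placed; message names the limiting parameter."""


@dataclass(frozen=True)
class ProphageSpec:
    """An element inserted into the reference lineage after divergence.

    The insertion duplicates a short target sequence, leaving one copy of the
    direct repeat at each end.  ``length_bp`` is the phage interior, excluding
    the two repeat copies; the full inserted span is
    ``length_bp + 2 * repeat_length``.
    """

    length_bp: int = 6000
    insertion_site: int = 110_000
    repeat_length: int = 26
    n_orfs: int = 5

    def __post_init__(self) -> None:
        if self.repeat_length < 15:
            raise ValueError("prophage repeat_length must be >= 15")
        if self.length_bp < 600:
            raise ValueError("prophage length_bp must be >= 600")


@dataclass(frozen=True)
class TranslocationSpec:
    """Two reference regions joined adjacently in the query lineage.

    In the reference, ``region_a`` and ``region_b`` are separated by
    ``gap_bp``; in the query, region B is excised and re-inserted directly
    after region A.  Coordinates are 0-based half-open on the reference.
    """

    region_a: tuple[int, int] = (10_000, 25_000)
    region_b: tuple[int, int] = (75_000, 90_000)

    def __post_init__(self) -> None:
        a, b = self.region_a, self.region_b
        if not (a[0] < a[1] <= b[0] < b[1]):
            raise ValueError("translocation regions must be ordered and disjoint")

    @property
    def gap_bp(self) -> int:
        return self.region_b[0] - self.region_a[1]


@dataclass(frozen=True)
class SimConfig:
    """All tunables of one simulated study, including the RNG seed."""

    seed: int = 0
    genome_length: int = 150_000
    n_orfs: int = 80
    gc_reference: float = 0.43
    gc_query: float = 0.38
    nt_divergence: float = 0.30
    syn_nonsyn_ratio: float = 3.0
    translocation: TranslocationSpec | None = TranslocationSpec()
    n_fusions: int = 2
    prophage: ProphageSpec | None = ProphageSpec()
    n_transposase_copies: int = 10
    n_foreign_orfs: int = 3
    read_length_mean: float = 755.0
    read_length_sd: float = 50.0
    insert_size_mean: float = 3000.0
    insert_size_sd: float = 300.0
    coverage_target: float = 6.0

    def __post_init__(self) -> None:
        for name in ("gc_reference", "gc_query"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if not (0.0 <= self.nt_divergence < 1.0):
            raise ValueError("nt_divergence must be in [0,1)")
        if self.coverage_target <= 0:
            raise ValueError("coverage_target must be positive")
        if self.translocation and self.prophage:
            b = self.translocation.region_b
            ps = self.prophage.insertion_site
            if self.translocation.region_a[0] <= ps < b[1]:
                raise ValueError(
                    "prophage insertion_site must lie outside the translocation regions"
                )


# ---------------------------------------------------------------------------
# Truth ledger
# ---------------------------------------------------------------------------

LEDGER_KINDS = (
    "substitution-rate",
    "translocation",
    "fusion",
    "prophage",
    "transposase-copy",
    "foreign-orf",
    "orf-identity",
)


@dataclass(frozen=True)
class LedgerRecord:
    """One planted event; coordinates are 0-based half-open.

    ``identity`` carries the event's quantitative ground truth: the overall
    substitution rate for ``substitution-rate`` rows, the per-ORF amino-acid
    identity for ``orf-identity`` rows, NaN otherwise.
    """

    kind: str
    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    strand: str
    identity: float
    note: str


@dataclass
class TruthLedger:
    seed: int
    records: list[LedgerRecord] = field(default_factory=list)

    def of_kind(self, kind: str) -> list[LedgerRecord]:
        return [r for r in self.records if r.kind == kind]

    def one(self, kind: str) -> LedgerRecord:
        recs = self.of_kind(kind)
        if len(recs) != 1:
            raise KeyError(f"expected exactly one {kind!r} record, found {len(recs)}")
        return recs[0]

    def write(self, path: str | Path) -> None:
        with open(path, "w", newline="\n") as fh:
            fh.write("# truth ledger; coordinates 0-based half-open\n")
            fh.write(f"# seed={self.seed}\n")
            fh.write("kind\tref_start\tref_end\tquery_start\tquery_end\tstrand\tidentity\tnote\n")
            for r in self.records:
                fh.write(
                    f"{r.kind}\t{r.ref_start}\t{r.ref_end}\t{r.query_start}\t"
                    f"{r.query_end}\t{r.strand}\t{r.identity!r}\t{r.note}\n"
                )

    @classmethod
    def read(cls, path: str | Path) -> "TruthLedger":
        seed = 0
        records: list[LedgerRecord] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# seed="):
                    seed = int(line.split("=", 1)[1])
                    continue
                if not line or line.startswith("#") or line.startswith("kind\t"):
                    continue
                k, rs, re_, qs, qe, st, ident, note = line.split("\t")
                records.append(
                    LedgerRecord(k, int(rs), int(re_), int(qs), int(qe), st, float(ident), note)
                )
        return cls(seed=seed, records=records)


# ---------------------------------------------------------------------------
# Random sequence helpers
# ---------------------------------------------------------------------------

def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    idx = rng.choice(4, size=n, p=_base_probs(gc))
    return "".join(_BASES[i] for i in idx)


def _random_codons(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """n_codons sense (non-stop) codons drawn base-wise at the GC target."""
    out: list[str] = []
    p = _base_probs(gc)
    while len(out) < n_codons:
        draw = rng.choice(4, size=3 * (n_codons - len(out)), p=p)
        for i in range(0, len(draw), 3):
            codon = _BASES[draw[i]] + _BASES[draw[i + 1]] + _BASES[draw[i + 2]]
            if codon not in STOP_CODONS:
                out.append(codon)
            if len(out) == n_codons:
                break
    return "".join(out)


def _random_coding(rng: np.random.Generator, length_bp: int, gc: float) -> str:
    """ATG + sense codons + stop, exactly ``length_bp`` (multiple of 3)."""
    assert length_bp % 3 == 0 and length_bp >= 9
    body = _random_codons(rng, length_bp // 3 - 2, gc)
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    return "ATG" + body + stop


_PRODUCT_CYCLE = (
    "sulfur oxidation protein",
    "ABC transporter permease",
    "carbon fixation enzyme",
    "outer membrane protein",
    "two-component sensor kinase",
    "ribosomal protein",
    "hypothetical protein",
    "carbonic anhydrase",
    "flagellar assembly protein",
    "cytochrome c oxidase subunit",
)

_PHAGE_PRODUCTS = (
    "phage integrase",
    "hypothetical protein",
    "phage capsid protein",
    "hypothetical protein",
    "hypothetical protein",
)


def _tune_gc(
    arr: np.ndarray,
    target: float,
    eligible: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Flip eligible positions between base classes until GC hits the target
    (to within one base).  ``arr`` is a 1-char unicode array, edited in place."""
    is_gc = np.isin(arr, list("GC"))
    n = len(arr)
    delta = int(round((target - is_gc.mean()) * n))
    if delta == 0:
        return
    if delta > 0:
        pool = eligible[~is_gc[eligible]]
        new_bases = "GC"
    else:
        pool = eligible[is_gc[eligible]]
        new_bases = "AT"
    k = min(abs(delta), len(pool))
    chosen = rng.choice(pool, size=k, replace=False)
    arr[chosen] = [new_bases[i] for i in rng.integers(0, 2, size=k)]


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

def build_reference(config: SimConfig) -> AnnotatedGenome:
    """Generate the mock finished genome: annotated ORFs on both strands at
    the reference GC target, with the prophage (and its duplicated direct
    repeat) inserted at an intergenic site."""
    rng = np.random.default_rng([1, config.seed])
    L = config.genome_length
    pro = config.prophage
    elem_len = (pro.length_bp + 2 * pro.repeat_length) if pro else 0
    backbone = L - elem_len
    if backbone <= 0:
        raise PlacementError("genome_length too small for the prophage element")

    n = config.n_orfs
    min_gap = 40
    if n > 0:
        lens = (rng.integers(100, 801, size=n) * 3).astype(int)  # 300..2403 bp
        spare = backbone - int(lens.sum()) - min_gap * (n + 1)
        if spare < 0:
            raise PlacementError(
                f"cannot place n_orfs={n} ORFs totalling {int(lens.sum())} bp in a "
                f"{backbone} bp backbone; reduce n_orfs or increase genome_length"
            )
        cuts = np.sort(rng.integers(0, spare + 1, size=n))
        extras = np.diff(np.concatenate([[0], cuts, [spare]]))
        gaps = extras + min_gap
    else:
        lens = np.empty(0, dtype=int)
        gaps = np.array([backbone])

    parts: list[str] = []
    orf_spans: list[tuple[int, int, str]] = []  # 0-based half-open
    pos = 0
    for i in range(n):
        parts.append(_random_seq(rng, int(gaps[i]), config.gc_reference))
        pos += int(gaps[i])
        coding = _random_coding(rng, int(lens[i]), config.gc_reference)
        strand = "+" if rng.random() < 0.5 else "-"
        parts.append(coding if strand == "+" else reverse_complement(coding))
        orf_spans.append((pos, pos + int(lens[i]), strand))
        pos += int(lens[i])
    parts.append(_random_seq(rng, int(gaps[-1]), config.gc_reference))
    seq = "".join(parts)
    assert len(seq) == backbone

    prophage_span: tuple[int, int, int] | None = None
    phage_spans: list[tuple[int, int, str]] = []
    if pro:
        # snap the insertion site to the nearest intergenic point
        site = min(max(pro.insertion_site, 0), backbone)
        for s, e, _ in orf_spans:
            if s <= site < e:
                site = s if site - s < e - site else e
                break
        for _ in range(50):
            repeat = _random_seq(rng, pro.repeat_length, config.gc_reference)
            if repeat not in seq and reverse_complement(repeat) not in seq:
                break
        else:  # pragma: no cover
            raise PlacementError("could not draw a unique direct repeat sequence")
        gap = 40
        per = ((pro.length_bp - gap * (pro.n_orfs + 1)) // max(pro.n_orfs, 1) // 3) * 3
        if pro.n_orfs > 0 and per < 300:
            raise PlacementError("prophage length_bp too small for its ORF count")
        interior_parts: list[str] = []
        ipos = 0
        for j in range(pro.n_orfs):
            interior_parts.append(_random_seq(rng, gap, config.gc_reference))
            ipos += gap
            interior_parts.append(_random_coding(rng, per, config.gc_reference))
            phage_spans.append((ipos, ipos + per, "+"))
            ipos += per
        interior_parts.append(
            _random_seq(rng, pro.length_bp - ipos, config.gc_reference)
        )
        interior = "".join(interior_parts)
        element = repeat + interior + repeat
        seq = seq[:site] + element + seq[site:]
        orf_spans = [
            (s + elem_len, e + elem_len, st) if s >= site else (s, e, st)
            for s, e, st in orf_spans
        ]
        phage_off = site + pro.repeat_length
        phage_abs = [(s + phage_off, e + phage_off, st) for s, e, st in phage_spans]
        prophage_span = (site, site + elem_len, pro.repeat_length)
    else:
        phage_abs = []

    # GC tuning on intergenic positions (never inside ORFs or the repeat copies)
    arr = np.array(list(seq), dtype="<U1")
    covered = np.zeros(len(arr), dtype=bool)
    for s, e, _ in orf_spans + phage_abs:
        covered[s:e] = True
    if prophage_span:
        ps, pe, rl = prophage_span
        covered[ps : ps + rl] = True
        covered[pe - rl : pe] = True
    _tune_gc(arr, config.gc_reference, np.nonzero(~covered)[0], rng)
    if prophage_span:
        # keep a local alignment of the two boundary windows from extending
        # past the planted repeat copies by a chance matching base
        ps, pe, rl = prophage_span
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        if ps > 0 and arr[ps - 1] == arr[pe - rl - 1]:
            arr[pe - rl - 1] = flip[str(arr[pe - rl - 1])]
        if pe < len(arr) and arr[ps + rl] == arr[pe]:
            arr[ps + rl] = flip[str(arr[ps + rl])]
    seq = "".join(arr)

    all_spans = sorted(
        [(s, e, st, False) for s, e, st in orf_spans]
        + [(s, e, st, True) for s, e, st in phage_abs]
    )
    orfs: list[OrfRecord] = []
    products: dict[str, str] = {}
    phage_i = 0
    for i, (s, e, st, is_phage) in enumerate(all_spans, start=1):
        tag = f"REF_{i:04d}"
        coding = seq[s:e] if st == "+" else reverse_complement(seq[s:e])
        orfs.append(
            OrfRecord(
                contig_id="REFGENOME",
                locus_tag=tag,
                start=s + 1,
                end=e,
                strand=st,
                translation=str(Seq(coding).translate())[:-1],
            )
        )
        if is_phage:
            products[tag] = _PHAGE_PRODUCTS[phage_i % len(_PHAGE_PRODUCTS)]
            phage_i += 1
        else:
            products[tag] = _PRODUCT_CYCLE[(i - 1) % len(_PRODUCT_CYCLE)]
    return AnnotatedGenome(
        record=SeqRecord(id="REFGENOME", sequence=seq, description="simulated reference"),
        orfs=orfs,
        products=products,
        prophage=prophage_span,
    )


# ---------------------------------------------------------------------------
# Query evolution
# ---------------------------------------------------------------------------

@dataclass
class _QOrf:
    start: int  # 0-based half-open, query coordinates
    end: int
    strand: str
    kind: str  # ortholog | transposase | foreign
    ref_locus: str = ""
    ref_aa_off: int = 0  # codon offset into the reference protein (fusion parts)
    product: str = ""


def _snap_outside_orfs(pos: int, spans: list[tuple[int, int]]) -> int:
    for s, e in spans:
        if s < pos < e:
            return s if pos - s < e - pos else e
    return pos


def _segment_offsets(segments: list[tuple[int, int]]) -> list[tuple[int, int, int]]:
    """(ref_start, ref_end, query_start) per materialized segment."""
    out = []
    q = 0
    for s, e in segments:
        out.append((s, e, q))
        q += e - s
    return out


def evolve_query(
    ref: AnnotatedGenome, config: SimConfig
) -> tuple[AnnotatedGenome, TruthLedger]:
    """Evolve the diverged query lineage from the reference.

    Applied in order: prophage + direct repeat removal (the query shows the
    pre-insertion state, with no repeat copy), translocation, fusion splits,
    codon-aware substitutions with GC drift, intergenic insertion of
    transposase copies and reverse-orientation foreign ORFs.  Every event is
    recorded in the returned truth ledger.
    """
    rng = np.random.default_rng([2, config.seed])
    L = len(ref)
    refseq = ref.sequence
    ref_spans = [(o.start - 1, o.end) for o in ref.orfs]
    ledger = TruthLedger(seed=config.seed)

    # --- structural plan in reference coordinates --------------------------
    deleted: list[tuple[int, int]] = []
    if ref.prophage:
        deleted.append((ref.prophage[0], ref.prophage[1]))

    if config.translocation:
        t = config.translocation
        a1 = _snap_outside_orfs(t.region_a[1], ref_spans)
        b0 = _snap_outside_orfs(t.region_b[0], ref_spans)
        b1 = _snap_outside_orfs(t.region_b[1], ref_spans)
        if not (a1 <= b0 < b1):
            raise PlacementError("translocation regions collapsed after snapping")
        segments = [(0, a1), (b0, b1), (a1, b0), (b1, L)]
    else:
        a1 = b0 = b1 = -1
        segments = [(0, L)]

    # subtract deleted (prophage) intervals
    final_segments: list[tuple[int, int]] = []
    for s, e in segments:
        pieces = [(s, e)]
        for ds, de in deleted:
            nxt: list[tuple[int, int]] = []
            for ps, pe in pieces:
                if de <= ps or ds >= pe:
                    nxt.append((ps, pe))
                else:
                    if ps < ds:
                        nxt.append((ps, ds))
                    if de < pe:
                        nxt.append((de, pe))
            pieces = nxt
        final_segments.extend(p for p in pieces if p[1] > p[0])

    offsets = _segment_offsets(final_segments)

    def ref_to_query(x: int) -> int | None:
        for s, e, q in offsets:
            if s <= x < e:
                return q + (x - s)
        return None

    qseq = "".join(refseq[s:e] for s, e, _ in offsets)
    # reference-aligned copy for divergence accounting
    ref_aligned = np.array(list(qseq), dtype="<U1")
    qarr = ref_aligned.copy()

    # map reference ORFs into query coordinates
    qorfs: list[_QOrf] = []
    dropped_loci: list[str] = []
    for orf in ref.orfs:
        s0, e0 = orf.start - 1, orf.end
        placed = False
        for rs, re_, q in offsets:
            if rs <= s0 and e0 <= re_:
                qorfs.append(
                    _QOrf(
                        start=q + (s0 - rs),
                        end=q + (e0 - rs),
                        strand=orf.strand,
                        kind="ortholog",
                        ref_locus=orf.locus_tag,
                        product=ref.products.get(orf.locus_tag, ""),
                    )
                )
                placed = True
                break
        if not placed:
            dropped_loci.append(orf.locus_tag)
    qorfs.sort(key=lambda o: o.start)

    if config.translocation:
        tq0 = ref_to_query(b0)
        tq1 = tq0 + (b1 - b0) if tq0 is not None else 0
        ledger.records.append(
            LedgerRecord(
                kind="translocation",
                ref_start=b0,
                ref_end=b1,
                query_start=tq0 or 0,
                query_end=tq1,
                strand="+",
                identity=float("nan"),
                note=f"gap_bp={b0 - a1};joined_after_ref={a1}",
            )
        )
    if ref.prophage:
        es, ee, rl = ref.prophage
        junction = ref_to_query(ee)  # first retained base after the element
        repeat_seq = refseq[es : es + rl]
        ledger.records.append(
            LedgerRecord(
                kind="prophage",
                ref_start=es,
                ref_end=ee,
                query_start=junction or 0,
                query_end=junction or 0,
                strand="+",
                identity=float("nan"),
                note=f"repeat={repeat_seq};deleted_loci={','.join(dropped_loci)}",
            )
        )

    # --- fusion splits ------------------------------------------------------
    # one reference ORF appears as two adjacent, separately coded query ORFs
    candidates = [
        i
        for i, o in enumerate(qorfs)
        if o.kind == "ortholog" and (o.end - o.start) >= 900
    ]
    if config.n_fusions > len(candidates):
        raise PlacementError(
            f"n_fusions={config.n_fusions} exceeds the {len(candidates)} ORFs >= 900 bp"
        )
    fusion_idx = sorted(
        rng.choice(np.array(candidates), size=config.n_fusions, replace=False).tolist()
    )
    new_qorfs: list[_QOrf] = []
    for i, o in enumerate(qorfs):
        if i not in fusion_idx:
            new_qorfs.append(o)
            continue
        n_codons = (o.end - o.start) // 3
        k = n_codons // 2  # codon index of the new stop
        if o.strand == "+":
            stop_at = o.start + 3 * k
            qarr[stop_at : stop_at + 3] = list("TAA")
            qarr[stop_at + 3 : stop_at + 6] = list("ATG")
            part1 = replace(o, end=stop_at + 3)
            part2 = replace(o, start=stop_at + 3, ref_aa_off=k + 1)
        else:
            # coding strand runs right-to-left; codon k sits at the high end
            stop_at = o.end - 3 * (k + 1)
            qarr[stop_at : stop_at + 3] = list(reverse_complement("TAA"))
            qarr[stop_at - 3 : stop_at] = list(reverse_complement("ATG"))
            part1 = replace(o, start=stop_at)
            part2 = replace(o, end=stop_at, ref_aa_off=k + 1)
        new_qorfs.extend([part1, part2])
        ro = ref.orf_by_tag(o.ref_locus)
        ledger.records.append(
            LedgerRecord(
                kind="fusion",
                ref_start=ro.start - 1,
                ref_end=ro.end,
                query_start=o.start,
                query_end=o.end,
                strand=o.strand,
                identity=float("nan"),
                note=f"ref_locus={o.ref_locus};split_codon={k}",
            )
        )
    qorfs = sorted(new_qorfs, key=lambda o: o.start)

    # --- codon-aware substitutions -----------------------------------------
    d = config.nt_divergence
    n_query = len(qarr)
    coding_mask = np.zeros(n_query, dtype=bool)
    for o in qorfs:
        coding_mask[o.start : o.end] = True
    intergenic = np.nonzero(~coding_mask)[0]

    mutated_intergenic: list[int] = []
    if d > 0:
        # substitute-base composition solved so the genome lands on gc_query
        ref_gc = gc_content(qseq).gc_fraction
        g_sub = min(0.95, max(0.05, (config.gc_query - (1 - d) * ref_gc) / d))
        p_sub = _base_probs(g_sub)

        def pick_base(exclude: str, allowed: str = _BASES) -> str:
            choices = [b for b in allowed if b != exclude]
            w = np.array([p_sub[_BASES.index(b)] for b in choices])
            if w.sum() == 0:
                w = np.ones(len(choices))
            return choices[rng.choice(len(choices), p=w / w.sum())]

        # intergenic: plain substitution at the target rate
        hits = intergenic[rng.random(len(intergenic)) < d]
        for pos in hits:
            qarr[pos] = pick_base(str(qarr[pos]))
        mutated_intergenic = list(hits)

        # coding: synonymous third positions at `ratio` times the
        # nonsynonymous rate, never creating or destroying stops.  Synonymous
        # flips from the AT into the GC class are damped: two-fold degenerate
        # sites always change class, which would otherwise push the AT-rich
        # genome's GC upward against the target drift.  The realized coding
        # rate is pinned to the target afterwards by adding or reverting
        # synonymous third-position changes, so divergence stays spatially
        # uniform across coding and intergenic sequence.
        ratio = config.syn_nonsyn_ratio
        syn_swap: list[tuple[int, str, str]] = []  # mutated: (gpos, AT opts, GC opts)
        syn_add: list[tuple[int, str, str]] = []  # unmutated, syn option exists
        syn_revert: list[int] = []  # mutated third positions revertable to ref
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for o in qorfs:
            if o.kind != "ortholog":
                continue
            span = qarr[o.start : o.end]
            coding = (
                "".join(span) if o.strand == "+" else reverse_complement("".join(span))
            )
            codons = [coding[i : i + 3] for i in range(0, len(coding), 3)]
            syn_possible = sum(1 for c in codons[1:-1] if _SYN3.get(c))
            f_syn = syn_possible / max(len(codons) - 2, 1)
            p12 = 3 * d / (ratio * f_syn + 2)
            p3 = min(0.98, ratio * p12)
            out = list(codons)
            for ci in range(1, len(codons) - 1):
                codon = out[ci]
                if rng.random() < p3 and _SYN3.get(codon):
                    b = pick_base(codon[2], _SYN3[codon])
                    to_gc = codon[2] in "AT" and b in "GC"
                    if not to_gc or rng.random() < 0.5:
                        codon = codon[:2] + b
                for pos in (0, 1):
                    if rng.random() < p12:
                        for _ in range(8):
                            b = pick_base(codon[pos])
                            cand = codon[:pos] + b + codon[pos + 1 :]
                            if cand not in STOP_CODONS:
                                codon = cand
                                break
                out[ci] = codon
                # classify the finalized third position for later calibration
                if o.strand == "+":
                    gpos = o.start + 3 * ci + 2
                    to_genome = lambda b: b
                    to_coding = lambda b: b
                else:
                    gpos = o.end - 3 * ci - 3
                    to_genome = comp.get
                    to_coding = comp.get
                ref_b = str(ref_aligned[gpos])
                final_b = to_genome(codon[2])
                syn_set = set(_SYN3.get(codon, "")) | {codon[2]}
                opts = {to_genome(b) for b in syn_set} - {ref_b, final_b}
                at = "".join(sorted(b for b in opts if b in "AT"))
                gc = "".join(sorted(b for b in opts if b in "GC"))
                if final_b != ref_b:
                    if at or gc:
                        syn_swap.append((gpos, at, gc))
                    if to_coding(ref_b) in syn_set:
                        syn_revert.append(gpos)
                elif at or gc:
                    syn_add.append((gpos, at, gc))
            new_coding = "".join(out)
            if o.strand == "-":
                new_coding = reverse_complement(new_coding)
            qarr[o.start : o.end] = list(new_coding)

        # per-stratum rate calibration: coding first (synonymous sites only,
        # so proteins are untouched), then intergenic
        mism = qarr != ref_aligned
        cod_needed = int(round(d * coding_mask.sum())) - int(mism[coding_mask].sum())
        if cod_needed > 0:
            take = rng.choice(len(syn_add), size=min(cod_needed, len(syn_add)), replace=False)
            for i in take:
                gpos, at, gc = syn_add[int(i)]
                pool = at + gc
                w = np.array([p_sub[_BASES.index(b)] for b in pool])
                qarr[gpos] = pool[rng.choice(len(pool), p=w / w.sum())]
        elif cod_needed < 0:
            take = rng.choice(
                len(syn_revert), size=min(-cod_needed, len(syn_revert)), replace=False
            )
            for i in take:
                gpos = syn_revert[int(i)]
                qarr[gpos] = ref_aligned[gpos]

        # top-up/down on intergenic sites to pin the intergenic rate
        mismatch = qarr != ref_aligned
        needed = int(round(d * len(intergenic))) - int(mismatch[intergenic].sum())
        if needed > 0:
            pool = intergenic[~mismatch[intergenic]]
            for pos in rng.choice(pool, size=min(needed, len(pool)), replace=False):
                qarr[pos] = pick_base(str(qarr[pos]))
                mutated_intergenic.append(int(pos))
        elif needed < 0:
            pool = np.array(mutated_intergenic, dtype=int)
            for pos in rng.choice(pool, size=min(-needed, len(pool)), replace=False):
                qarr[pos] = ref_aligned[pos]
                mutated_intergenic.remove(int(pos))

    # --- insertions: transposase copies and reverse-orientation ORFs --------
    tp_len = 960
    transposase = _random_coding(rng, tp_len, config.gc_query)
    foreign_seqs = [
        _random_coding(rng, int(rng.integers(200, 301)) * 3, config.gc_query)
        for _ in range(config.n_foreign_orfs)
    ]

    # pre-insertion GC target compensating for inserted material
    ins_total = config.n_transposase_copies * tp_len + sum(map(len, foreign_seqs))
    if ins_total > 0 and d > 0:
        ins_gc = gc_content(transposase * config.n_transposase_copies + "".join(foreign_seqs)).gc_fraction
        target_pre = (config.gc_query * (n_query + ins_total) - ins_gc * ins_total) / n_query
    else:
        target_pre = config.gc_query

    if d > 0 and (mutated_intergenic or syn_swap):
        # divergence-preserving GC swap pass: re-draw substituted bases into
        # whichever class is short, never matching the ancestral base.
        # Candidates are mutated intergenic sites plus mutated synonymous
        # third positions with a same-class-complementing synonymous option.
        arr_is_gc = np.isin(qarr, list("GC"))
        delta = int(round((target_pre - arr_is_gc.mean()) * n_query))
        want = "GC" if delta > 0 else "AT"
        pool = np.array(sorted(mutated_intergenic), dtype=int)
        inter = pool[arr_is_gc[pool] != (delta > 0)]
        syn_elig = [
            (gpos, at if want == "AT" else gc)
            for gpos, at, gc in syn_swap
            if (at if want == "AT" else gc)
            and arr_is_gc[gpos] == (delta < 0)
            and qarr[gpos] != ref_aligned[gpos]  # may have been reverted
        ]
        cands: list[tuple[int, str]] = [
            (int(p), "".join(b for b in want if b != str(ref_aligned[p])))
            for p in inter
        ] + syn_elig
        k = min(abs(delta), len(cands))
        for ci in rng.choice(len(cands), size=k, replace=False):
            pos, options = cands[int(ci)]
            qarr[pos] = options[rng.integers(0, len(options))]

    measured_d = float((qarr != ref_aligned).mean()) if n_query else 0.0
    ledger.records.append(
        LedgerRecord(
            kind="substitution-rate",
            ref_start=0,
            ref_end=L,
            query_start=0,
            query_end=n_query,
            strand="+",
            identity=measured_d,
            note=f"target={d};syn_nonsyn_ratio={config.syn_nonsyn_ratio}",
        )
    )

    # choose intergenic insertion points on the mutated pre-insertion genome
    gaps: list[tuple[int, _QOrf | None, _QOrf | None]] = []
    for i in range(len(qorfs) + 1):
        lo = qorfs[i - 1].end if i > 0 else 0
        hi = qorfs[i].start if i < len(qorfs) else n_query
        if hi - lo >= 120:
            gaps.append(
                ((lo + hi) // 2, qorfs[i - 1] if i > 0 else None, qorfs[i] if i < len(qorfs) else None)
            )
    plus_plus = [
        g for g in gaps if g[1] and g[2] and g[1].strand == "+" and g[2].strand == "+"
    ]
    if config.n_foreign_orfs > len(plus_plus):
        raise PlacementError(
            f"n_foreign_orfs={config.n_foreign_orfs} exceeds the {len(plus_plus)} "
            "intergenic gaps between same-strand (+) ORF pairs"
        )
    chosen_f = rng.choice(len(plus_plus), size=config.n_foreign_orfs, replace=False)
    foreign_sites = [plus_plus[i][0] for i in sorted(chosen_f)]
    remaining = [g[0] for g in gaps if g[0] not in set(foreign_sites)]
    if config.n_transposase_copies > len(remaining):
        raise PlacementError(
            f"n_transposase_copies={config.n_transposase_copies} exceeds the "
            f"{len(remaining)} available intergenic gaps"
        )
    chosen_t = rng.choice(len(remaining), size=config.n_transposase_copies, replace=False)
    tp_sites = [remaining[i] for i in sorted(chosen_t)]

    ops: list[tuple[int, str, str, str]] = []  # (pos, seq, kind, strand)
    for site, fseq in zip(foreign_sites, foreign_seqs):
        ops.append((site, reverse_complement(fseq), "foreign", "-"))
    for site in tp_sites:
        strand = "+" if rng.random() < 0.5 else "-"
        ops.append((site, transposase if strand == "+" else reverse_complement(transposase), "transposase", strand))
    ops.sort(key=lambda t: t[0])

    def shifted(x: int) -> int:
        return x + sum(len(seq) for pos, seq, _, _ in ops if pos <= x)

    pieces: list[str] = []
    cursor = 0
    inserted_orfs: list[_QOrf] = []
    for pos, seq_i, kind, strand in ops:
        pieces.append("".join(qarr[cursor:pos]))
        start_final = shifted(pos) - len(seq_i)
        pieces.append(seq_i)
        inserted_orfs.append(
            _QOrf(
                start=start_final,
                end=start_final + len(seq_i),
                strand=strand,
                kind=kind,
                product="transposase" if kind == "transposase" else "membrane protein (foreign)",
            )
        )
        cursor = pos
    pieces.append("".join(qarr[cursor:]))
    query_seq = "".join(pieces)

    # insertions sit in intergenic gaps, so an ORF's two ends shift together
    final_orfs: list[_QOrf] = [
        replace(o, start=shifted(o.start), end=shifted(o.start) + (o.end - o.start))
        for o in qorfs
    ] + inserted_orfs
    final_orfs.sort(key=lambda o: o.start)

    for o in inserted_orfs:
        ledger.records.append(
            LedgerRecord(
                kind="transposase-copy" if o.kind == "transposase" else "foreign-orf",
                ref_start=0,
                ref_end=0,
                query_start=o.start,
                query_end=o.end,
                strand=o.strand,
                identity=float("nan"),
                note="identical copies" if o.kind == "transposase" else "reverse orientation",
            )
        )

    # events recorded before the insertions carry pre-insertion query
    # coordinates; shift them onto the final genome
    shifted_records = []
    for r in ledger.records:
        if r.kind in ("translocation", "prophage", "fusion"):
            r = replace(r, query_start=shifted(r.query_start), query_end=shifted(r.query_end))
        shifted_records.append(r)
    ledger.records = shifted_records

    # --- final annotation + per-ORF identity -------------------------------
    orfs_out: list[OrfRecord] = []
    products: dict[str, str] = {}
    for i, o in enumerate(final_orfs, start=1):
        tag = f"QRY_{i:04d}"
        sub = query_seq[o.start : o.end]
        coding = sub if o.strand == "+" else reverse_complement(sub)
        translation = str(Seq(coding).translate())[:-1]
        orfs_out.append(
            OrfRecord(
                contig_id="QRYGENOME",
                locus_tag=tag,
                start=o.start + 1,
                end=o.end,
                strand=o.strand,
                translation=translation,
            )
        )
        products[tag] = o.product
        if o.kind == "ortholog":
            ref_orf = ref.orf_by_tag(o.ref_locus)
            ref_prot = ref_orf.translation
            seg = ref_prot[o.ref_aa_off : o.ref_aa_off + len(translation)]
            if len(seg) == len(translation) and translation:
                ident = sum(a == b for a, b in zip(seg, translation)) / len(translation)
            else:
                ident = float("nan")
            ledger.records.append(
                LedgerRecord(
                    kind="orf-identity",
                    ref_start=ref_orf.start - 1,
                    ref_end=ref_orf.end,
                    query_start=o.start,
                    query_end=o.end,
                    strand=o.strand,
                    identity=ident,
                    note=f"{tag}={o.ref_locus};aa_off={o.ref_aa_off}",
                )
            )

    query = AnnotatedGenome(
        record=SeqRecord(id="QRYGENOME", sequence=query_seq, description="simulated diverged lineage"),
        orfs=orfs_out,
        products=products,
        prophage=None,
    )
    return query, ledger


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    genome: AnnotatedGenome, config: SimConfig
) -> tuple[list[SeqRecord], dict[str, tuple[int, int, str]]]:
    """Sanger-style paired-end reads from clone inserts.

    Returns the reads plus a truth table mapping each read id to its source
    interval (0-based half-open) and strand on the query genome.  Read names
    follow the clone-stem + suffix convention (``.b1``/``.g1``).
    """
    L = len(genome)
    if L == 0:
        raise ValueError("cannot simulate reads from an empty genome")
    rng = np.random.default_rng([3, config.seed])
    n_pairs = int(round(config.coverage_target * L / (2 * config.read_length_mean)))
    reads: list[SeqRecord] = []
    truth: dict[str, tuple[int, int, str]] = {}
    seq = genome.sequence
    for i in range(n_pairs):
        l1 = int(np.clip(rng.normal(config.read_length_mean, config.read_length_sd), 50, None))
        l2 = int(np.clip(rng.normal(config.read_length_mean, config.read_length_sd), 50, None))
        insert = int(rng.normal(config.insert_size_mean, config.insert_size_sd))
        min_insert = 2 * max(l1, l2)
        if insert < min_insert:
            logger.warning(
                "clone %d: insert size %d smaller than twice the read length; "
                "clamped to %d",
                i,
                insert,
                min_insert,
            )
            insert = min_insert
        insert = min(insert, L)
        l1, l2 = min(l1, insert), min(l2, insert)
        start = int(rng.integers(0, L - insert + 1))
        stem = f"LCS{i:05d}"
        fwd_id, rev_id = f"{stem}.b1", f"{stem}.g1"
        reads.append(SeqRecord(id=fwd_id, sequence=seq[start : start + l1]))
        truth[fwd_id] = (start, start + l1, "+")
        rev_lo = start + insert - l2
        reads.append(
            SeqRecord(id=rev_id, sequence=reverse_complement(seq[rev_lo : start + insert]))
        )
        truth[rev_id] = (rev_lo, start + insert, "-")
    return reads, truth


# ---------------------------------------------------------------------------
# Contig fixtures
# ---------------------------------------------------------------------------

def make_contig_fixtures(
    genome: AnnotatedGenome,
    reads: Sequence[SeqRecord],
    config: SimConfig,
    read_truth: dict[str, tuple[int, int, str]],
    ledger: TruthLedger | None = None,
    n_large: int = 4,
    n_small: int = 30,
) -> tuple[list[SeqRecord], list[MembershipRow]]:
    """Simulated assembly: contigs are disjoint windows of the query genome.

    Large windows (>10 kb) are centred on the planted structural events when a
    ledger is supplied (the translocation junction, the prophage junction,
    and each fusion locus), echoing the real situation where the informative
    loci sit on the largest contigs.  Each read is assigned to the window
    containing its source midpoint, or marked unassembled.
    """
    L = len(genome)
    rng = np.random.default_rng([4, config.seed])
    centres: list[int] = []
    if ledger is not None:
        for r in ledger.of_kind("translocation"):
            centres.append(r.query_start)  # the junction, not the region middle
        for r in ledger.of_kind("prophage"):
            centres.append(r.query_start)
        for r in ledger.of_kind("fusion"):
            centres.append((r.query_start + r.query_end) // 2)
    windows: list[tuple[int, int]] = []

    def disjoint(s: int, e: int) -> bool:
        return all(e <= ws or s >= we for ws, we in windows)

    for c in centres[:n_large]:
        size = int(rng.integers(11_000, 15_001))
        # prefer a centred window; when that collides with an earlier event
        # window, slide the window while keeping the event well inside it
        candidates = [c - size // 2]
        for ws, we in windows:
            candidates.extend([we, ws - size])
        for s in candidates:
            s = max(0, min(s, L - size))
            if disjoint(s, s + size) and s + 500 <= c <= s + size - 500:
                windows.append((s, s + size))
                break
    attempts = 0
    while len(windows) < n_large and attempts < 200:
        size = int(rng.integers(11_000, 15_001))
        s = int(rng.integers(0, max(L - size, 1)))
        if disjoint(s, s + size):
            windows.append((s, s + size))
        attempts += 1
    small_added = 0
    attempts = 0
    while small_added < n_small and attempts < 2000:
        size = int(rng.integers(600, 2201))
        s = int(rng.integers(0, max(L - size, 1)))
        if disjoint(s, s + size):
            windows.append((s, s + size))
            small_added += 1
        attempts += 1

    windows.sort()
    contigs: list[SeqRecord] = []
    for i, (s, e) in enumerate(windows, start=1):
        contigs.append(
            SeqRecord(
                id=f"C{i:04d}",
                sequence=genome.sequence[s:e],
                description=f"window={s + 1}..{e}",
            )
        )

    starts = np.array([w[0] for w in windows])
    ends = np.array([w[1] for w in windows])
    rows: list[MembershipRow] = []
    for read in reads:
        rs, re_, _ = read_truth[read.id]
        mid = (rs + re_) // 2
        idx = np.nonzero((starts <= mid) & (mid < ends))[0]
        if len(idx) == 0:
            rows.append(MembershipRow(read_id=read.id, contig_id="", read_bp=len(read)))
            continue
        w = int(idx[0])
        ws = int(starts[w])
        lo = max(rs, ws) - ws
        hi = min(re_, int(ends[w])) - ws
        rows.append(
            MembershipRow(
                read_id=read.id,
                contig_id=contigs[w].id,
                read_bp=len(read),
                start=lo + 1,
                end=hi,
            )
        )
    return contigs, rows


# ---------------------------------------------------------------------------
# One-call bundle
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    config: SimConfig
    reference: AnnotatedGenome
    query: AnnotatedGenome
    ledger: TruthLedger
    reads: list[SeqRecord]
    read_truth: dict[str, tuple[int, int, str]]
    contigs: list[SeqRecord]
    membership: list[MembershipRow]

    @property
    def transposase_protein(self) -> SeqRecord | None:
        """The transposase protein planted in the query (one copy's
        translation), or None on a null simulation."""
        for orf in self.query.orfs:
            if self.query.products.get(orf.locus_tag) == "transposase":
                return SeqRecord(id="TPASE_1", sequence=orf.translation, description="planted transposase")
        return None

    @property
    def foreign_proteins(self) -> list[SeqRecord]:
        """Translations of the planted foreign ORFs (the 'other taxa' set)."""
        out = []
        for i, orf in enumerate(self.query.orfs):
            if "foreign" in self.query.products.get(orf.locus_tag, ""):
                out.append(
                    SeqRecord(id=f"FOREIGN_{i}", sequence=orf.translation, description="")
                )
        return out


def simulate_all(config: SimConfig) -> SimResult:
    """Run the full simulation: reference, query, reads, contig fixtures."""
    ref = build_reference(config)
    query, ledger = evolve_query(ref, config)
    reads, truth = simulate_reads(query, config)
    contigs, membership = make_contig_fixtures(
        query, reads, config, truth, ledger=ledger
    )
    return SimResult(
        config=config,
        reference=ref,
        query=query,
        ledger=ledger,
        reads=reads,
        read_truth=truth,
        contigs=contigs,
        membership=membership,
    )
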