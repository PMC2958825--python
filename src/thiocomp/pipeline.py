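"""End-to-end pipeline orchestration over a simulated study.

Stages run in a fixed order (simulate, orfs, search, recruit, contigstats,
synteny, prophage, telink, census); every stage writes plain-text artifacts
into the run directory and records their checksums in ``manifest.json``.
Re-running skips stages whose parameters and outputs are unchanged; a
corrupted or missing artifact invalidates its stage and all stages after it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Callable

from . import __version__
from .census import census, missing_gene_report, tier_counts, validate_tier_nesting, write_census
from .contig_stats import contig_table, size_filter_report, write_contig_table
from .genome import AnnotatedGenome
from .homology_search import (
    NucleotideSearcher,
    ProteinDatabase,
    ScoringScheme,
    TranslatedDatabase,
)
from .io_formats import (
    SeqRecord,
    pair_reads,
    read_annotations,
    read_fasta,
    read_hits_tabular,
    read_membership,
    read_orf_table,
    write_fasta,
    write_hits_tabular,
    write_membership,
)
from .prophage_indel import find_insertions, repeat_test
from .recruitment import recruit, recruited_fraction, write_profile
from .simulate import SimConfig, TruthLedger, simulate_all
from .synteny_fusion import (
    anchor_orfs,
    build_blocks,
    call_fusions,
    flag_discordant_orfs,
)
from .transposase_linkage import (
    classify_transposase_sequences,
    density_estimate,
    link_contigs,
    write_linkage_report,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "STAGES"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_hash(config: SimConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _orfs_with_translations(orf_table_path: Path, proteins_path: Path):
    """Rehydrate ORF records with their translations from the paired FASTA."""
    orfs = read_orf_table(orf_table_path)
    prots = {r.id: r.sequence for r in read_fasta(proteins_path)}
    return [
        dataclasses.replace(o, translation=prots.get(o.locus_tag, "")) for o in orfs
    ]


# --------------------------------------------------------------------------
# stage implementations: each takes the run directory + config, reads its
# inputs from earlier stages' files, and returns the files it wrote
# --------------------------------------------------------------------------

def _stage_simulate(d: Path, config: SimConfig) -> list[str]:
    res = simulate_all(config)
    res.reference.write(d, "ref")
    res.query.write(d, "query")
    write_fasta(res.reads, d / "reads.fasta")
    write_fasta(res.contigs, d / "contigs.fasta")
    write_membership(res.membership, d / "membership.tsv")
    res.ledger.write(d / "truth.tsv")
    write_fasta(res.reference.protein_records(), d / "ref.proteins.faa")
    tp = res.transposase_protein
    write_fasta([tp] if tp else [], d / "transposase.faa")
    write_fasta(res.foreign_proteins, d / "foreign.faa")
    with open(d / "elements.tsv", "w", newline="\n") as fh:
        fh.write("name\tstart\tend\n")
        if res.reference.prophage:
            ps, pe, _ = res.reference.prophage
            fh.write(f"prophage\t{ps + 1}\t{pe}\n")
    return [
        "ref.fasta", "ref.orfs.tsv", "ref.annotations.tsv",
        "query.fasta", "query.orfs.tsv", "query.annotations.tsv",
        "reads.fasta", "contigs.fasta", "membership.tsv", "truth.tsv",
        "ref.proteins.faa", "transposase.faa", "foreign.faa", "elements.tsv",
    ]


def _stage_orfs(d: Path, config: SimConfig) -> list[str]:
    from .seq_core import find_orfs

    contigs = read_fasta(d / "contigs.fasta")
    orfs = []
    prots = []
    for c in contigs:
        for o in find_orfs(c.sequence, contig_id=c.id, locus_prefix=f"{c.id}_ORF"):
            orfs.append(o)
            prots.append(SeqRecord(id=o.locus_tag, sequence=o.translation))
    from .io_formats import write_orf_table

    write_orf_table(orfs, d / "contig_orfs.tsv")
    write_fasta(prots, d / "contig_orfs.faa")
    return ["contig_orfs.tsv", "contig_orfs.faa"]


def _stage_search(d: Path, config: SimConfig) -> list[str]:
    ref = read_fasta(d / "ref.fasta")[0]
    reads = read_fasta(d / "reads.fasta")
    contigs = read_fasta(d / "contigs.fasta")
    ref_prots = read_fasta(d / "ref.proteins.faa")
    contig_prots = read_fasta(d / "contig_orfs.faa")
    tpase = read_fasta(d / "transposase.faa")
    foreign = read_fasta(d / "foreign.faa")
    membership = read_membership(d / "membership.tsv")
    singlet_ids = {r.read_id for r in membership if r.unassembled}
    singlets = [r for r in reads if r.id in singlet_ids]

    # +5/-4 keeps ~70%-identity alignments near-global, so binned identities
    # track the population's true divergence instead of a trimmed core
    nt = NucleotideSearcher(
        ref, ScoringScheme.nucleotide(match=5, mismatch=-4, gap_open=10, gap_extend=6)
    )
    hits = []
    for r in reads:
        hits.extend(nt.search(r))
    write_hits_tabular(hits, d / "reads_vs_ref.tsv")

    contig_db = TranslatedDatabase(contigs)
    hits = [h for p in ref_prots for h in contig_db.search(p)]
    write_hits_tabular(hits, d / "refprot_vs_contigs.tsv")

    singlet_db = TranslatedDatabase(singlets)
    hits = [h for p in ref_prots for h in singlet_db.search(p)]
    write_hits_tabular(hits, d / "refprot_vs_singlets.tsv")

    read_db = TranslatedDatabase(reads)
    hits = [h for p in tpase for h in read_db.search(p)]
    for p in tpase:
        hits.extend(contig_db.search(p))
    write_hits_tabular(hits, d / "tpase_hits.tsv")

    prot_db = ProteinDatabase(ref_prots)
    hits = [h for p in contig_prots for h in prot_db.search(p)]
    write_hits_tabular(hits, d / "contigorf_vs_refprot.tsv")

    foreign_db = ProteinDatabase(foreign)
    hits = [h for p in contig_prots for h in foreign_db.search(p)]
    write_hits_tabular(hits, d / "contigorf_vs_foreign.tsv")
    return [
        "reads_vs_ref.tsv", "refprot_vs_contigs.tsv", "refprot_vs_singlets.tsv",
        "tpase_hits.tsv", "contigorf_vs_refprot.tsv", "contigorf_vs_foreign.tsv",
    ]


def _stage_recruit(d: Path, config: SimConfig) -> list[str]:
    ref = read_fasta(d / "ref.fasta")[0]
    reads = read_fasta(d / "reads.fasta")
    hits = read_hits_tabular(d / "reads_vs_ref.tsv")
    profile = recruit(
        hits,
        reference_length=len(ref.sequence),
        n_reads_total=len(reads),
        read_ids={r.id for r in reads},
    )
    write_profile(profile, d / "recruitment.tsv")
    with open(d / "recruitment_summary.tsv", "w", newline="\n") as fh:
        lo, hi = profile.modal_bin
        fh.write("recruited_percent\tmodal_bin_low\tmodal_bin_high\n")
        fh.write(f"{recruited_fraction(profile):.1f}\t{lo:g}\t{hi:g}\n")
    return ["recruitment.tsv", "recruitment_summary.tsv"]


def _stage_contigstats(d: Path, config: SimConfig) -> list[str]:
    contigs = read_fasta(d / "contigs.fasta")
    membership = read_membership(d / "membership.tsv")
    hits = read_hits_tabular(d / "refprot_vs_contigs.tsv")
    stats = contig_table(contigs, membership, hits)
    write_contig_table(stats, d / "contig_stats.tsv")
    counts = size_filter_report(stats)
    with open(d / "contig_size_report.tsv", "w", newline="\n") as fh:
        fh.write("threshold_bp\tn_contigs_above\n")
        for t, n in counts.items():
            fh.write(f"{t}\t{n}\n")
    return ["contig_stats.tsv", "contig_size_report.tsv"]


def _load_anchor_inputs(d: Path):
    q_orfs = _orfs_with_translations(d / "contig_orfs.tsv", d / "contig_orfs.faa")
    r_orfs = _orfs_with_translations(d / "ref.orfs.tsv", d / "ref.proteins.faa")
    hits = read_hits_tabular(d / "contigorf_vs_refprot.tsv")
    return q_orfs, r_orfs, hits


def _stage_synteny(d: Path, config: SimConfig) -> list[str]:
    q_orfs, r_orfs, hits = _load_anchor_inputs(d)
    anchors, unanchored = anchor_orfs(q_orfs, r_orfs, hits)
    blocks, breaks, singletons = build_blocks(anchors)
    fusions = call_fusions(anchors, hits, r_orfs, q_orfs)
    membership = read_membership(d / "membership.tsv")
    sec = read_hits_tabular(d / "contigorf_vs_foreign.tsv")
    discordant = flag_discordant_orfs(anchors, q_orfs, sec, membership)

    with open(d / "synteny_blocks.tsv", "w", newline="\n") as fh:
        fh.write("contig_id\tsense\tn_anchors\tref_start\tref_end\tquery_start\tquery_end\n")
        for b in blocks:
            rs, re_ = b.reference_span
            qs, qe = b.query_span
            fh.write(f"{b.contig_id}\t{b.sense}\t{len(b.anchors)}\t{rs}\t{re_}\t{qs}\t{qe}\n")
    with open(d / "synteny_breaks.tsv", "w", newline="\n") as fh:
        fh.write("contig_id\tkind\tref_distance\tleft_ref\tright_ref\n")
        for br in breaks:
            fh.write(
                f"{br.contig_id}\t{br.kind}\t{br.reference_distance}"
                f"\t{br.left.reference_orf.locus_tag}\t{br.right.reference_orf.locus_tag}\n"
            )
    with open(d / "fusions.tsv", "w", newline="\n") as fh:
        fh.write("reference_orf\tquery_orf_1\tquery_orf_2\tcov1\tcov2\toverlap_res\n")
        for f in fusions:
            q1, q2 = f.query_orf_pair
            fh.write(
                f"{f.reference_orf.locus_tag}\t{q1.locus_tag}\t{q2.locus_tag}"
                f"\t{f.coverage_each[0]}\t{f.coverage_each[1]}\t{f.overlap_residues}\n"
            )
    with open(d / "discordant_orfs.tsv", "w", newline="\n") as fh:
        fh.write("contig_id\tlocus_tag\treason\tn_spanning_reads\tassembly_supported\n")
        for fl in discordant:
            n = "-" if fl.n_spanning_reads is None else fl.n_spanning_reads
            s = "-" if fl.assembly_supported is None else int(fl.assembly_supported)
            fh.write(f"{fl.orf.contig_id}\t{fl.orf.locus_tag}\t{fl.reason}\t{n}\t{s}\n")
    return ["synteny_blocks.tsv", "synteny_breaks.tsv", "fusions.tsv", "discordant_orfs.tsv"]


def _stage_prophage(d: Path, config: SimConfig) -> list[str]:
    q_orfs, r_orfs, hits = _load_anchor_inputs(d)
    anchors, _ = anchor_orfs(q_orfs, r_orfs, hits)
    elements = []
    with open(d / "elements.tsv") as fh:
        for line in fh:
            if line.startswith("name\t") or not line.strip():
                continue
            name, s, e = line.rstrip("\n").split("\t")
            elements.append((int(s) - 1, int(e)))
    refseq = read_fasta(d / "ref.fasta")[0].sequence
    contigs = {c.id: c.sequence for c in read_fasta(d / "contigs.fasta")}
    calls = find_insertions(anchors, element_annotations=elements or None)
    out = []
    for call in calls:
        qseq = contigs.get(call.contig_id, "")
        out.append(repeat_test(call, refseq, qseq) if qseq else call)
    with open(d / "prophage_calls.tsv", "w", newline="\n") as fh:
        fh.write(
            "element_start\telement_end\tcontig_id\tverdict\trepeat_len"
            "\trepeat_identity\trepeat_ref_start\trepeat_ref_end\trepeat_in_query\n"
        )
        for c in out:
            r = c.repeat_in_reference
            fh.write(
                f"{c.element_start + 1}\t{c.element_end}\t{c.contig_id or '-'}\t{c.verdict}"
                f"\t{r.length if r else '-'}\t{r.percent_identity if r else '-'}"
                f"\t{r.start if r else '-'}\t{r.end if r else '-'}"
                f"\t{int(c.repeat_in_query is not None)}\n"
            )
    return ["prophage_calls.tsv"]


def _stage_telink(d: Path, config: SimConfig) -> list[str]:
    membership = read_membership(d / "membership.tsv")
    reads = read_fasta(d / "reads.fasta")
    pairs, _ = pair_reads([r.id for r in reads])
    tp_hits = read_hits_tabular(d / "tpase_hits.tsv")
    flagged = classify_transposase_sequences(tp_hits)
    contigs = read_fasta(d / "contigs.fasta")
    stat_hits = read_hits_tabular(d / "refprot_vs_contigs.tsv")
    stats = contig_table(contigs, membership, stat_hits)
    report = link_contigs(membership, pairs, flagged, stats)
    write_linkage_report(report, d / "linkage.tsv")
    with open(d / "linkage_summary.tsv", "w", newline="\n") as fh:
        fh.write("n_large\tn_linked\tlinked_read_percent\tdensity_kb\n")
        if report.n_linked_contigs:
            density, _ = density_estimate(report)
        else:
            density = "-"
        pct = report.linked_read_percent if report.n_member_reads_total else "-"
        fh.write(f"{report.n_large_contigs}\t{report.n_linked_contigs}\t{pct}\t{density}\n")
    return ["linkage.tsv", "linkage_summary.tsv"]


def _stage_census(d: Path, config: SimConfig) -> list[str]:
    ref_prots = read_fasta(d / "ref.proteins.faa")
    annotations = read_annotations(d / "ref.annotations.tsv")
    hc = read_hits_tabular(d / "refprot_vs_contigs.tsv")
    hs = read_hits_tabular(d / "refprot_vs_singlets.tsv")
    rows = census(ref_prots, hc, hs, annotations)
    counts = tier_counts(rows)
    validate_tier_nesting(counts)
    write_census(rows, d / "census.tsv")
    report = missing_gene_report(rows, annotations)
    with open(d / "missing_genes.tsv", "w", newline="\n") as fh:
        fh.write(f"# missing={report.n_missing} hypothetical={report.n_hypothetical}\n")
        fh.write("locus_tag\tproduct\n")
        for locus in report.missing:
            fh.write(f"{locus}\t{annotations.get(locus, '')}\n")
    with open(d / "census_summary.tsv", "w", newline="\n") as fh:
        fh.write("tier\tcount\n")
        for k, v in counts.items():
            fh.write(f"{k}\t{v}\n")
    return ["census.tsv", "missing_genes.tsv", "census_summary.tsv"]


STAGES: list[tuple[str, Callable[[Path, SimConfig], list[str]]]] = [
    ("simulate", _stage_simulate),
    ("orfs", _stage_orfs),
    ("search", _stage_search),
    ("recruit", _stage_recruit),
    ("contigstats", _stage_contigstats),
    ("synteny", _stage_synteny),
    ("prophage", _stage_prophage),
    ("telink", _stage_telink),
    ("census", _stage_census),
]


def run_pipeline(config: SimConfig, outdir: str | Path, force: bool = False) -> Path:
    """Run (or resume) all pipeline stages in ``outdir``.

    Stages whose parameters and output checksums match the manifest are
    skipped; any invalidated stage also invalidates everything after it.
    Returns the run directory.
    """
    d = Path(outdir)
    d.mkdir(parents=True, exist_ok=True)
    manifest_path = d / "manifest.json"
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    if manifest_path.exists() and not force:
        try:
            manifest = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            logger.warning("manifest unreadable; recomputing all stages")
            manifest = {"version": __version__, "seed": config.seed, "stages": {}}
    phash = _params_hash(config)

    invalidated = force
    for name, fn in STAGES:
        entry = manifest.get("stages", {}).get(name)
        valid = (
            not invalidated
            and entry is not None
            and entry.get("params") == phash
            and all(
                (d / f).exists() and _sha256(d / f) == sha
                for f, sha in entry.get("outputs", {}).items()
            )
        )
        if valid:
            logger.info("stage %s: up to date, skipped", name)
            continue
        invalidated = True
        logger.info("stage %s: running", name)
        try:
            outputs = fn(d, config)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest.setdefault("stages", {})[name] = {
            "params": phash,
            "outputs": {f: _sha256(d / f) for f in outputs},
        }
        # drop stale entries for downstream stages
        later = [n for n, _ in STAGES[[s[0] for s in STAGES].index(name) + 1 :]]
        for n in later:
            manifest["stages"].pop(n, None)
        manifest["version"] = __version__
        manifest["seed"] = config.seed
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return d
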