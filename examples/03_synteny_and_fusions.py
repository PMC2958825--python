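"""Synteny blocks, rearrangement breaks, and gene-fusion calls.

Anchors the diverged lineage's ORFs onto the reference by best protein hit,
walks them into collinear blocks, and reports where the planted
translocation breaks synteny and where one reference ORF corresponds to two
adjacent query ORFs (a fusion event relative to the query lineage).
"""

from thiocomp.homology_search import ProteinDatabase
from thiocomp.simulate import SimConfig, TranslocationSpec, ProphageSpec, simulate_all
from thiocomp.synteny_fusion import anchor_orfs, build_blocks, call_fusions

config = SimConfig(
    seed=5,
    genome_length=50_000,
    n_orfs=26,
    translocation=TranslocationSpec(region_a=(5_000, 10_000), region_b=(30_000, 35_000)),
    prophage=ProphageSpec(length_bp=3_000, insertion_site=44_000, n_orfs=3),
    coverage_target=3.0,
)
res = simulate_all(config)

# protein-protein search of query ORFs against the reference annotation
db = ProteinDatabase(res.reference.protein_records())
hits = [h for p in res.query.protein_records() if p.sequence for h in db.search(p)]
anchors, unanchored = anchor_orfs(res.query.orfs, res.reference.orfs, hits)
print(f"{len(anchors)} anchors, {len(unanchored)} query ORFs without a reference homolog")

blocks, breaks, singles = build_blocks(anchors)
print(f"\n{len(blocks)} synteny blocks:")
for b in blocks:
    rs, re_ = b.reference_span
    print(f"  {b.sense:9s} {len(b.anchors):3d} anchors  ref {rs}-{re_}")
print(f"{len(breaks)} breaks:")
for br in breaks:
    print(f"  {br.kind}: {br.reference_distance} bp between "
          f"{br.left.reference_orf.locus_tag} and {br.right.reference_orf.locus_tag}")
planted_gap = res.ledger.one("translocation").note.split(";")[0]
print(f"  (planted translocation {planted_gap})")

fusions = call_fusions(anchors, hits, res.reference.orfs, res.query.orfs)
print(f"\n{len(fusions)} fusion calls (planted: {len(res.ledger.of_kind('fusion'))}):")
for f in fusions:
    q1, q2 = f.query_orf_pair
    print(f"  {f.reference_orf.locus_tag} = {q1.locus_tag} + {q2.locus_tag} "
          f"(covering {f.coverage_each[0]:.0%} and {f.coverage_each[1]:.0%}, "
          f"span overlap {f.overlap_residues} aa)")
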