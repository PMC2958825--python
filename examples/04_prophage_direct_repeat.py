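"""Prophage-insertion polarity from flanking direct repeats.

The reference genome carries an integrated prophage whose insertion
duplicated a 26 bp target sequence.  The diverged lineage has the genes on
both sides of the prophage adjacent to each other, with no prophage and no
repeat copy between them -- which dates the insertion to after the two
lineages diverged (had the element been deleted, the repeat would remain).
"""

from thiocomp.homology_search import ProteinDatabase
from thiocomp.prophage_indel import find_insertions, repeat_test
from thiocomp.simulate import SimConfig, TranslocationSpec, ProphageSpec, simulate_all
from thiocomp.synteny_fusion import anchor_orfs

config = SimConfig(
    seed=8,
    genome_length=40_000,
    n_orfs=20,
    translocation=None,
    prophage=ProphageSpec(length_bp=4_000, insertion_site=20_000),
    n_transposase_copies=2,
    n_foreign_orfs=0,
    coverage_target=3.0,
)
res = simulate_all(config)

db = ProteinDatabase(res.reference.protein_records())
hits = [h for p in res.query.protein_records() if p.sequence for h in db.search(p)]
anchors, _ = anchor_orfs(res.query.orfs, res.reference.orfs, hits)

es, ee, repeat_len = res.reference.prophage
(call,) = find_insertions(anchors, element_annotations=[(es, ee)])
call = repeat_test(call, res.reference.sequence, res.query.sequence)

r = call.repeat_in_reference
print(f"annotated element: reference {es + 1}-{ee} ({ee - es} bp)")
print(f"flanking anchors adjacent on the query at position {call.query_junction}")
print(f"direct repeat in reference: {r.length} bp at {r.start}-{r.end} and "
      f"{r.partner_start}-{r.partner_end} ({r.percent_identity:.0f}% identity)")
print(f"repeat at the query junction: {call.repeat_in_query is not None}")
print(f"verdict: {call.verdict}")
print("\n(no repeat at the junction means the element inserted into the")
print(" reference lineage after divergence, rather than being lost by the query)")
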