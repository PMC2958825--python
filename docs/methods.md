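# Methods

This note documents the models, algorithms and numerical choices behind
`thiocomp`, in the spirit of a methods section: what each component assumes,
which parameters matter, and what the synthetic studies do and do not show
about real data.

## The comparative setting

The package targets one recurring situation in comparative metagenomics: a
shotgun dataset dominated by a single population that is moderately diverged
(~60–75% nucleotide identity) from a finished reference genome. At that
distance most genes remain confidently alignable in protein space while the
two genomes differ by rearrangements, gene fusions, mobile-element load and
lineage-specific insertions — exactly the events the toolkit detects. All
internal coordinates are 0-based half-open; all human-facing reports are
1-based inclusive (the GenBank convention).

## Homology search

The built-in aligner exists so the pipeline runs with no external
dependency; every stage nevertheless consumes plain tabular hits, so any
aligner emitting the standard 12/13-column dialect can substitute, in which
case downstream statistics inherit that tool's E-values.

**Algorithm.** Exact-word seeds (default word size 11 nt, 3 aa) are grouped
into clusters of nearby diagonals (band 16) per database entry. Amino-acid
modes additionally require two seed words on one exact diagonal before a
cluster counts — a word of three residues alone is unspecific. Each cluster
must pass an ungapped best-segment filter (Kadane's maximum-sum segment on
each seeded diagonal): nucleotide clusters must beat a bare seed's score by
four further matches, protein clusters must reach 40 raw score. Surviving
clusters get a *full* affine-gap Smith–Waterman restricted to the subject
window spanning the cluster's diagonals plus the query projection and 100 bp
of padding, so the only losses relative to an unrestricted alignment are
seed sensitivity and the window bounds. On random pairs up to 2 kb the top
seeded score equals the unrestricted Smith–Waterman score in ≥95% of trials
(measured 96–99.5% at word size 5 across seeds; the acceptance script
reports the realized value).

The Smith–Waterman engine is row-vectorized numpy: vertical gap scores are
an elementwise recurrence, and the horizontal-gap recurrence is solved per
row with a running prefix maximum, which is exact for affine costs because
a gap that extends another gap in the same direction never beats the single
longer gap containing it. Traceback re-derives gap runs from the score
matrix by testing whole-run costs.

**Scoring and statistics.** Gapped Karlin–Altschul parameters come from a
versioned constants table of published values per scheme: nucleotide
+1/−2 (λ=1.28, K=0.46), +1/−3 (1.37, 0.711), +2/−3 with gaps 5/2
(0.550, 0.210; the package default), +5/−4 with gaps 10/6 (0.163, 0.068),
and BLOSUM62 with gaps 11/1 (0.267, 0.041). Schemes without tabulated
constants require explicit λ/K. The effective search space is the raw
`m × n` product with no length correction; this shifts absolute E-values
slightly but preserves orderings, and every threshold used downstream is an
order-of-magnitude tier. Percent identity is computed over all alignment
columns, gaps included, matching tabular-output convention.

**Scheme choices by stage.** Read recruitment uses +5/−4: at ~70% identity
its expected score per column (+2.3) keeps alignments essentially global
over the homologous span, so the binned identity tracks the population's
true divergence instead of a trimmed high-identity core (under +2/−3 the
end-trimming bias inflates reported identity by ~3 points). The direct-
repeat search uses +1/−3, under which a single-mismatch extension is
strictly unprofitable, so an exact planted repeat is recovered at its exact
boundaries while 80–90%-identity repeats still score positively (E-values
are not used there). Everything else uses the +2/−3 default.

## Fragment recruitment

One best hit per read (lowest E, ties to highest bit score) — binning reads
rather than HSPs avoids double-counting coverage when a read yields several
local alignments. Alignments must be strictly longer than 500 bp. Bins are
1 percentage point wide over [50, 100], with 100% in the top bin; bin
coverage is the bin's aligned bp divided by the reference length. The
recruited fraction is recruited reads over the full read manifest.

## Contig characterization

Coverage is assembly-based — total member-read bp divided by contig
length — not alignment depth, because read membership is what an assembler
reports. Raw (untrimmed) read lengths are used. Best-hit classes use strict
"better than" thresholds at 10⁻¹⁰⁰, 10⁻⁵⁰, 10⁻¹⁰; size filters are strict
(">7 kb" excludes 7000).

## Synteny, breaks, fusions, discordant ORFs

Anchoring is directional best-hit (not reciprocal-best), E ≤ 10⁻⁵; ties
break by bit score, then lowest reference coordinate. Within a block,
consecutive anchors must advance along the reference by at most 20 kb
(configurable) in the direction set by the block's sense; colinear blocks
walk the reference forward, inverted blocks backward. A zero reference
advance — two query ORFs on one reference ORF, as a fusion produces —
continues the block. A larger jump, a reversal, or a sense flip closes the
block and records a break carrying the reference distance between the
flanking anchors; blocks need at least two anchors and leftovers are
reported as singletons. The 20 kb default tolerates local indels while
sitting far below the tens-of-kb rearrangements of interest; there is no
natural threshold separating "syntenic" from "rearranged", which is why it
is a parameter.

A fusion call requires two query ORFs adjacent in coordinate order on one
contig and on the same strand, each covering ≥25% of one reference protein,
with covered spans overlapping ≤30 residues and ordered consistently with
the strand. Discordant-ORF flags require both a missing anchor (or a better
hit against a supplied "other taxa" protein set) and strand discordance
with every neighbouring ORF; with read membership supplied, each flag
counts reads overlapping both the flagged ORF and an anchored neighbour by
≥100 bp (≥3 such reads marks the arrangement assembly-supported, i.e. not
an artifact of mis-joined contigs).

## Insertion detection and repeat polarity

Candidate elements come from an annotation or, de novo, from reference gaps
≥5 kb between anchors adjacent on the query (query gap ≤2 kb). A valid call
needs flanking anchors on one contig with no anchor inside the element. The
repeat test locally aligns the two reference boundary windows (±500 bp)
against each other; a ≥20 bp, ≥80%-identity alignment is the direct-repeat
pair. The query junction window is then searched for a copy. The verdict is
a pure function of the two outcomes: reference repeat present and query
copy absent ⇒ inserted after divergence; query copy present ⇒ deleted from
the query; no reference repeat ⇒ indeterminate. The window and thresholds
are configurable because real target-site repeats vary in length and decay.

## Transposase linkage

A read or contig is transposase-positive when any translated hit from the
transposase protein set reaches E ≤ 10⁻¹⁰ (the criterion for a read
"containing" a transposase is a documented default, not derivable from
first principles). For contigs strictly longer than 10 kb, a member read is
linked when its clone mate is transposase-positive; mates inside the same
large contig still count (switchable), and a contig that itself encodes a
transposase can additionally be linked — both facts are reported
independently. The density estimate conservatively assumes one element per
linked contig: summed linked-contig length over linked-contig count,
reported in kb both rounded and raw, alongside the reference genome's
annotated-transposase spacing.

## Homolog census

One row per reference protein with its best contig hit and best singlet
(unassembled read) hit kept separate, then merged for the tier. Tiers are
cumulative — a 10⁻¹⁰⁰ hit counts at 10⁻⁵⁰ and 10⁻¹⁰ too — so the counts
nest monotonically and the tier-none count is exactly total minus the
loosest tier. "Better than" is strict less-than throughout. The missing-
gene report lists tier-none proteins, counts those annotated hypothetical,
and groups the remainder by product name.

## The synthetic study generator

The generator emulates the study design the analyses target, with defaults
chosen to match that setting: a 150 kb reference at 43% GC with 80
annotated ORFs (300–2400 bp, both strands, ATG starts, no internal stops)
plus a 6 kb prophage carrying 5 ORFs and a duplicated 26 bp target repeat;
a query lineage at 30% nucleotide divergence drifted to 38% GC, with the
prophage and *both* repeat copies absent (the query shows the pre-insertion
state), one translocation joining two regions 50 kb apart, two fusions
(one reference ORF split into two adjacent query ORFs at its middle codon),
ten identical intergenic transposase copies (960 bp) and three
reverse-orientation foreign ORFs placed between forward-strand neighbours;
Sanger-style paired reads (length ~N(755, 50), insert ~N(3000, 300) — a
conventional plasmid-library insert size, exposed as a parameter) at 6×
coverage; and window-based contig fixtures. Assembly is simulated, not
performed: contigs are genome windows, which keeps read membership and
event coordinates exact. Large (11–15 kb) windows are centred on the
planted events, echoing the real situation where the informative loci sit
on the largest contigs; ~30 small windows (0.6–2.2 kb) fill in elsewhere,
leaving roughly half the reads unassembled.

**Divergence engine.** Substitutions are codon-aware: synonymous third
positions mutate at three times the nonsynonymous rate (configurable), so
~70% nucleotide identity coexists with per-protein amino-acid identities of
roughly 0.6–0.95. Start and stop codons are never touched and no
substitution creates or destroys a stop. Substituted bases are drawn from a
composition solved so the genome lands on its GC target, with synonymous
AT→GC flips damped (two-fold degenerate sites always change base class,
which would otherwise push an AT-rich genome's GC upward). The realized
rate is then pinned per stratum — coding via added or reverted synonymous
third-position changes (protein sequences untouched), intergenic via plain
top-up — so divergence is spatially uniform; without the stratified
calibration, coding-dense reads would recruit ~2–3 identity points above
the planted rate. Finally a divergence-preserving swap pass re-draws
already-substituted bases between base classes (never matching the
ancestral base) until GC sits within one base of target. Both GC targets
and the substitution rate are therefore recovered to well within binomial
sampling error by construction; the tests verify it.

Randomness uses numpy Generator streams keyed by `(stage, seed)` — one
documented stream per stage rather than a single global stream, so each
stage is individually reproducible; the seed is recorded in the ledger
header and the same configuration yields byte-identical outputs.

**Truth ledger.** Every planted event is one record (kind, reference and
query coordinates, strand, quantitative ground truth such as the realized
substitution rate or per-ORF amino-acid identity), written as TSV with
0-based half-open coordinates and read back losslessly. Detector tests are
scored against it: fusion recall/precision against the planted loci,
repeat recovery against exact coordinates, linkage recall against contigs
whose member reads' mates genuinely overlap a planted copy by ≥150 bp.

**What the simulation does not model.** Sequencing error, quality values,
chimeric clones, within-population heterogeneity, real assembly artifacts,
rate variation among genes, and compositional structure beyond a single GC
target. Passing the recovery tests therefore shows the detectors are
correct and calibrated under clean planted truth, not that they are robust
to every artifact of real shotgun data; on real data the external-aligner
entry points and configurable thresholds are the knobs that matter.

## ORF calling

The bundled ORF finder reports maximal ATG-to-stop spans ≥300 bp on both
strands (standard genetic code, M only for ATG, no coding-statistics
model), resolving same-strand overlaps by keeping the longer call. Gene
calls only anchor comparisons here; a trained bacterial gene finder would
change boundaries slightly but not the anchoring, since anchors are
best-protein-hit based.

## Pipeline sizes and runtime

The default study (150 kb genome, ~1240 reads at 6×) runs the full pipeline
in about two minutes on one CPU, dominated by the read-vs-reference and
protein-vs-six-frame searches; the test suite's reduced study (45 kb, ~250
reads) exercises the same event menu in under a second. Stage outputs are
checksummed into `manifest.json`; re-runs skip valid stages and a corrupted
artifact invalidates its stage and all later ones.
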