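# Methods

This note documents the models and procedures implemented in
`contamscreen`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic fixtures do and do
not demonstrate.

## h-mer hashing

A reference h-mer is computed from a 56-bp window: positions `i` with
`i mod 3 == 2` (the wobble frame of each strand's own 5'→3' reading) are
dropped, the 38 retained bases are encoded 1 bit each (A,G → 0; C,T → 1),
and the packed value is mixed through a splitmix64-style finalizer
(constants `0xBF58476D1CE4E5B9`, `0x94D049BB133111EB`, pinned in
`hashing.py`) truncated to 38 bits. The canonical key is the minimum of
the forward and reverse-complement hashes; on a tie the forward
orientation wins and the node is stored once with positive sign. Because
56 ≡ 2 (mod 3), the reverse complement's own wobble frame drops exactly
the same physical base set as the forward frame, which is what makes the
key invariant to *any* substitution at a wobble position as well as to
transitions at retained positions. The mixing function is an
implementation choice — any good 64-bit finalizer works — but it is part
of the on-disk format and must never change silently.

Query-side refinement uses the same construction over 30-bp windows
(20 retained bits).

Non-ACGT bases (ambiguity codes, remnant Ns shorter than the contig-split
threshold) are replaced by pseudorandom bases derived deterministically
from the sequence id and position, so database rebuilds are bit-identical.
Filled positions are flagged and never count toward 100%-identity
segments: they behave as mismatches during scoring.

## Index layout

Nodes are 9 bytes: 1-byte lower subkey (low 8 key bits), 4-byte subject
ordinal, 4-byte signed position. The position stores `sign × (start + 1)`;
the +1 bias keeps the orientation sign meaningful for windows starting at
position 0 (`start = |position| − 1` everywhere). Buckets are addressed by
an explicit offsets array of `2^upper_bits + 1` entries. The key type
always splits 30/8, but the library default is `upper_bits = 20`: a
`2^30`-entry table costs gigabytes of static overhead, which is
pointless for databases of a few megabases. With `upper_bits < 30` the
index discriminates on `upper_bits + 8` key bits; at the scales this
package targets (≤ tens of millions of nodes in a 28-bit effective key
space) cross-key collisions are vanishingly rare and at worst contribute a
few extra pass-1 seeds, which the noise filter removes. Databases needing
full 38-bit discrimination can be built with `upper_bits = 30` unchanged.

Strides: 10 bp for prokaryote, virus, and synthetic references, 20 bp for
eukaryote references (chosen per sequence from its kingdom; covers all
reading frames in both cases).

## Alignment

Pass 1 samples the query every base (`query_stride = 1`), so any database
window sampled at stride 10/20 on the subject can seed. Seeds keep only
close-neighbour pairs: `|Δ(q−s)| ≤ 1 kbp` and `|Δ(q+s)| ≤ 10 kbp`, with
subject positions signed by relative orientation so both inequalities
apply to either strand. The filter bins seeds on a
(diagonal ÷ 1 kbp, antidiagonal ÷ 10 kbp) grid per subject: two seeds in
one cell satisfy both bounds by construction; singleton cells check their
eight neighbours. Surviving same-diagonal seeds within 1 kbp merge into
ungapped runs (the merge radius is an implementation choice; the run list
is then reduced per taxon to the best non-overlapping runs by length).
Four per-taxon metrics — run count, maximum length, summed length, summed
squared length — rank taxa, and the union of the top three under each
metric (≤ 12 taxa) proceeds. "Summed squared length" is read as Σ lᵢ²,
consistent with the score definition below.

Pass 2 indexes each 100-kbp query chunk with 20-bit h-mers at stride 1 and
scans subject neighbourhoods of `min(100 kbp, 2 × chunk length)` around
the pass-1 loci. Seeds on one diagonal within 60 bp chain into groups;
groups need ≥ 2 seeds to anchor an extension (a lone 20-bit match in a
large neighbourhood is usually a hash collision). Ungapped extension is
x-drop with match +1, mismatch −2, drop-off 20. Gapped extension
repeatedly scans a ±25 bp indel band within 60 bp of the alignment end for
the continuation with the longest exact run (≥ 8 bp to count), extends it,
and stops when no significant segment results. A finished hit must span
≥ 30 bp and contain at least one 18-bp exact run — random seed chains
essentially never do, while genuine alignments at any divergence this
screen can use always do (at 15% divergence the expected maximal exact run
in a kilobase-scale alignment is ~30 bp).

Score: `sqrt(Σ lᵢ²)` over 100%-identity segment lengths. The L2 form is
strictly subadditive under splitting, so clustered mismatches lower the
score relative to the same matches unbroken.

Chunks overlap by 100 bp; hits from adjacent chunks with compatible
diagonals are merged, dropping segments inside the already-covered range
so overlap bases are not double-counted.

## Masking

Low complexity: a 50-bp window slides 1 bp at a time; its 45 overlapping
hexamers give a Shannon entropy in bits, and windows under 4.5 bits merge
into mask intervals. Sequences shorter than one window are evaluated as a
single window when they hold at least one hexamer.

Transposons (eukaryote queries only): h-mer counts are taken genome-wide
over contigs of length ≥ min(100 kbp, scaffold N80 before N-splitting), so
a genome consisting of many short similar sequences (e.g. a viral bloom)
contributes no statistics. Keys with count > max(10, 5 × the expected
count under uniform sampling) are flagged, and query positions covered by
flagged windows become transposon intervals. The cutoff is an
implementation default chosen to behave at both fixture and genome scale;
it is configurable.

Masked windows are excluded from seeding (by window midpoint), but
extension crosses masked regions freely — mirroring standard masker
practice — and per-division masked fractions feed the classifier.

## Classification

Per sequence, hits aggregate per species (coverage = union of query
intervals; score = L2 over all identity segments) and species are reported
up to 4 per sequence and 2 per division; per-division aggregates always
use all hits, the caps govern reporting only. Conserved intervals —
positions covered by ≥ 5 distinct divisions — are computed for eukaryote
queries only.

Genome-wide, a division's aggregate uses only (sequence, division)
alignments with score ≥ 150 and coverage > 80% of the sequence, and is
flagged as a contamination source when all four criteria hold (< 75%
low-complexity/conserved, < 75% transposon, > 10 kbp non-repetitive,
< 75% overlap with the declared division).

The inferred primary set starts from the top-coverage division: divisions
of the same kingdom whose alignments overlap it above
`max(0.5, 0.75 × aggregate coverage)` join. The linear scaling is a
design choice realizing "concordance relaxes for poorly covered genomes";
only the 0.75 ceiling is externally fixed. If the declared division is
absent from the inferred set but well represented in the database
(defaults at desk scale: ≥ 1 sequence and ≥ 50 kbp), the inferred
divisions are reported as contaminants and a wrong-taxid warning is
emitted; if the declared division is poorly represented, the inferred set
is trusted.

Per-sequence calls: flagged divisions need score > 50, or inter-kingdom
coverage ≥ 80%; unflagged divisions need score > 100 and repeat/conserved
content < 50% of their aligned bases. Every call must clear
`max(0.2, 0.6 × (1 − aggregate coverage))` — applied to whole-sequence
coverage for whole-sequence calls and to within-span coverage for chimeric
spans (applying the cutoff to a 1-kbp span's share of a 100-kbp chimera
would make chimera detection impossible, so the span is the denominator).
A sequence with < 1 kbp of primary-division anchor is treated as wholly
contaminant; otherwise contaminant intervals (joined across ≤ 1 kbp gaps)
minus primary intervals form chimeric spans. Primary slivers under 100 bp
(shared-repeat remnants) do not carve spans. Flagged-division sequences
that meet the score rule but miss the coverage cutoff surface as REVIEW.

Actions: whole-sequence → EXCLUDE; inter-kingdom chimeric spans → TRIM
when the span reaches within 100 bp of a sequence end, FIX otherwise;
chimeras from configured lateral-gene-transfer source divisions
(endosymbiont-like; default `prok:a-proteobacteria`) → INFO; intra-kingdom
chimeras ≥ 10 kbp → REVIEW (smaller ones are not reported);
prokaryote-in-prokaryote corrective calls totalling ≤ 1% of the genome are
demoted to REVIEW_RARE. Virus calls: in eukaryote queries only
whole-virus sequences are cleaned and chimeric viral spans are ignored;
in prokaryote queries all viral elements are ignored; virus queries report
cross-superkingdom viral hits and all non-viral contaminants.

For direct host–contaminant fusions (no intervening contig break) the
junction base attribution jitters by a few bases, because ungapped
extension may carry a handful of coincidentally matching bases across the
junction. Spans measured against the 10-kbp reporting threshold are
therefore exact when chimera parts are separated by a contig break (the
common real-world case — chimeras form at contig boundaries) and accurate
to a few bases otherwise.

## Synthetic fixtures

The generator emulates: random ancestral genomes per species (order-0
composition, GC 0.45), strains diverged by 2% substitutions
(transition:transversion 2:1, so h-mer transition tolerance is genuinely
exercised) plus rare short indels (5 × 10⁻⁴/site, geometric mean 3 bp),
sibling species at 10% divergence for novel-species drop-out experiments,
two 2-kbp conserved elements planted identically across all eukaryote
species (≥ 5 divisions cover them, driving the conserved-interval logic),
and a 3-kbp transposon-like family at 30 copies per eukaryote genome with
2% inter-copy divergence (driving overrepresented-h-mer masking). Default
genome sizes are 150 kbp (prokaryote), 300 kbp (eukaryote), 20 kbp
(virus) — deliberately desk-scale so a full screen takes seconds; the
pipeline itself is size-oblivious. Query sets: size-selected fragments
(1/10/100 kbp), mixtures (5% contamination by length in 1-kbp pieces), and
chimeras (100-kbp host + 1-kbp contaminant, optionally separated by
10 Ns), each with truth labels.

What the fixtures do **not** emulate: real coding/non-coding structure
(h-mer wobble tolerance helps most in coding sequence; random genomes
understate that advantage), genome-scale repeat landscapes, GC
heterogeneity, sequencing error, or assembler artifacts. Passing tests
demonstrate the machinery — indexing, alignment, masking, thresholds,
actions — behaves exactly as specified on controlled inputs; they do not
certify sensitivity/specificity on real genomes, which depends on database
breadth above all.

Sensitivity/specificity are scored exactly as defined for the screen:
sensitivity = % of contaminant sequences receiving a corrective action
(EXCLUDE/TRIM/FIX) with the source genome's division (prokaryote-virus
counts as a true positive for prokaryote sources); specificity subtracts
sequences with corrective *or* REVIEW actions from the clean total.
Length-based sequence-level bounds treat same-kingdom calls (upper) or all
calls (lower) as false positives.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally; the action report is
  1-based inclusive.
- All tie-breaks are pinned (taxid ascending after score descending;
  metric value then taxid in taxa selection; smallest indel on equal
  continuation runs), so identical inputs produce byte-identical reports.
- Empty inputs degrade cleanly: an all-N scaffold yields no contigs; a
  sequence with zero alignments is inconclusive; an empty reference set is
  a valid database whose lookups are empty.
- A taxid absent from the taxonomy is a hard error raised before any
  alignment work, naming the offending sequence or input.
- FIX splits rename parts `<id>.1`, `<id>.2`, …; removed material is
  binned as `<id>:<start>-<end>`.

## Known limitations

- Contaminants are characterized at division level; no discrimination
  below that rank (e.g. within-family prokaryote contamination in
  multi-isolate or metagenomic data).
- Virus screening uses the conservative rules above and nothing more.
- The aligner is a correctness-first reimplementation: single-threaded,
  NumPy-vectorized, suitable for megabase-scale screens, and not tuned
  for terabase databases (no memory mapping, no parallel chunk workers).
- Pass-2 extension is heuristic; its identity segments agree with an
  optimal edit-distance alignment on ≥ 95% of short diverged fixtures
  (asserted in the test suite) but path-level equality is not guaranteed.
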