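# contamscreen

Desk-scale genome contamination screening: an h-mer-indexed cross-species
aligner plus a rule-based taxonomic classifier. Given an assembly FASTA and
a declared taxid, `contamscreen` identifies whole-sequence and chimeric
contaminants from foreign organisms, emits a TSV action report, and writes
a cleaned FASTA with the corrective actions applied.

It is intended for people who assemble genomes (or curate collections of
them) and want an automated, reproducible contaminant check: sequences from
host-associated bacteria in a eukaryote assembly, stray host scaffolds in a
parasite genome, cross-sample bleed-through, or chimeric contigs fused from
two organisms.

## How it works

**Index.** Reference sequences are indexed with *h-mers*: 56-bp windows in
which every third base (the codon wobble position for in-frame coding
sequence) is dropped and the remaining 38 bases are collapsed to a 1-bit
purine/pyrimidine alphabet, so transition substitutions and wobble changes
never alter the key. The packed 38 bits pass through a fixed
multiply-xorshift finalizer, and the canonical key is
`min(h(window), h(reverse_complement(window)))`, making keys
strand-invariant. Keys split into a 30-bit upper and 8-bit lower subkey;
the index is a sorted array of 9-byte nodes (lower subkey, subject ordinal,
signed position) located by a bucket-offsets table plus binary search.
h-mers are sampled every 10 bp from prokaryote references and every 20 bp
from eukaryote references.

**Alignment.** Screening runs in two passes. Pass 1 looks up every query
h-mer in the full index, removes isolated seeds (a seed survives only with
a neighbour within 1 kbp on the diagonal and 10 kbp on the antidiagonal),
merges survivors into ungapped runs, and keeps the taxa ranked top-3 under
any of four per-taxon metrics. Pass 2 re-indexes the query with smaller
20-bit h-mers and extends seeds in subject neighbourhoods around the pass-1
loci, ungapped first (x-drop) and then across indels. An alignment scores

```
score = sqrt( sum_i  l_i^2 )
```

over the lengths `l_i` of its 100%-identity segments, so clustered
mismatches (alignment artifacts, multi-nucleotide mutations) cost more than
the same number of mismatches spread thinly.

**Classification.** Hits aggregate per taxonomic division (e.g.
`anml:primates`, `prok:g-proteobacteria`) within eight kingdoms. A division
is a high-confidence contamination source only if, over alignments with
score ≥ 150 covering > 80% of their sequence: < 75% of its aligned regions
are low-complexity/conserved, < 75% are transposon-like repeats, > 10 kbp
is non-repetitive, and < 75% overlaps the declared division's alignments.
Individual sequences are then called with score thresholds (> 50 for
flagged divisions, > 100 with < 50% repeat content otherwise), a minimum
coverage cutoff `max(0.2, 0.6 × (1 − aggregate coverage))`, and
kingdom-aware rules: intra-kingdom chimeras under 10 kbp are ignored,
prokaryote-in-prokaryote contamination totalling ≤ 1% of the genome is
only flagged for review, and viral hits are treated conservatively. Actions
are `EXCLUDE` / `TRIM` / `FIX` (applied automatically when cleaning) and
`INFO` / `REVIEW` / `REVIEW_RARE` (reported, never auto-removed).

No reference downloads are required for development or testing: the
`simulate` module generates mock taxonomies, reference genomes, diverged
strains, fragment/mixture/chimera query sets with truth labels, and the
`evaluate` module scores sensitivity and specificity against them.

## Worked example

Simulate a reference world, build a database, screen a host genome carrying
5% bacterial contamination, and score the result:

```sh
contamscreen simulate --mode refset --out-dir refs --seed 5
contamscreen build-db refs/refs.fa --taxonomy refs/taxonomy.tsv \
    --seq-taxids refs/seq_taxids.tsv --out db/gx
contamscreen simulate --mode mixture --out-dir q --seed 5 \
    --host-taxid 1000003 --contaminant-taxid 1000000
contamscreen screen q/query.fa --tax-id 1000003 --db db/gx --out-dir out
contamscreen evaluate --report out/contam_report.tsv --truth q/truth.tsv \
    --fasta q/query.fa
```

This prints:

```
reference set: 11 genomes -> refs
database: 11 sequences, 151963 nodes -> db/gx.*
mixture query set: 10 sequences -> q
8 action records; 2 sequences kept, 8 binned -> out
{
  "sensitivity_percent": 100.0,
  "specificity_percent": 100.0,
  "n_contaminant_truth": 8,
  "n_clean_truth": 2,
  "true_positives": 8,
  "false_positives": 0,
  "action_counts": { "EXCLUDE": 8 }, ...
}
```

All eight 1-kbp bacterial fragments were excluded with the correct source
division and neither 100-kbp host sequence was touched. The report itself
is a plain TSV (1-based inclusive coordinates):

```
#seq_id              start_pos  end_pos  seq_len  action   div                    agg_cont_cov  top_tax_name
contam_1000000_11    1          1000     1000     EXCLUDE  prok:g-proteobacteria  100.0         Simulatus g-proteobacteria-1
```

`contamscreen clean` re-applies an existing report to a FASTA (optionally
dropping cleaned sequences under a length threshold, e.g. 1 kbp for
eukaryote assemblies), binning removed material into a separate file.

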