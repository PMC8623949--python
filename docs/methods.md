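# Methods

`cerealqtl` automates a comparative analysis of QTL-bearing chromosomal
regions across related cereal genomes: wheat insect-tolerance loci (stem
solidness against wheat stem sawfly; antibiosis and oviposition deterrence
against orange wheat blossom midge) and their homologous segments in other
wheat genotypes, barley, rye, rice and oat.  This note documents the
models, parameters and numerical choices behind each stage, what the
synthetic-data generator does and does not emulate, and the package's
known limitations.

## Marker projection and species-scaled filtering

QTL borders are defined by molecular markers (SNP-array probes and
similar, 60–200 nt).  Markers are aligned to each genome and hits are
retained when they cover at least 90% of the marker and exceed a percent
identity scaled to the evolutionary distance from wheat:

| species class | min identity (marker) | min coverage |
|---|---|---|
| wheat genotypes | 95% | 0.90 |
| barley / rye | 90% | 0.90 |
| oat | 85% | 0.90 |
| rice | 80% | 0.90 |

Transcript-projection presets (used where markers are too sparse to
anchor a region) relax coverage to 0.80 (0.50 for rice CDS against pooled
locus transcripts) at the same identity ladder, and cross-genome
transcript ordering uses 0.80 coverage with the 95/90/80 identity ladder.
Oat is assembled only in contigs, where introns inside genomic contigs
make query coverage meaningless; oat contigs are therefore matched when
identity is strictly above 85% over at least 300 aligned nucleotides.
Protein-annotation matches are kept at ≥50% similarity and ≥50% coverage
against the Viridiplantae section of Uniprot, and ≥75%/50% against the
Brachypodium proteome (the closer relative justifies a stricter floor).
"Similarity" is taken as whatever the hit table provides (positives if
the producer reports them, otherwise identity); the run log records
which.

Coverage is computed from the aligned query span, `(qend − qstart +
1)/qlen`, not from the alignment length, which gaps inflate.

A marker whose two or more best placements (maximal coverage and
identity) fall at *distinct locations* cannot be anchored and is dropped
entirely.  Distinct locations are different chromosomes, or
non-overlapping spans at least 10 kb apart on one chromosome — tandem
split hits of one probe do not discard it.  Otherwise only the single
best hit (coverage, then identity, then bitscore) is kept.

Hits can come from any aligner that emits the standard 12-column tabular
format plus query and subject lengths.  The package also ships an exact
ungapped ≤k-mismatch scanner (vectorized window comparison; `N` never
matches) sufficient for desk-scale sequences and for the miRNA stage;
full-genome gapped alignment remains the job of an external aligner
consumed through the hit-table interface.

## Interval inference

Filtered, disambiguated hits are grouped by subject chromosome.  A
chromosome nominates an interval only with support from at least 3
distinct queries (default `min_support`), so a single spurious hit can
never create a "homologous region"; borders snap to the strand-normalized
hit extremes.  Gene-aware trimming is deliberately left out: the interval
records the evidence, annotation is applied downstream.

Where a permissive identity threshold lets stray hits through, the
continuity rule keeps only hits forming one continuous interval: single-
linkage clustering with a maximum inter-hit gap (default 2 Mb for dense
transcript projections, 5 Mb for sparse marker panels — both
configurable and logged), retaining the cluster with the most distinct
queries (ties: higher summed bitscore).  The filter is idempotent and
returns a subset of its input.

## Gene complement and longest isoforms

All annotated genes intersecting the interval (any overlap by default;
strict containment is available) are listed in coordinate order and each
contributes its longest isoform: the mRNA with the maximal summed CDS
length, ties broken by lexicographically smaller transcript id so reruns
are bit-identical.  Genes without any protein-coding isoform (e.g. ncRNA
genes) are excluded from transcript sets but counted in a side report.

## Synteny against a reference genotype

Each locus gene set is compared to the reference genotype's set by CDS
homology.  Assignment is one-to-one best-hit (bitscore, then identity,
then proximity of the reference rank to the nearest assigned neighbours —
which keeps collinear choices among tandem duplicates — then reference id
for determinism).  Each gene therefore carries at most one reference
"color", and genes without a passing hit stay uncolored, matching how
such comparisons are usually drawn.

Inversions are called as maximal runs of at least `min_run` (default 4)
consecutive *mapped* genes whose reference ranks strictly decrease;
unmapped genes inside the run are skipped.  This is an explicit
operationalization of what is usually judged by eye from the ordered
diagram; it is exact for clean single inversions and is not a
rearrangement-distance model.  Reversing a called range always restores
monotonicity over its span.

## miRNA discovery

Matures from a miRBase-style reference set are scanned against the locus
(both strands) allowing at most 1 mismatch.  Around every hit, candidate
precursor windows of 100/150/200/250 nt are cut with the mature anchored
to either arm (the hairpin extraction geometry is not standardized
anywhere; these lengths cover the plant pre-miRNA range and are
configurable).  Windows are folded with the ViennaRNA MFE engine and
tested against four structural criteria:

1. **Dicer cut sites** — the terminal 2 bases of the mature at each end
   are paired in the duplex (configurable 1–3 bp).
2. **No multibranch** — the hairpin region carrying the mature/star
   duplex encloses exactly one terminal loop.
3. **Not in head** — the mature does not overlap a terminal loop.
4. **Duplex mismatches** — at most 4 unpaired bases in the mature and 6
   in the star.  The star is inferred from structure as the positions
   pairing with the mature plus the canonical 2-nt 3′ overhang.

A candidate is accepted iff all four hold.  Accepted candidates whose
genomic windows overlap ≥50% (of the shorter) and share a family are
collapsed to the lowest-energy one, so one genomic hairpin is counted
once regardless of how many windows and strands recovered it.  Tests
assert structural predicates, never exact free energies, so results are
robust to fold-engine versions.

Family names are normalized by stripping the species prefix and
letter/arm suffixes (`tae-miR1122b-3p` → `miR1122`).  Family sharing
across genomes is reported as the exclusive Venn partition of per-genome
family sets, optionally pooling the wheat genotypes into one set.

Target scoring follows the psRNAtarget-style expectation: the mature is
aligned antiparallel to each ungapped CDS window; per mature position a
Watson–Crick pair costs 0, a G:U wobble 0.5, a mismatch 1 (a gap would
cost 2; ungapped enumeration produces none), doubled at mature positions
2–13 (the seed).  Sites with expectation ≤3 are retained.  Target-site
accessibility (UPE) is **not** computed — it would require a windowed
partition-function calculation that adds a second, less interpretable
cutoff — and the run configuration records the filter as disabled.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes: an
ancestral locus of protein-coding genes (1–3 exons, 1–3 isoforms as exon
prefixes, uniform gene and intergenic lengths) is copied into each genome
with i.i.d. substitutions (transitions twice as likely as transversions
combined), planted structural events (inversions, translocations, gene
losses at the gene-block level), markers embedded as locus substrings at
known positions, and pre-miRNA hairpins engineered per criterion.  Each
locus border is anchored by a *pair* of markers, as real panels saturate
QTL flanks; a single filtered-out edge marker therefore does not move the
recoverable border.  Default divergences mirror the real series: wheat
genotypes 0–1%, barley/rye 5%, rice 12% — under which wheat markers pass
the 95% preset, and rice markers fail it but pass the 80% preset, which
is the point of the scaled thresholds.

Hairpin positives are perfect inverted repeats with the mature at the 5′
end of one arm; each decoy class breaks exactly one criterion (mismatched
star bases at one Dicer site; two GC-stem subhairpins inside the duplex;
a self-complementary mature straddling the terminal loop; five spaced
star mismatches opposite the mature interior).  Because thermodynamic
folding can defeat any fixed construction for pathological random
matures, constructs are verified at design time: the bare construct must
fold to exactly the intended verdict pattern, and it must keep its
accept/reject outcome in random downstream contexts.  Hairpin parts are
exempt from substitution so each planting's intended verdict is exact.
Exact criterion *attribution* is guaranteed on the construct itself, not
in arbitrary flanking contexts, where distant sequence can always fold
into the hairpin's neighbourhood; in-locus discovery guarantees
accept/reject outcomes.

All randomness flows from one seeded generator; identical seeds give
byte-identical fixtures.  The generator does **not** emulate repeat
landscapes, transposons, paralogous gene families, indel divergence, or
assembly artifacts — so passing tests demonstrate correctness of the
pipeline's logic under the stated divergence model, not robustness to
repeat-rich real genomes.

## Problem sizes and numerical choices

Tests and the acceptance script run compact configurations (8–12 genes,
2–6 genomes, ~10–70 kb loci, markers 90–200 nt), which exercise every
code path of the full-scale analysis; the scanner and filters are exact,
so scale changes statistics only through marker-edge binomial tails, not
through the algorithms.  Tie-breaks are deterministic everywhere
(lexicographic ids, reference-rank proximity, lowest energy then
coordinates), and reports serialize with sorted keys so reruns are
byte-identical.  Degenerate inputs are defined, not special-cased: empty
hit lists infer no intervals, an empty marker panel aborts the pipeline
with a stage-named error, and a mature fully unpaired in its window fails
the Dicer and duplex criteria.

## Known limitations

- Inversion calling assumes a clean single inversion; nested or
  overlapping rearrangements produce fragmented calls.
- One-to-one best-hit homology collapses tandem expansions to a single
  reference partner (reciprocal-best is not the default).
- The built-in scanner is ungapped; indel-diverged homologs need an
  external gapped aligner through the hit-table interface.
- The head-violation decoy requires a self-complementary mature by
  construction; arbitrary matures cannot straddle a terminal loop while
  keeping the other three criteria intact, and the constructor raises on
  such requests.
- Precursor counts are per deduplicated genomic window; pipelines that
  count once per mature hit will report higher totals on the same locus.
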