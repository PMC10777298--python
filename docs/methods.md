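# Methods

## The assay this package models

A TRIP experiment (thousands of reporters integrated in parallel)
measures the chromatin position effect directly: a library of reporter
constructs, each carrying a unique 18-nt DNA barcode in its transcribed
3'UTR, is integrated into a cell population with the piggyBac
transposon, which inserts at TTAA tetranucleotides and duplicates the
target site. Three sequencing libraries are then read per population:

* **normalization** (gDNA amplicons) — each barcode's abundance in the
  cell population, i.e. clone size;
* **expression** (cDNA amplicons) — each barcode's abundance among
  transcripts;
* **mapping** (inverse PCR) — each barcode joined to its genomic flank,
  bounded by DpnII (GATC) digestion and self-ligation.

A 5-bp *promoter index* immediately upstream of the barcode records
which of four promoter variants drives the construct (`tacaa` = short
EF-1α, `ccgag` = long EF-1α, `ctagt` = mouse PGK, `agctc` = hamster
PGK), so all four construct classes can be sequenced in one pool. The
four indexes are pairwise Hamming distance ≥ 4, making single-mismatch
demultiplexing unambiguous.

## Statistics and procedures

**Normalized expression.** For barcode *i*,
`a_i = (e_i / E) / (n_i / N)` where `e_i, n_i` are collapsed
expression/normalization read counts and `E, N` the library totals.
Abundances are within-library parts-per-million before the ratio, so
the statistic is invariant to sequencing depth in both libraries.
Units are arbitrary (a.u.). A transgene with zero expression reads is
*completely silent*; the silence threshold is configurable because a
single stray read can otherwise mark a silent transgene as expressed.

**Reliability filter.** A transgene is retained when
`norm_count >= 5` (DNA evidence), `reads_r >= 10` (mapping depth) and
`freq1_r > 0.60` (mapping concordance, strict inequality). `norm` is
the collapsed raw read count in the normalization library, not a
per-million value. `reads_r` counts *all* mapping reads carrying the
barcode — unalignable and ambiguous reads included — so `freq1_r`
penalizes chimeric or repetitive products.

**Barcode error collapsing.** PCR and sequencing substitutions create
low-count mutant barcodes near genuine ones. We use a greedy
directional network collapse, the standard deterministic scheme for
UMI/barcode correction: barcodes are visited in (count descending,
lexicographic) order and merged into the first already-accepted
barcode at Hamming distance ≤ 2 whose original count satisfies
`count < 0.1 × parent_count`. The map is idempotent; counts are
conserved per (library, promoter) stratum. Mutants of very shallow
clones (parent count ≤ 10) stay unmerged by the ratio rule — they are
harmless because they cannot pass the reliability filter. The mapping
stage applies the same collapse to its read groups before locus
calling so that error reads rejoin their parent barcode and exact
joins across libraries operate on genuine barcodes.

**Insertion mapping.** The flank of an insertion is defined as the
duplicated TTAA followed by genomic sequence up to and including the
first downstream GATC (DpnII leaves the site on the self-ligated
circle); minus-strand flanks are reverse complements ending at the
TTAA, which works symmetrically because GATC is palindromic. Flanks
are aligned by exact k-mer seeding on their first k bases plus
full-length extension with ≤ 2 substitutions; all loci tied at the
minimal mismatch count are reported. The called coordinate is always
the 1-based first T of the duplicated TTAA on the plus strand,
regardless of transgene orientation. Per barcode, each read with a
*unique* best locus votes for it; the top locus wins, ties breaking
lexicographically by (chrom, position, strand).

*Seed length.* The aligner default is k = 20. For toy genomes of a few
hundred kb we recommend and use k = 12 (the permitted minimum):
DpnII fragments shorter than 20 bp arise at a few percent of TTAA
sites and would otherwise be unmappable, while a 12-mer is effectively
unique at this genome size (4^12 ≈ 1.7 × 10^7 ≫ genome length).
Flanks shorter than the seed are rejected as `flank_too_short`;
barcodes whose reads all fail produce no call and are reported as
residuals.

**Element annotation.** Genes span −1000 bp from the *distal*
transcription start site (the furthest-upstream transcript start) to
the transcription termination site; promoters are the strand-aware
window −1000…+100 bp around the TSS (1101 bases). 5'/3'UTRs are
exonic sequence up-/downstream of the CDS; introns are the gaps
between exons, unioned over transcripts. A locus overlapping several
labels is classified by the priority
promoter > utr5 > utr3 > exon > intron (configurable); the priority
makes the categories mutually exclusive with regulatory regions
dominant, and ties between genes break by TSS proximity. The query
point is the TTAA start coordinate, not the 4-base interval — a point
query keeps categories unambiguous. TSS/TTS distances are unsigned
minima over *all* genes on the chromosome, not just the host gene.
Chromatin types come from a user-supplied non-overlapping BED4
segmentation; a locus in a gap or on an absent chromosome is
`unassigned`.

**Motif statistic.** Windows of 2W+4 nt (default W = 10) are extracted
around each insertion, reverse-complemented for minus-strand sites so
all windows share the transgene orientation; positions are labeled
−W…−1, +1…+4 (the duplicated target site), +5…+(W+4), with no
position 0. Per position and base, enrichment against genome-wide
mononucleotide frequencies is scored with a binomial tail statistic in
the style of positional-probability logos:
`-log10 P(X >= k)` for over-representation, `+log10 P(X <= k)` for
depletion, `X ~ Binomial(n, p_background)`, computed with log-space
tail functions for numerical stability. The background is the supplied
genome's composition rather than a shuffled-site control
(configurable). Orientation normalization makes the matrix invariant
under mirroring the genome together with positions and strands; it is
*not* invariant under flipping a site's strand alone, which by design
reverse-complements that site's window.

## The synthetic-data generator

The generator stands in for an undeposited CHO-cell dataset and defines
the conditions every downstream stage is tested under.

* **Genome** — i.i.d. nucleotides at configurable GC (default 0.41,
  rodent-like), several chromosomes of 10 kb–1 Mb. Random sequence at
  this composition carries ~7 TTAA sites per kb, so insertion sites
  are plentiful; the generator errors out if fewer than 1/kb exist.
  Genes (1–6 exons, 300–900 bp exons, 0.5–3 kb introns, UTRs carved
  from the terminal exons) are placed with exponential spacing; a
  chromatin segmentation of 11 states tiles each chromosome exactly,
  with the three inactive states weighted to cover most of the genome
  as in mammalian segmentations.
* **Insertions** — n distinct TTAA sites, strand uniform, promoter
  class drawn from the 7:7:7:1 mixing ratio, barcodes drawn with
  pairwise Hamming distance ≥ 5 so that collapse correctness is
  testable (real data offers no such guarantee; thresholds remain
  configurable). Exactly `round(silent_fraction × n)` insertions are
  silent (default 0.55 — a majority-silent population); the mechanism
  of silencing is not modeled, silence is simply zero activity.
  Active insertions draw
  `activity = promoter_factor × state_factor × LogNormal(0, σ)` with
  promoter factors 10 : 1 : 0.5 : 0.3 (long EF-1α : short EF-1α :
  mPGK : PGK), state factors boosting transcription/enhancer states,
  and σ = 1 by default.
* **Clone abundance** — LogNormal(0, σ = 1), emulating a month of
  unselected polyclonal drift; no distribution is prescribed by the
  assay, and a log-normal is the conventional model for multiplicative
  growth dispersion.
* **Libraries** — read counts are Poisson: normalization rate ∝
  abundance, expression rate ∝ abundance × activity, mapping depth
  uniform; 2 × 75 bp reads, mapping library paired (R1 barcode side,
  R2 anchor + flank), substitution errors i.i.d. per base (< 5 %),
  constant quality strings. Amplicons carry only
  `constant_prefix + index + barcode (+ flank)`; real primer tails are
  protocol detail that downstream code must not depend on. No indels,
  PCR jackpots or chimeras are simulated — indel-tolerant matching is
  out of scope, and artifact products are represented only through
  the `freq1_r` mechanism. Insertions whose flank is shorter than
  20 bp are emitted but flagged `short_flank` in the truth TSV.

What passing tests on this generator do **not** show: robustness to
indels and adapter read-through, to PCR chimeras joining barcodes to
wrong flanks, to barcode collisions (real random barcodes can be
close or identical), to repetitive genomes where flanks multi-map
broadly, or to unequal per-base quality. The package's statistics are
designed to degrade gracefully in those cases (via `freq1_r` and the
ratio-bounded collapse) but the simulator does not exercise them.

## Numerical and design choices

* Coordinates are 1-based inclusive in memory; GFF3 is written
  1-based, BED 0-based half-open.
* Determinism: every stochastic step derives its generator from
  `(seed, stage_constant)`; identical configuration and seed give
  byte-identical FASTQ and TSV outputs.
* Top-decile cohorts take `ceil(0.10 × n)` records after sorting by
  activity, ties broken by barcode. Whether the denominator is the
  filtered cohort or its expressed subset is ambiguous in such
  experiments; both are supported (`promoter_summary` /
  `enrichment_report` accept any cohort), with the filtered cohort as
  default.
* Promoter summaries use medians of expressed records only; fold
  ratios are medians relative to the long EF-1α baseline.
* Degenerate inputs: empty promoter strata report NaN statistics (not
  zero); categories with zero baseline report NaN enrichment ratios;
  an empty top set or empty window list is an error; barcodes seen
  only in cDNA are excluded as lacking DNA evidence.
* Test problem sizes: most tests run on 60–320 insertions over
  60–200 kb toy chromosomes, and the replicate-average tests use 200
  populations of 641 insertions — sizes at which the checked
  statistics have sampling errors comfortably inside the asserted
  tolerances.

## Known limitations

* The aligner is substitution-only, seed-on-first-k-mer; it will miss
  flanks whose first k bases contain an error and has no gapped or
  spliced mode. Pre-aligned SAM/BAM with barcode tags can be supplied
  instead for real-genome workflows.
* Chromatin-state inference is out of scope; the segmentation is an
  input.
* Real assemblies (multi-Gb) would need a disk-backed k-mer index or
  the SAM input path; the built-in index targets toy genomes.
* The silent/expressed boundary at exactly zero reads is sharp;
  shallow expression libraries will overestimate silence.
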