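# Methods

`splicesurvey` re-implements, as a reusable and fully tested pipeline, a
genome-wide survey of splice-site border dinucleotides: classification of
all CDS-flanked introns from a genome assembly and its annotation,
validation of the annotated sites from RNA-Seq per-base coverage,
quantification of splice-site usage, detection of alignment-ambiguous
(shift-equivalent) intron placements, and comparison of the substitution
spectrum implied by minor non-canonical sites against genome-wide
substitution rates. This note documents the model, the defaults, the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## Splice-site model

An intron's *combination* is the 4-letter string formed by its donor
dinucleotide (first two intronic bases, 5′ end) and acceptor dinucleotide
(last two intronic bases, 3′ end), written in DNA letters on the coding
strand. The 256 unambiguous combinations partition into:

- **canonical**: GT-AG (1 combination);
- **major non-canonical**: GC-AG and AT-AC (2);
- **minor non-canonical**: the remaining 253.

Combinations containing any non-ACGT IUPAC character are **ambiguous** and
masked from diversity statistics; they are tallied separately
(`ambiguous_masked`) so per-species totals can be formed under either
masking convention.

Introns are defined only between consecutive CDS segments of one
*representative transcript* per gene — the transcript encoding the longest
polypeptide, with total CDS nucleotide length as the peptide-length proxy
(equivalent once CDS lengths are multiples of three) and a lexicographic
transcript-ID tie-break so selection is deterministic and order-invariant.
Restricting to the representative transcript makes species with different
isoform-annotation depth comparable; restricting to CDS-flanked introns
avoids the less reliably annotated UTRs. Genes failing structural sanity
checks (no CDS, CDS out of sequence bounds, overlapping CDS segments, CDS
length not a multiple of three, internal stop codon in the strand-aware
conceptual translation) are removed before extraction and accounted per
reason in a `FilterReport`; this minimal rule set is the package's own
choice and guarantees that every retained gene has a well-defined
translation.

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive)
and VCF (1-based) conventions are converted at the I/O boundary. On the
minus strand, combinations are read off the reverse complement so the donor
always sits at the biological 5′ end; a mirrored genome with mirrored
annotation therefore yields an identical profile (tested).

## Statistics layer

- **Divergence–frequency correlation.** One observation per unambiguous
  combination (n = 256): x = Hamming distance to GT-AG, y = the pooled
  count across species profiles. Spearman's rho with the t-approximation
  p-value. GT-AG itself (distance 0) is included by default, and pooled raw
  counts are the default frequency axis; a per-species-normalized mode and
  an unpooled (species × combination) mode are available.
- **Profile similarity.** Pairwise Spearman over the 256 aligned counts;
  zero-variance profiles give missing entries rather than a fabricated
  value.
- **Closest reference.** Each minor combination is assigned the nearest of
  GT-AG / GC-AG / AT-AC by Hamming distance, ties preferring
  GT-AG > GC-AG > AT-AC (the globally more frequent origins); the implied
  substitutions (reference base → observed base per mismatching position)
  feed the splice-site substitution spectrum.
- **Intron-length comparison.** A focal gene set's intron lengths are
  compared against equally sized draws (without replacement) from the
  background, two-sided Wilcoxon rank-sum per replicate, 100 replicates by
  default, reporting the median p and the mean of mean differences. The
  rank-sum (Mann-Whitney) form is used because the groups are independent
  samples.
- **Long-intron enrichment.** Restricted to minor unambiguous
  combinations, counts in introns > 5 kb versus the rest are converted to a
  ratio of proportions with pseudocount 1 on counts (so absent combinations
  stay comparable and no division by zero occurs), ranked descending with
  lexicographic tie-break, and the per-rank base composition of the
  combinations is reported.
- **Substitution spectra.** Genome-wide rates use only biallelic SNPs whose
  first-sample genotype is homozygous-alternative ("nucleotide substitution
  rate" is only well defined for single-base changes); indels,
  multi-allelic, heterozygous and missing calls are skipped and tallied.
  The splice-site spectrum is compared against expected counts =
  observed total × genome-wide relative rates over the 12 ordered
  substitution categories (unconditional on the ancestral base by default;
  a conditional comparison can be formed from the reported per-category
  tables). Categories with zero expected rate cannot enter a Pearson
  chi-square; observed counts falling there are pooled into an "unmodeled"
  remainder and flagged. Variant-overlap majority calls resolve ties as
  alternative-majority, i.e. conservatively against the reference.

## Coverage validation and usage

Coverage is consumed as BedGraph-style text (0-based half-open, one depth
per row, gaps = 0). For each intron, four single-base depths are read
strand-awarely: the last exonic base and first intronic base at the donor
border (E5, I5) and the mirror pair at the acceptor border (I3, E3). A
window-averaged mode exists but defaults to width 1.

A border is **supported** when the depth drops by at least `min_drop`
(default 0.2) stepping from exon into intron; **usage** is
1 − intron/exon, clipped to [0, 1], so "supported" coincides with
usage ≥ min_drop. A 1e-9 tie tolerance keeps the exact-boundary case (an
exactly 20% drop) supported under binary floating point, where
`1 − 80/100 < 0.2` even though `80 ≤ 0.8·100`. Zero exon coverage leaves
usage undefined with reason `no_expression`; validation ratios are reported
both excluding and including such introns, and both per-border and
combination-level (both borders supported) calls are emitted, since a
ratio can reasonably be defined either way.

## Shift-equivalent placements

Moving both boundaries of an intron by the same offset s leaves the mature
mRNA unchanged exactly when the |s| exonic bases surrendered at one end
equal the |s| intronic bases exposed at the other. All such placements
within ±`max_shift` (default 3) are reported with their new combinations;
every emitted placement is re-splice-verified byte-for-byte in the tests.
Placements whose combination is canonical or major are the diagnostic for
alignment artifacts such as CA-GG annotations overlapping a genuine GC-AG
site. Note that a repeat context can admit more than one mRNA-identical
placement (e.g. a CA-GG intron in a GG context has both a −1 GC-AG and a
−2 GG-TA equivalent); the class filter, not uniqueness, identifies the
biologically meaningful alternative.

## Synthetic data generator

The generator emulates the *shape* of the survey's inputs with exact ground
truth:

- protein-coding genes (valid start/stop, no internal stops by codon-level
  construction) split into exons of 60–240 nt, 1–8 introns per gene
  (uniform; mean 4.5, matching typical plant gene fragmentation);
- intron lengths from a log-normal body with mode 200 nt (σ = 0.6) plus a
  configurable heavy tail (default 1%) uniform on 5–9 kb, floor 20 nt;
- border combinations planted from the class composition
  (default GC-AG 1.2%, AT-AC 0.06%, minor 0.09%, canonical the remainder
  0.9865 — the published class averages with the dominant class absorbing
  their rounding remainder so fractions sum to 1), minor combinations
  uniform over the 253 or weighted ∝ 3^−d (d = distance to GT-AG) to
  mimic the observed divergence gradient;
- a 50/50 strand mix, genes tiled over chromosome-like sequences with
  random intergenic spacers, optional ambiguity-character injection at
  intron borders, and optional planted annotation errors (internal stops,
  out-of-bounds CDS) to exercise the filters;
- per-intron spliced fractions s (default 0.9) realized in coverage as
  exon depth × (1 − s) across the intron; `noise = 0` is exact, otherwise
  integer depths are drawn per base from a gamma-Poisson with variance
  m + noise·m²;
- homozygous biallelic SNPs drawn from a 12-category substitution
  spectrum, placed by rejection sampling at positions whose reference base
  matches the category and which avoid splice-site border bases.

Every planted feature is recorded in a JSON `TruthManifest`; because combos
are planted (not sampled at read-out), classification of generated data
must match the manifest *exactly*, and the tests assert this. What the
generator does **not** emulate: read-level sequencing (no FASTQ, no
alignment artifacts), alternative isoforms, UTRs, repeats/transposons, GC
heterogeneity, and pseudogenes. Passing tests therefore demonstrate
correctness of the measurement machinery under known truth — not that real
annotations are error-free, which is precisely what the survey is designed
to assess on real data.

## Problem sizes and calibration experiments

The test and acceptance workloads are sized to the method, not the data
volume of a full multi-genome survey: exact-recovery and composition
checks use a ~50,000-intron genome (3 binomial SE per class); the
multi-species statistics use a 10-species cohort (400–1200 genes each)
whose genome sizes are drawn independently of gene content so the
size/count decoupling is real; spectrum recovery uses 10,000 variants
(3 multinomial SE per category). The type-I calibration of the resampled
length comparison runs 1000 trials at 10 replicates with a background
(n = 4000) much larger than the focal sample (n = 25): when focal and
replicate samples are drawn from a small common pool they share elements,
and the induced rank ties make the rank-sum test conservative (measured
size ≈ 0.041 at background 400), whereas with negligible overlap the
design attains its nominal size (measured 0.048–0.052). A calibration
experiment must be run in the regime where the nominal size is the correct
reference, hence the large background.

## Known limitations

- The GFF3 reader handles the gene/mRNA(transcript)/CDS subset with `ID=`
  / `Parent=` attributes (GTF is out of scope); CDS rows may list multiple
  comma-separated parents.
- Coverage validation is strictly profile-based (four border depths); no
  split-read counting or junction discovery is performed, so a uniformly
  expressed retained intron and an unexpressed gene are distinguished only
  through the `no_expression` reason codes.
- Spearman p-values use the t approximation, adequate at n = 256 but
  approximate for very small profiles.
- The chi-square comparison treats the genome-wide rates as fixed expected
  proportions; their own sampling error is ignored (negligible for
  variant sets of realistic size).
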