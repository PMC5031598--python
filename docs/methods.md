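# Methods

This note records the model and procedure `gcxscan` implements, the
parameters that matter, the choices made where the design was genuinely
open, and what the synthetic-data tests do and do not establish.

## Gene models and coordinates

All internal coordinates are 0-based half-open; GFF3 (1-based closed) is
converted on read and on write, BED output stays 0-based. Each locus is
reduced to one representative transcript: the mRNA with the longest
total CDS, ties broken by the lexicographically smallest transcript id.
This is a stand-in for a curated "filtered" gene set in which each locus
already carries one model; it is deterministic and favours the most
complete coding form. Within the representative transcript, overlapping
CDS intervals (invalid but tolerated) are merged, the merged segment
keeping the phase of its first piece in transcription order, so no
genomic base is ever counted twice.

CDS *phase* is the number of bases to remove from a segment's start (in
transcription order) to reach the first base of a complete codon.
Missing phases are inferred by propagation from segment lengths with the
first segment assumed phase 0; explicit phases are trusted and restart
the propagation. The spliced coding sequence keeps its leading
phase-offset bases, but they are excluded before codon framing.

UTRs come from annotation when present; otherwise exonic sequence
outside the CDS span is classed 5' or 3' by its position on the coding
strand. Region classification (CDS / intron / UTR5 / UTR3 / intergenic)
is exclusive per position per gene model.

## Codon-position GC

GC_k is the GC fraction over the k-th positions of consecutive triplets
after the phase trim. Conventions:

- N and other ambiguity codes are excluded from numerator and
  denominator; a zero denominator yields an undefined (missing) value,
  never 0, so missing data cannot leak into densities or class tallies.
- A trailing partial triplet contributes its present positions by
  default (`include_partial`), maximizing data use; dropping it is a
  config switch. On a clean CDS with length divisible by 3,
  mean(GC1, GC2, GC3) equals CDS GC exactly.
- The whole-gene GC (intron-inclusive) spans the representative
  transcript from transcription start to stop.
- High/low classification uses an inclusive cutoff, default 0.80; the
  classification is monotone in the cutoff.
- Kernel density estimates use a Gaussian kernel with Scott's-rule
  bandwidth (overridable), renormalized to unit area on [0, 1]. An
  all-equal sample gets a narrow Gaussian at the common value rather
  than an error.

The degeneracy profile counts, for each codon position, the codons (of
64) admitting at least one synonymous substitution at that position,
with the three stop codons treated as their own synonymy class. Third
position degeneracy strictly exceeds the first and second — the
structural fact behind the wobble reading of GC3 bimodality.

## Motif model and scanning

The data-derived weight matrix behind the hotspot consensus is not
available, so the PWM is reconstructed from the IUPAC string: each
position distributes probability uniformly over its allowed bases
(V → A/C/G at 1/3 each, S → C/G at 1/2, …). Scores are log2 odds against
a background distribution (default uniform; overridable), with a
pseudo-probability ε = 1e-3 for disallowed bases so one mismatch is
penalized but finite. Windows containing N score the N position at 0
(the log-odds of a background-distributed base).

The 80% stringency is implemented as score ≥ 0.80 × max attainable
score; a min-anchored scaling (min + 0.80 × (max − min)) sits behind
`threshold_anchor="minmax"` since the original scanner's convention is
not recoverable. Both strands are scanned by default, coordinates always
reported on the forward strand with the motif-aligned sequence attached;
overlapping hits are all retained (tandem occurrences are real — genes
carry up to 16 instances).

A uniform-within-code PWM has the property that every sequence composed
of allowed bases attains the maximum score; sampled instances therefore
score fraction 1.0 by construction. This is a feature for planted-truth
testing and a documented limitation as a stand-in for the unpublished
matrix.

Hit localization assigns region from the hit's start position. The CDS
offset — and hence the codon frame — is defined only when all 19 bases
are consecutive in the spliced coding sequence; a hit interrupted by an
intron keeps region CDS but is flagged `split` with no frame. A hit
under two overlapping genes is assigned to both and flagged. Frames are
computed from the footprint's first base in the gene's *coding*
orientation, so hits on either strand of either-strand genes get a
well-defined frame (GC content is complement-symmetric, so the frame
analyses are insensitive to hit strand).

## Motif GC statistics

Per-position GC is averaged across instances in motif coordinates
(positions 1–19), then grouped into the fixed periodicity partition
{1,4,…,19}, {2,5,…,17}, {3,6,…,18}. For the codon-coordinate view, each
instance's bases are mapped to codon positions via its frame and the end
overhangs are trimmed: leading bases before the first complete codon and
trailing bases after the last complete codon are dropped, leaving only
complete codon columns (18, 15 or 18 bases for frames 1, 2, 3).

Group comparisons use per-position GC values as the unit of observation
(n = 7/6/6 in motif coordinates). For the codon-coordinate comparison,
where instances in different frames map the same motif position to
different codon positions, the sample for codon position k is the set of
per-(motif-position, codon-position) GC fractions — a reasoned stand-in,
since the original analysis never states its n.

The F-test is two-sided (p = 2·min(cdf, sf) of the variance ratio), the
spreadsheet convention. The gate α = 0.10 is the only threshold
consistent with the published routing of all nine comparisons (an F p of
0.058 went to the unequal-variance column, 0.289 to the equal-variance
one). Two zero-variance samples with equal means report t = 0, p = 1.
No multiple-testing correction is applied across the three pairwise
comparisons, matching the source analysis.

## Enrichment tests

All enrichment questions reduce to a 1-df goodness-of-fit chi-square of
a yes/no split against universe proportions: E_yes = n·U_yes/U_total at
full float64 precision, χ² = Σ(O−E)²/E, two-sided upper-tail p, no Yates
correction. Full-precision expectations are essential: recomputing the
published p-values from rounded printed expectations shifts log10(p) by
several tenths, while unrounded expectations reproduce them to the
printed digits. p-values below 1e-300 are displayed as "< 1e-300".
Degenerate inputs (empty universe class, empty observed subset) skip the
row with a warning rather than emitting a meaningless statistic.

Expression labels (up/down per comparison tissue) are consumed as input,
never recomputed; a gene may not be both up and down in one comparison.

## Synthetic data: the stated world

The generator emits one-gene contigs (FASTA + GFF3 + truth tables) whose
defaults mirror the genome-scale observations the analysis targets:

| parameter | default | rationale |
|---|---|---|
| class proportions high1/high2/high3 | 0.092 / 0.016 / 0.144 | genome-wide class fractions (3,647 / 629 / 5,719 of 39,656) |
| high-class GC probability | 0.90 | high-mode peak position |
| low-class GC per position | 0.52 / 0.45 / 0.52 | low-mode peaks (GC2 lowest) |
| intron / UTR / intergenic GC | 0.40 / 0.45 / 0.35 | introns GC-poorer than exons |
| codons per gene | uniform 100–300 | typical plant CDS lengths, scaled |
| motif-gene fraction | 0.10 | enough motif genes at n = 500 for stable recovery |
| per-gene motif count | geometric(p = 0.25), truncated at 16 | observed mean ≈ 3.9, observed max 16 |
| enrichment odds toward high-GC_x | 5 : 1 | strong, recoverable association |
| frame distribution | 868 : 389 : 1094 | observed genome-scale frame split |
| up/down fractions (vs seedling) | 0.0816 / 0.1044 | observed expression-class sizes |
| motif×up odds | 0.25 | up-regulation biased against motif genes |

Codons are sampled per-position independently (G/C and A/T split
evenly), not from a codon-usage table: the analysis consumes only
positional GC, and independence makes truth analytic. Stop codons are
resampled away inside CDS bodies; the appended terminal stop is T, A,
then G-or-A drawn at the gene's GC3 probability, so a degenerate config
with GC3 probability 1 measures GC3 = 1.0 exactly. Motif instances are
planted codon-aligned, non-overlapping, wholly inside one CDS segment;
genes with no feasible site are skipped with a log entry and the truth
updated. Everything derives from one seeded generator; the same seed
produces byte-identical files.

What the generator does *not* emulate: real codon usage and amino-acid
composition, isoform diversity (one model per locus), transposable
elements, soft-masking, GC gradients along genes, linkage between
neighbouring genes, or a realistic intergenic landscape (each gene sits
on its own contig). A green recovery test therefore establishes that the
pipeline's measurements invert the generator's stated world — not that
the biological effect sizes are realistic.

## Numerical and degenerate-input choices

- Undefined GC values propagate as None/NaN end to end.
- Chi-square rows with a zero expected cell raise (direct calls) or are
  skipped with a warning (table builders).
- The scan returns empty (not an error) for sequences shorter than the
  motif.
- Scores are compared with ≥ at the threshold; the inclusive boundary
  matches the inclusive GC_x cutoff.
- Seeds: every stochastic routine takes a numpy Generator or integer
  seed; nothing draws from global state.

## Known limitations

- The consensus-derived PWM is flat within each IUPAC code; real
  information content varies across positions, so absolute hit counts at
  a given stringency are not comparable to a scan with the original
  (unpublished) matrix.
- Genome-scale published counts (class sizes, 3,423 motifs, the
  868/389/1,094 frame split) require the real maize assembly and
  annotation, which are not shipped; they are used here only as printed
  inputs to arithmetic/statistical reproduction tests and as simulation
  defaults.
- The published motifs-per-gene histogram sums to 545 genes while the
  accompanying text says 544; totals are taken from the text and the
  discrepancy is surfaced, not silently reconciled. Similarly the
  published union count 380/544 is not exactly reconstructible by
  inclusion–exclusion (which gives 381) and is reported as stated.
- The representative-transcript rule and the per-position unit for the
  codon-coordinate group comparison are reasoned stand-ins for
  procedures the source does not specify.
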