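# Methods

This note documents the models, conventions and numerical choices behind
`spidmir`, and what the synthetic experiments do and do not demonstrate.

## Experimental design being modelled

Four single (pooled) small-RNA libraries from cucumber seedling leaves:
water or 1 mM spermidine spray, at control or high day/night temperature
(CW, CS, HW, HS). There are no sequencing replicates; inference is
count-based per library, which is why the exact tag-count test rather
than a dispersion-modelling method (edgeR/DESeq-style) is the core DE
engine, and why no replicate-based method is offered for the library
contrasts. The two-way ANOVA applies to replicated expression
measurements (e.g. qPCR validation), not to the library counts.

## Read cleaning

Rules run in a fixed order and each removed read is charged to the first
failing rule, so the categories partition the input (the closure
identities `high_quality = total − low_quality − high_N` and
`clean = high_quality − Σ structural categories` hold exactly and are
asserted in tests). Conventions the category names alone do not fix:

* *Low quality*: ≥4 bases with phred score <10. Quality is
  `ASCII − 64` by default (phred64, the HiSeq-era encoding), range 0–41;
  out-of-range characters raise an error naming the other encoding.
* *High N*: the N proportion must be strictly greater than 10 % — a
  proportion is the only dimensionally sensible reading of the rule.
* *3′ adapter location*: leftmost exact occurrence of the adapter
  prefix, allowing truncation by the read end down to a 6 nt seed. A
  seed match whose extension fails (e.g. spanning the insert/adapter
  junction) is skipped and the scan continues. Adapter at position 0 =
  no insert; no match anywhere = missing 3′ adapter.
* *5′ contamination*: the full 5′ adapter occurring anywhere in the read.
* *Poly(A)*: trimmed insert ≥80 % A (configurable; the threshold is a
  convention, not a published value).
* Inserts longer than 30 nt are retained: the 18–30 nt selection happens
  at the gel stage of library construction; the only stated computational
  length filter is <18 nt.

Cleaning-table percentages are computed against the high-quality count
(that is the 100 % row of the published table layout; the printed
clean-read percentages, e.g. 96.62 % for CW, only reproduce with that
denominator) and rounded half-up to two decimals.

## Annotation

Genome mapping is exact with no mismatches, both strands, all
occurrences; reverse-strand hits are reported against the plus-strand
interval. Multi-locus tags count once, toward a single category, chosen
by priority rRNA > snRNA > snoRNA > tRNA > repeat > exon (sense before
antisense) > intron (sense before antisense) > known miRNA >
unannotated. The priority encodes the usual removal order (structural
RNA and degradation fragments are annotated away before miRNA
identification); how multi-category overlaps were resolved in the
original pipelines is not documented anywhere, so this ordering is a
stated convention of this package. Sense/antisense is relative to the
feature strand. Coordinates are 0-based half-open internally; GFF3
(1-based closed) and BED (0-based half-open) are both emitted and parsed
so each convention is exercised.

A known-miRNA call requires a perfect substring match to a reference
precursor and ≥16 nt overlap with the annotated mature sequence; ties
prefer the longest overlap, then the lexicographically first name.
Per-miRNA counts sum the reads of all tags assigned to that miRNA.

## Novel miRNA model

The hairpin detector is a deliberate simplification of thermodynamic
folding, built to be deterministic, dependency-free and exhaustively
checkable: over all pairings (a, b) with loop ≥3 it finds the best
*contiguous* run of complementary pairs (WC = 1, G:U = 0.5; an unpaired
position terminates the stem) and scores it as minus the summed weight —
a dimensionless proxy for the minimum folding free energy. Contiguity
matters: with free internal mismatches, random ~100-mers would routinely
accumulate 14+ paired positions along a diagonal and the score threshold
would lose its meaning; with contiguity the null rejection rate of
random 100-mers at the −14 threshold exceeds 95 % (checked by Monte
Carlo). `call_candidates` accepts an external folding engine through its
`fold` argument for users who want true thermodynamics.

Candidate criteria (≥14 stem pairs inside the mature tag, loop ≥3,
score ≤ −14, tag boundary within 3 nt of a stem end as a Dicer-cut
proxy, ≥5 supporting reads) are configuration defaults, documented as
conventions. Candidates expressed in fewer than two libraries are
removed — the same rule applied to known miRNAs before DE — and
overlapping loci merge with support summed over distinct tags.

## Differential expression

Normalization is transcripts per million of clean reads. Zeros are
imputed to 0.01 *only* where a ratio is formed; the normalized matrix
itself keeps true zeros. miRNAs with nonzero counts in fewer than two of
the four libraries are excluded before testing.

The p-value is an exact tag-count test in the Audic–Claverie family:
conditioned on the count x in the first library, the count in the second
is negative binomial with q = N₂/(N₁+N₂). A two-sided value defined as
2·min(lower tail, upper tail) of that single conditional is not
symmetric under swapping the libraries, so this package defines

    p = min(1, 2·min( P(Y ≥ y | x; N₁,N₂), P(X ≥ x | y; N₂,N₁) ))

— the smaller of the two one-sided "at least as extreme" probabilities,
one in each conditioning direction, doubled and capped. This is
symmetric by construction, equals 1 at x = y = 0, and is maximal over y
at y = x for equal depths. Tails are evaluated by direct summation of
all-positive terms (log-gamma term generation, `math.fsum`): below the
distribution mode the short complementary lower sum is used (the tail
there is of order one, so the subtraction from 1 is harmless); at or
above the mode the decreasing tail is summed directly, preserving full
relative precision for p-values down to ~10⁻³⁰⁰. Tests hold the
implementation to ≤10⁻¹² relative agreement with a 50-digit
arbitrary-precision oracle over x, y ∈ [0, 50] at equal and strongly
unequal depths.

Significance is |log₂FC| > 1 (strict) and p < 0.05, with no
multiple-testing correction on the DE calls — matching the original
screening design; a BH option exists in the enrichment stage only.
`fold_change` computes log₂(treat) − log₂(ctrl) so the swap antisymmetry
is exact in floating point.

The two-way ANOVA is the balanced 2×2 fixed-effects decomposition with
exact sum-of-squares partitioning, cross-checked in tests against
statsmodels' `anova_lm` and calibrated by simulation (null interaction
p-values uniform by KS test; power >95 % at a 5σ interaction with four
replicates). All-constant input is flagged degenerate rather than
returning an arbitrary F.

## Screening

Class rules (heat = HW/CW ∧ HS/CW; spd = CS/CW ∧ HS/CW ∧ HS/HW; both =
all four, taking precedence) make the classes mutually exclusive: a
miRNA satisfying both the heat and spd rules is necessarily in all four
pairs. Direction patterns record the sign of log₂FC only in pairs where
the miRNA is significant; non-member pairs are excluded from the pattern
(for the "both" class all four pairs are members, so the full pattern is
always reported). Venn region counts are exclusive (disjoint) regions
and close over the union.

## Targets and enrichment

Duplexes are scored ungapped, miRNA 5′→3′ against the reverse complement
of the transcript window: mismatch 1, G:U 0.5, doubled at positions 2–13
from the miRNA 5′ end. The strict preset (max 4.0, no mismatch at the
slicing positions 10–11, no bulge) and relaxed preset (max 5.0, one
single-nucleotide transcript bulge costing 1, doubled in the core) are
this package's named presets — honest stand-ins for two published
prediction engines whose exact criteria are not public — and only genes
passing *both* are reported, so the intersection can never exceed either
preset's gene set. Enrichment is the upper-tail hypergeometric
probability against a user-supplied background (default: all genes in
the bundled transcriptome), corrected per ontology class with
Benjamini–Hochberg (switchable to Bonferroni); "corrected p < 0.05"
defines enrichment.

## Growth arithmetic

Percent change is 100·(b − a)/a rounded half-up to two decimals, which
reproduces the published contrast values from the published means —
except one value sitting exactly on a rounding boundary (the printed
means give 17.105 %, printed as 17.10), where agreement is to the ±0.01
uncertainty that two-decimal input means carry. Post-hoc grouping
letters are preserved as opaque annotations; re-deriving them would
require the unpublished replicate data.

## Synthetic data: what it emulates and what it does not

The generator plants, in a ~100 kb single-contig genome: 50 known miRNA
hairpins in 20 families, structural-RNA/repeat/exon/intron loci, novel
hairpin loci in unannotated space, a 60-gene transcriptome with perfect
complementary target sites for five of the responsive miRNAs (the other
three target nothing, mirroring the usual outcome that some screened
miRNAs have no predicted targets), and a term map whose planted enriched
terms are specific to the planted target set. Reads are insert + 3′
adapter + carrier sequence at fixed 49 nt with phred64 qualities;
contaminants of each removal class are injected at realistic rates
(totalling ~3.5 %, dominated by short inserts) and each is constructed
to fail exactly its intended rule, which is what makes exact
filter-vs-manifest accounting a meaningful test. Tag sequences are drawn
to avoid the 3′-adapter seed and the 5′ adapter so trimming is
unambiguous.

Clean reads are multinomial over a fixed tag-template distribution:
log-normal baseline abundances for known miRNAs (median ≈150 reads at
the default depth of 100,000 reads per library, which is depth-scaled
from the tens of millions of a real experiment) times per-library effect
multipliers for the planted responsive set (every planted contrast ≥4×).
Planted responsive miRNAs sit at ≈2 % of clean reads each; this was
chosen by a power argument — the weakest planted cell (a 16× knockdown)
then expects ≈140 reads, putting the log₂ fold-change sampling SD near
0.13, small against both the |log₂FC| > 1 call threshold and the 0.5
recovery tolerance used in validation. True per-library TPM and
fold-changes recorded in the manifest are the *realized* template
probabilities, so the recorded truth includes the small compositional
shift that strong effects impose on everything else (kept under 0.6
log₂ units by construction).

What passing these tests shows: the pipeline's bookkeeping is exact, its
numerical kernels match independent oracles, and planted effects of the
published magnitude are recovered at desk scale. What they do not show:
robustness to sequencing error (qualities are injected, not simulated
from an error model), isomiR heterogeneity (each miRNA emits its exact
mature sequence only), multi-contig genomes, imperfect target sites, or
real secondary-structure thermodynamics.

## Determinism and seeds

Every random draw flows from the single configuration seed through
`numpy.random.default_rng`; identical configurations give byte-identical
FASTQ, reference files, manifests and pipeline summaries (asserted by
double-run comparison). The validation script derives all of its
randomness from its `--seed` argument.

## Known limitations

* The hairpin score is not a free energy; thresholds are calibrated to
  the synthetic null, not to folding physics.
* The exact tag-count test assumes pooled single libraries; with
  replicates a dispersion-based model would be preferable.
* Enrichment results depend on the background definition; only the
  bundled-transcriptome background is validated here.
* The annotation priority order is a convention; real pipelines differ
  in how they resolve overlapping features.
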