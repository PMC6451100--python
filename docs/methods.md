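# Methods

This note documents the models, conventions and parameter choices behind
the package, the places where the procedure admitted more than one
reasonable reading, and what the synthetic-data tests do and do not show
about real libraries.

## Library architectures and read parsing

An oligo design is declared by the lengths and constant sequences of the
read layout `[UMI][anchor5][linker-random][variable][constant insert]
[3' adapter]`, with the UMI at the read 5′ end.  Two designs ship as
defaults:

| design | UMI | anchor | linker-random | variable | constant insert |
|--------|-----|--------|---------------|----------|-----------------|
| 5′-5N  | 0   | —      | 0             | 5 nt     | `TGAAATGCAAGCAAG` |
| 5′-8N  | 12  | `TGTAGC` | 2           | 8 nt     | `AATGCAAGCAAG`  |

The 8-nt design enforces a 10-nt distance between the anchor and the
constant insert (2 linker-random + 8 variable), so truncated or shifted
ligation products are rejected as `bad_anchor_gap` rather than quantified
with a frame-shifted variable region.  Constant-region matching is exact
at the expected coordinate by default (`max_constant_mismatches=0`); the
anchor itself must match exactly, and a read missing it is tallied as
`rejected_other`.  All coordinates are 0-based half-open; RNA input (U) is
normalized to DNA (T) before any comparison.  The layout is fully
configurable (YAML or dict), including whether the linker-random bases are
separate from or part of the UMI — they are separate fields by default.

Adapter handling: a full internal adapter occurrence is trimmed at its
first position; otherwise the longest adapter prefix of at least 6 nt that
is a suffix of the insert is trimmed.  Adapter presence is deliberately
not an acceptance requirement — "correct length" is defined by the insert
structure (constant insert at offset `variable_length`), so a read that
ends exactly at the insert boundary is still usable.

Base qualities are ignored throughout; quality control of raw FASTQ files
is an upstream concern outside the package.

## Deduplication and error elimination

Reads sharing a (UMI, variable-region) combination are collapsed into one
molecule.  Duplication statistics are computed from the pre-collapse
counts: the fraction of reads belonging to multi-read molecules, the
histogram of per-molecule read counts above 1, and the mean reads per
amplified molecule.

The iterative error elimination then runs per group:

1. take the entry with the highest read count as the representative —
   ties broken by lexicographically smallest sequence, which keeps the
   procedure deterministic without a random seed;
2. absorb every other entry within Hamming distance ≤ 4
   (`elimination_radius`) of the representative, adding its reads to the
   representative's count;
3. set the representative aside and repeat on the remainder, until all
   survivors in the group differ pairwise by more than the radius.

The pass is applied first to variable regions within UMI groups, then to
UMIs within variable-region groups.  A 2-mismatch pre-clustering radius is
accepted for interface compatibility but is a no-op: any entry within the
elimination radius of a representative is absorbed regardless of how the
candidates were grouped first, so pre-clustering cannot change the result.
Absorbed read counts are merged into the representative by default so that
total read counts are conserved and duplication statistics stay
meaningful; `drop_absorbed=True` discards them instead.  The procedure is
idempotent and, on groups of ≤ 100 entries, verified entry-for-entry
against an independent brute-force application of the same rules.

Libraries without UMIs (the 5-nt design) skip error elimination entirely;
raw read counts feed the count table directly.

Contamination removal deletes sequences within ≤ 2 mismatches of any
endogenous reference compared at the 5′ register (an endogenous hairpin
loop read through the pipeline puts its 5′ end in the variable-region
slot), and sequences structurally matching a different design (variable
prefix of the other length followed by the other design's constant-insert
prefix, optionally restricted to sequences actually observed in the other
library).

A caveat the simulator makes measurable: with uniform random UMIs,
distinct molecules can collide in UMI space, and the error-elimination
passes will merge those whose other dimension happens to lie within the
radius.  Exact molecule recovery is therefore a property of the exact
(UMI, insert) collapse; after error elimination the recovered count can
fall slightly below truth even at zero sequencing error.  At realistic
depths the deficit is a handful of molecules in 10^5.

## Enrichment statistics

All statistics normalize within-library (RPM or fractions) and are
therefore invariant to rescaling either library's counts.

- **Per-sequence**: `E(s) = RPM_IP(s) / RPM_input(s)`, ranked descending.
  Sequences with zero molecules in either library are excluded from
  ranking and reported with NaN factor rather than imputed; an optional
  pseudocount is available but off by default, since at 5-nt complexity
  essentially all 1024 sequences are observed directly.
- **Per-position**: percentage of molecules carrying each nucleotide at
  each position, per library; log2 of the IP/input percentage ratio per
  cell.  Cells with a zero input percentage are NaN, never silent ±inf.
  The matrix also carries a delta-method standard error per cell
  (multinomial sampling in both libraries), used by the null-calibration
  tests.
- **k-mer**: every overlapping window of every sequence contributes its
  molecule count; per-library window frequencies are ratioed.  The count
  is position-independent, which is what makes a position-anchored motif
  like 5′-GAC appear with diluted (but still top-ranked) enrichment.
- **5′ nucleotide**: log2 ratio of the fraction of molecules starting with
  each nucleotide.  `exclude_nac=True` removes molecules with `AC` at
  positions 2–3 from both libraries first — the re-analysis that asks
  whether 5′-G preference persists outside the GAC/NAC context.
- **Endogenous library summary**: sequences sorted by abundance; the
  selected set is the smallest prefix whose cumulative abundance reaches
  the top fraction (default 0.70).  The alternative reading — top 70% of
  distinct sequences — is available as `mode="distinct"`, but cumulative
  abundance is the default because the abundances are expressed as
  percentages of the total immediately before extraction.  Motif presence
  is a substring count over the selected set; the positional probability
  matrix covers a fixed logo length (default 21) with shorter sequences
  contributing only to positions they cover.

## Pairwise interaction analysis

The response variable is `log2(fraction_IP / fraction_input)` of each
projected 4-mer — the same enrichment currency as every other statistic;
nothing else in the procedure pins this choice down, so it is the
package's own.  Within each of the 70 windows, each of the 6 position
pairs × 16 nucleotide pairs is screened by a univariate regression of the
responses on the pair indicator (exactly a two-sample t-test), keeping
terms with two-sided *P* < 0.1.  No multiple-testing correction is applied
at the screen; the stepwise stage is what controls the final model.
Screened terms enter a joint linear model (intercept plus pair
indicators, main effects deliberately excluded to mirror the pair-only
formulation) and a bidirectional stepwise search minimizes AIC (BIC
selectable), starting from the full screened set and considering single
drops and re-additions until no move improves the criterion.  Weighted
least squares by input count is available (`weighted=True`); the default
is unweighted, since at 10^5 molecules the per-cell counts are nearly
uniform and weighting is immaterial.

Final coefficients are averaged per absolute (position, nucleotide) pair
over the windows where the term survived — windows not retaining a term
contribute nothing (no zero-filling), so a term retained in one window
reports that window's coefficient exactly.  Degenerate indicators
(constant within a window's observed cells) are skipped with a warning.

## Fragment pipeline

The filter cascade runs in a fixed order: keep reads fully contained in
gene loci (strand-aware); remove reads overlapping (≥ 1 nt) miRNA, siRNA,
piRNA, then RepeatMasker annotations — the small-RNA removals are
strand-aware, RepeatMasker is strand-agnostic because repeat annotations
are not reliably stranded for this purpose; remove multi-mappers
(multiplicity > 1); remove staggered reads; remove reads of length exactly
21 nt (the dominant siRNA length).  Containment-vs-overlap is
configurable per the gene stage.  Missing annotation sets (e.g. piRNA for
non-ovary libraries) skip their stage with an explicit warning recorded in
the attrition report.

"Staggered read" has no standard definition; here a read is staggered when
any read of the same library overlaps it on the opposite strand — a duplex
signature consistent with the cascade's goal of excluding duplex-derived
species.  This is an interpretation, flagged as such; partner search uses
the full input read set, since the duplex partner may itself fail an
earlier filter.

Motif testing extracts the 3-mers at read positions 1–3, 2–4 and 3–5
(read 5′→3′; minus-strand reads are reverse-complemented on load when the
BED stores reference-orientation sequence), tallied with read-count
weighting into zero-filled 64-slot tables.  Fold enrichment is the ratio
of within-library motif percentages; p-values are two-sided Fisher exact
tests on `[[motif_IP, other_IP], [motif_input, other_input]]`, using the
conventional two-sided rule (sum of same-margin table probabilities not
exceeding the observed one).  The p-value route is verified against an
independent hypergeometric-summation oracle to 1e-12 over an exhaustive
sweep of small tables (all tables with grand total ≤ 50, plus the full
grid with both library margins exactly 50).

## Simulator

The loading model is multiplicative: a sequence's IP sampling weight is
the product of its matching single-nucleotide, motif and pair effects over
a baseline of 1.  Input molecules are uniform over the 4^L space; IP
molecules are drawn proportionally to weight.  Two factory models mirror
the biology the package targets: `gac_model(2.0)` (5′-GAC doubles loading,
the AGO1-style preference) and `g_rich_model(1.3)` (per-position G
preference, the AGO2 style).

Read-level simulation adds a uniform-random UMI per molecule (collisions
deliberately allowed — they exercise the insert-grouped UMI collapse),
linker-random bases, a read multiplicity from the amplification
distribution, and independent per-base substitution errors.  The default
amplification is geometric truncated at 1 with mean 1.25, which puts
~36% of reads in multi-read molecules — inside the 30–40% duplication
range typical of these libraries — while keeping a long right tail; a
log-normal alternative is provided for heavier tails.  Errors are
substitutions only: every comparison in the pipeline is fixed-length
Hamming, so indels would only manifest as structural parse failures, and
they are not modeled.  Identical seeds give byte-identical FASTQ/BED
output.

The fragment fixture plants reads that each defeat exactly one cascade
stage (outside gene loci, inside each removal annotation, multi-mapped,
opposite-strand staggered pair, 21-nt) alongside clean survivor reads, and
records the expected survivor list by construction — an oracle independent
of the filter code.  Survivor sequences can carry a frame-1 GAC bias of
configurable strength for motif-enrichment power tests.

What the simulator does *not* emulate: ligation sequence biases, quality
score structure, platform-specific error profiles, RNA secondary structure
effects on selection, or chimeric/indel artifacts.  Passing tests
therefore demonstrate correctness and calibration of the computations, not
robustness to every artifact of real libraries.

## Problem sizes and numerical choices

Calibration and recovery tests run at 10^5 molecules per library — the
scale at which the 8-nt design's per-window cells hold ~400 molecules,
enough for stable log ratios — with 20 seeded replicates where a
frequency-of-success property is asserted.  Read-level end-to-end checks
use 10^4 molecules.  Fragment motif power checks use 3000 surviving reads
per library, matching the 1000–9000 uniquely mapped reads a real library
yields after the cascade.  The acceptance script reports planted-motif
recovery over 5 replicates at 10^5 molecules and sweeps the exact-test
oracle over all 2×2 tables with grand total ≤ 40 (the test suite extends
this to ≤ 50 plus the margin-50 grid).

Ties anywhere (representative selection, enrichment ranking, top-fraction
sorting) are broken lexicographically, making every output deterministic
given the input.  Log ratios with zero denominators are NaN, and NaN
records are excluded from ranking rather than imputed.

## Known limitations

- The staggered-read definition and the stepwise-regression details
  (response, criterion, pooling of all screened pairs per window) are
  documented interpretations; alternatives are exposed as options where
  they exist.
- Error elimination guarantees its pairwise-distinctness post-condition
  but, like any greedy representative scheme, can merge true molecules
  under UMI collision (quantified above).
- The fragment pipeline consumes already-mapped BED input; mapping itself,
  and the curation of annotation sets, are out of scope.
- Secondary-structure analysis of selected vs unselected pools is out of
  scope.
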