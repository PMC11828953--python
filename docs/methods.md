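# Methods

## Data model and conventions

All genomic coordinates are internally 0-based half-open; GFF3 and FIMO
files (1-based inclusive) are converted at the I/O boundary, BED is native.
"Upstream" and "downstream" are always relative to the gene's strand, with
the promoter window anchored at the start codon (the first coding base in
transcript orientation; on the minus strand this is the highest CDS
coordinate) and the downstream window just past the last coding base.

Abundance tables are gene × sample matrices with `SPECIES_R<k>` sample
headers. Missing protein/RPF values are *absent* (NaN), never zero: iBAQ
non-detection is censoring, and every downstream ratio requires detection
in both roles. Species-level values are arithmetic means over replicates;
proteomics and RNA-seq replicates are treated as unpaired, so all ratios
are formed on species means, never on paired replicates.

## PTR analysis

PTR(g, s) = protein mean / RNA mean for genes with RNA species-mean
TPM ≥ 1 (configurable floor) and any detected iBAQ. Low/moderate/high
classes use mean ± m·SD thresholds (default m = 1) computed per species on
log10(PTR). The log scale is a deliberate choice: PTR distributions span
decades and linear-scale thresholds would be driven entirely by the right
tail; a config flag (`ptr_log_scale=False`) restores linear thresholds.
Class thresholds are computed per species rather than pooled, since
detected gene lists differ across species.

Gene-set contrasts run a one-way ANOVA across species as a gate
(alpha = 0.05, configurable), then pairwise two-tailed Wilcoxon rank-sum
tests with BH adjustment over the pairwise family of one analysis.
Pairwise rows are still reported when the gate fails, flagged `gated`.
The resampling control draws 14 genes per species without replacement,
100 times (both configurable), records each draw's mean log10 PTR, and
feeds the per-species distributions through the same comparison machinery;
a set-specific effect leaves this genome-wide null flat.

## Translation efficiency

TE(g, s) = RPF mean / RNA mean for genes passing the TPM floor in both
roles. The species normalizer is the arithmetic mean of raw TE over the
photosynthesis set minus the C4 set (median available by config); the mean
normalized TE over that reference set is exactly 1 per species, and
normalized TE is invariant under global rescaling of the RPF column.
Extreme classes take exactly floor(frac·n) genes per tail (default
frac = 0.05) from the ranked list, ties broken by ascending gene
identifier so the classification is deterministic. The protein-to-RPF
ratio uses the same censoring and the same extreme fraction. Between-
species set contrasts are two-tailed rank-sum tests, BH-adjusted across
the sets tested.

## CRE enrichment

Occurrence context assignment labels each motif occurrence with every
(context, gene) pair whose window it intersects: genic (gene body),
upstream (3 kb from the start codon, strand-aware) and downstream (3 kb
past the stop codon). An occurrence may label several genes; it counts
once toward the target-associated total k even when multi-labeled, because
the pool is defined on occurrence totals, not label totals.

The permutation null draws k occurrences from the N-occurrence background
without replacement (a multivariate hypergeometric draw over per-CRE
counts; a with-replacement multinomial mode exists for very large pools)
B = 1000 times. The default p estimator is (1 + #{draws ≥ k_c}) / (B + 1):
it is never exactly zero and remains correct in degenerate pools (a
single-CRE pool yields p = 1, as it should). The literal exceedance rule
#{draws > k_c} / B is available as `p_mode="strict_paper"`; it underflows
to p = 0 for any sufficiently enriched CRE and is kept only for
comparability. The Fisher route tests each CRE's 2×2 margins one-sided
(greater); the odds ratio is the sample odds ratio with Haldane 0.5
correction when a cell is zero (flagged). Both p vectors are BH-adjusted
separately. The permutation shuffles occurrence identities only: ACR
spatial structure (overlaps, clustering along the chromosome) is not
preserved by this null — a known limitation of the count-based design.

## Sequence features

GC3 is the fraction of codons with G or C at the third position; codons
with N there are excluded from numerator and denominator.

The retroduplication scanner reports all maximal inverted-repeat pairs
with a flanking direct-repeat TSD: intervals [i, i+L) and [j, j+L) with
seq[i:i+L] equal to the reverse complement of seq[j:j+L] up to the
mismatch budget (default 0), L ≥ min_ir, spacer in [0, max_spacer], not
extendable by one base inward or outward, plus an identical direct repeat
of the longest length within tsd_range immediately outside the pair
(an inside-geometry flag covers the alternative TSD placement). Defaults —
min_ir = 6, tsd_range = (3, 6), max_spacer = 5000 — are deliberately
looser than the 9-bp/4-bp example signature so that detection is a
discovery, not an assumption. There is no field-standard score for this
signature; ranking uses L + t − 2·mismatches with ties broken by leftmost
position, purely to make output order deterministic. With a mismatch
budget > 0, "maximal" is evaluated under single-base extension only, so
near-maximal overlapping families can all be reported; the default budget
of 0 gives clean maximal runs.

The functional-copy rule designates, within a paralogous group, the member
with the highest mean TPM across C4-type species, provided it also exceeds
its C3-species counterpart (the same gene where annotated, otherwise the
group's most expressed C3 member). Ties yield no call with a tie flag.
Light-induction verification is experimental work and is not modeled.

## GRN refinement

An edge TF→gene survives cognate filtering iff the gene's promoter CRE
families intersect the families cognate to the TF's family; the shipped
cognate map is identity over ERF/bHLH/MYB/NAC/C2H2 (real analyses should
supply their own table — public TF-family↔CRE-family annotations operate
at family granularity, which is what the filter consumes). Filtering is
idempotent. The C4 sub-network keeps edges onto the target set; family
summaries count distinct TFs, and the ERF rate is distinct ERF TFs divided
by the number of target genes with at least one regulator.

## The synthetic generator

The generator emulates the five-species study design: one C3 species
(Frob), three C3–C4 intermediates (Fson, Fram, Flin), one C4 species
(Ftri); six RNA and protein replicates, two ribosome-profiling replicates.
Abundances are log10-normal (TPM/iBAQ span orders of magnitude): base RNA
mean per gene 10^N(1, 0.5); gene-level PTR 10^N(1, 0.25) and TE
10^N(0, 0.2); replicate noise SDs 0.1 (RNA), 0.2 (protein), 0.15 (RPF) on
log10 — free parameters chosen as plausible platform noise, not claimed to
match any measured dataset. In C4-type species the C4 gene set (14 genes,
matching the resampling-control size) gets RNA ×F (default 10, the
magnitude of the enzyme-level induction) and protein ×G (default 3), so
the realized PTR ratio is exactly G/F while TE is untouched — the
transcription-driven scenario. Protein couples to the species RNA mean,
not to individual RNA replicates.

The CRE pool draws background frequencies for 50 CREs (named by TF family)
from a Dirichlet with concentration 50 — large enough that no CRE is
vanishingly rare, so permutation means are estimable — places exactly
N = 100,000 occurrences in gene-tied ACRs, exactly k = 2,000 of them on
target-gene ACRs, and re-weights spiked CREs (default 3× on five CREs)
among target-associated draws only. Planted ACRs cover all three genomic
contexts with ≥3 kb spacing so each occurrence labels exactly its host
gene and generator counts are exact ground truth.

Sequence planting embeds TSD–IR–spacer–IRrc–TSD blocks in uniform-random
fragments with three single-base guards (spacer ends must not pair, the
TSD must block outward IR extension, the block's outer neighbours must not
lengthen the TSD) so the planted geometry is recovered exactly for any
background seed. CDS are random codons with third-position G/C probability
equal to the target GC3; they are not screened for stop codons, since only
third-position composition is analyzed.

The GRN generator assigns 50 TFs evenly to five families, draws 1000 edges
onto 200 genes with ERF edges biased 5× toward the 14 C4 genes (emulating
pronounced ERF prevalence in the C4 sub-network while the full TF
catalogue stays balanced), and plants cognate promoter CRE families for a
70% subset of TFs. Non-cognate TFs can survive filtering when a
same-family cognate TF targets the same gene, so the retained-edge
fraction sits slightly above the cognate fraction.

What the generator does *not* emulate: ortholog-mapping uncertainty across
species (a shared gene-id namespace is assumed; real cross-species tables
need an upstream ortholog map), compositional biases and mappability
artifacts in counts, overlapping ACRs and motif co-occurrence structure,
replicate-level batch effects, and read-level noise. Passing tests
therefore demonstrate correctness of the statistics under the stated
model, not robustness to those real-data complications.

## Problem sizes and numerical choices

Simulation-based checks use 2,000 genes × 5 species, pools of N = 100,000
occurrences over 50 CREs with k = 2,000 and B = 1,000 permutations, and 20
independent seeds per scenario — large enough that the targeted effects
(G/F = 0.3 PTR shifts at ~0.26 log10 within-set SD; 3× count spikes at
z ≈ 10) are resolved decisively, and small enough to run in seconds.
Permutation p-values use the +1 correction (above); BH adjustment is the
standard step-up with monotonicity enforcement; rank-sum tests use exact
enumeration for small untied samples and the normal approximation
otherwise (scipy's policy); Z-score rows with zero SD are emitted as zeros
and flagged; degenerate classification inputs (all-identical values,
fewer than two finite values) yield all-moderate classes rather than
errors where a downstream table would otherwise be lost.

## Known limitations

* The count-based permutation null ignores ACR spatial structure (above).
* Whether the original occurrence resampling was with or without
  replacement is ambiguous; without replacement is the default here, with
  the multinomial mode as the alternative.
* PTR thresholds per species and log-scale thresholds are this package's
  documented choices; per-species vs pooled thresholds change class counts
  by a few percent on synthetic data.
* The functional-copy rule uses transcript abundance only; experimental
  confirmation (light induction) is outside the package's scope.
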