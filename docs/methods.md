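# Methods

This note documents the models, decision rules, numerical conventions and
known limitations of the `gzexit` pipeline.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Migration-distance quantification

Slice assays export per-cell planar coordinates (µm) together with a
polyline tracing the pial surface.  The distance of a cell is the
Euclidean minimum over every *segment* of the polyline (closest point on
the segment, not nearest vertex), so concave surface traces are handled
correctly.  Distances are unsigned: a cell on the far side of the trace
still gets a positive distance, matching the "nearest surface" reading of
the assay.  The computation is exactly invariant under joint rigid motion
of cells and surface (tested to 1e-6 relative).

Distributions are binned over the assay's fixed 0–450 µm scoring domain.
The default **bin width is 10 µm** (45 bins): the source assays display
distributions "relative to a 450 µm scale" without stating a width, and
10 µm resolves every published condition mean while keeping expected
counts usable for the χ² test.  It is a parameter, not a constant.
Summaries are the mean, sample SD (n−1), n, and the 99th percentile
("migration front") computed with linear interpolation (the type-7
quantile convention, numpy's default).

### Condition comparison

Two conditions are compared with a two-sample χ² test on the shared-bin
contingency table (bins × 2 conditions).  Before testing, adjacent bins
are merged **rightward** until every expected cell count is ≥ 5 (the
classical χ² validity rule); a deficient tail folds into the last merged
bin.  Merging preserves totals, the test is symmetric in its arguments,
and p comes from χ² with (merged bins − 1) degrees of freedom.  The
source analyses do not state their binning or merging; these are this
package's choices.

Mean comparisons use **Welch's unequal-variance t** with
Welch–Satterthwaite degrees of freedom rather than a pooled Student's t:
the published group SDs differ by up to 3-fold, and the original analyses
do not state which variant they used.  This is a deliberate, documented
deviation.  The function accepts raw samples or (mean, SD, n) summary
triples, so printed summary statistics are directly testable.  Convention:
if both SDs are zero and the means are equal, p = 1 (logged).

### Rescue rule

A test condition is classified *rescued* when

1. its binned distribution is χ²-similar to the control: p(χ²) > 0.8, and
2. its mean differs from the phenotype condition: Welch t, p < 0.01.

Both thresholds are exposed as parameters with defaults (0.8, 0.01).  The
source material also phrases the second criterion as "average migration
distance less than 3% similar than the [phenotype] condition", which is
not interpretable as written; the t-test formulation, stated elsewhere in
the same material, is implemented instead.

## Synthetic cohorts

Cohorts are truncated-normal draws on [0, 450] µm, parameterized by a
registry of named presets holding the published per-condition mean, SD and
cell count — the presets *are* the study conditions, not free knobs.
Truncation is by rejection sampling (retry budget 1000 rounds); for every
shipped preset the nearest boundary lies ≥ 3.3 SD from the mean, so the
acceptance rate is ≈ 1 and the truncation bias (< 0.05 µm, verified
analytically against the truncated-normal mean) is documented rather than
corrected.  The synthetic surface is the line x = 0 with cells at
(distance, jittered y); any polyline is accepted downstream, the generator
simply uses the simplest one that makes recomputed distances equal the
drawn values.  The neurite-length presets reuse the same machinery (a
neurite length is a non-negative bounded measurement with a published
mean ± SD); for the rescue-screen neurite conditions the cell counts were
not published and n = 1000 is used, a round number of the same order as
the published assays.

**What the generator does not emulate:** the real migration distributions
are visibly non-normal (long inward tails, layer structure).  A truncated
normal recovers means, SDs and fronts, but *cannot* reproduce the
published χ² p-values between real conditions.  Consequently the χ² arm
of the rescue rule is exercised and reported on synthetic data but never
asserted against published χ² p-values, and with large-n normal cohorts of
different means the χ² arm essentially never passes — passing tests show
the rule's logic and the t-arm's behaviour, not χ²-level realism.

All generators draw from per-operation RNG streams seeded by
(seed, operation tag), so outputs are bit-identical for a fixed seed and
adding a generator never perturbs another's draws.

## Peak–gene association

Peaks are 0-based half-open intervals with a summit; gene TSSs are
1-based.  The conversion happens once, at the assignment/reader boundary.
Each peak is assigned to the gene minimising |summit − TSS| on its
chromosome; ties (equidistant TSSs, shared TSS positions) resolve to the
lexicographically smallest gene id, making assignment deterministic and
order-independent.  Signed distances are strand-aware (negative =
upstream).  Feature classes use a promoter window of −2000..+500 bp around
the TSS and a 10 kb proximal radius — common-practice values, configurable,
since the source does not state its windows.

**Binding events are counted as peaks, not genes** ("total number of
binding events"); a genes-mode is a one-line aggregation away via the
assignment table.  The association test draws N = 1000 random gene sets of
the observed size from the array universe *without replacement*, computes
the binding-event count of each, and reports z = (observed − null mean) /
null SD with a one-sided (enrichment) normal p by default; two-sided and
depletion tails are options.  A zero-variance null (e.g. the gene set is
the whole universe) raises a named error rather than returning p = 0 or 1.
Null boxplot statistics (median, quartiles, 1.5·IQR whiskers clipped to
the null range) are reported for plotting.  Calibration (uniform p under
no signal; type-I error at nominal level) is asserted in the test suite
over 200 seeds.

The cumulative-fraction map sorts up- and down-regulated genes separately
by decreasing |fold change| into 20 equal-size bins (the source says only
"equal bins") and reports, for each cumulative bin prefix and each binding
p-value threshold, the fraction of genes bound.  The threshold grid is
10⁻⁵…10⁻¹·⁵ in half-log steps plus 0.05.  The control map reassigns the
observed binding p-values to uniformly random same-size gene sets and
averages 100 draws.  Rows are non-decreasing along the threshold axis by
construction.

The E-box density profile counts, per offset in ±2000 bp around each
summit, the fraction of peaks with a motif match starting at that offset
on either strand (IUPAC motifs; default CACCTG, the Zeb-class core;
CANNTG supported).  Windows truncated at contig ends are dropped and
logged.  Under a uniform base model the expected per-position frequency is
2·(1/4)⁶ − (1/4)¹², which the tests verify on random sequence.

## Expression arithmetic

Deregulated genes are selected at |FC| ≥ 1.5 (linear scale, i.e.
|log2FC| ≥ log2 1.5) and BH q ≤ 0.05, the published cutoffs.  The per-gene
statistic is a Welch t between conditions: a deliberately simple selector
for synthetic matrices with known planted truth, in place of the
moderated-statistics array pipeline that is out of scope here (array
normalisation and batch correction are likewise out of scope; the matrix
is taken as already normalised).  Zero-variance-in-both-groups genes get
p = 1 and a `degenerate` flag.  BH is the exact step-up definition
(q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j, clipped at 1), implemented directly and
cross-checked against statsmodels in the tests.

ΔΔCt: per sample, ΔCt = Ct_target − Ct_reference-gene (default 18S); per
gene and condition, ΔΔCt = mean ΔCt(condition) − mean ΔCt(reference
condition); fold = 2^(−ΔΔCt).  Amplification efficiency is fixed at 2.0
(plain SYBR ΔΔCt, no efficiency correction).  The arithmetic is invariant
to adding a constant to all Ct values of a sample (that is what per-sample
normalisation means), and noise-free tables from the Ct generator invert
exactly (tested to 1e-9 relative).  ChIP-qPCR enrichment is the ratio of
sample %input to IgG %input, with the IgG channel reported as exactly 1.0
by definition.

## Labeling indices

A cell is positive when its normalized intensity is **strictly above** the
threshold (ties count negative, documented).  The default threshold 0.225
is the midpoint of the published 20–25% cutoff range; a sensitivity sweep
across [0.20, 0.25] is a parameter away.  Percent positive carries a
Wilson 95% CI.  Condition comparison is a pooled two-proportion z-test
(two-sided) at cell level, or Welch's t on per-replicate percentages for
replicate-level designs, matching how such assays are usually summarised.

## Problem sizes and determinism

The test suite and acceptance script run everything at the published
cohort sizes (up to ~13k cells; milliseconds per cohort) and at
calibration scales of 50–200 seeds × 1000 resamples over 1000-gene
universes — sizes chosen so that the Monte-Carlo tolerances quoted
(3·SD/√n for cohort means, 3 binomial SE for labeling indices, KS at
α = 0.01 for calibration) are the binding constraints.  Every random draw
descends from an explicit seed; fixed seeds give bit-identical files
(writers emit shortest round-tripping float text, readers parse with
round-trip precision).

## Known limitations

* Truncated-normal cohorts reproduce summary statistics, not the real
  distribution shapes; χ²-level claims about real slice data are out of
  reach of these synthetics (see above).
* The Welch-t DE selector is not a substitute for moderated array
  statistics on real microarray data.
* Peak assignment considers TSS proximity only (no gene-body or
  enhancer-aware model), matching the closest-TSS annotation it
  re-implements.
* The per-peak loop in assignment is O(peaks × log genes) per chromosome
  in numpy/pandas; it is sized for peak sets in the thousands, not
  millions.
* Intensities for labeling indices are assumed already normalised to
  [0, 1] per experiment; upstream image processing is out of scope.
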