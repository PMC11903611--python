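# Methods

## The analysis model

The pipeline compares two measurements of the same quantity — per-gene
expression in kidney tissue — made on incommensurable scales, by
projecting both onto one ordinal scale with four levels
(`Not detected < Low < Medium < High`).

**IHC side.** Antibody-based immunohistochemistry already reports those
four levels per gene and kidney cell type, together with an antibody
evidence grade (`Enhanced`, `Supported`, `Approved`, `Uncertain`).
Records graded `Uncertain` are removed before any comparison, because
an unreliable antibody makes both a positive and a negative call
uninterpretable. Only the two cell types with dense coverage — "cells
in glomeruli" and "cells in tubules" — are analyzed; matching is
exact-string after case/whitespace canonicalization, so "distal
tubules" or "proximal tubules (cell body)" are distinct annotations and
excluded by default.

**RNA side.** Bulk transcript abundance (nTPM) is discretized by the
zero/tertile rule: exactly zero is `Not detected`; the positive values
are split at their empirical 1/3 and 2/3 quantiles. Quantiles use
linear interpolation between order statistics (probability *p* maps to
rank 1 + (n−1)*p*, numpy's default). Intervals are upper-closed —
`(0, t1] → Low`, `(t1, t2] → Medium`, `(t2, ∞) → High` — so boundary
values deterministically fall in the lower category, and only an exact
zero is `Not detected`. Tertiles are computed on the **full** kidney
transcript collection, before pairing with IHC: the boundaries describe
the transcriptome, not the subset that happens to have protein data.
On a tie-free sample whose positive count is divisible by 3 this yields
exactly equal tertile sizes; with ties, boundary-sharing values all
take the lower category.

**Pairing and accounting.** Genes present on both sides form at most
one pair per compartment (join on the stable gene identifier when both
tables carry one, otherwise case-insensitive gene symbol; no fuzzy
matching). The 4×4 contingency matrix over pairs gives: concordant =
trace; the two *extreme discordance* classes are protein `Not detected`
with any mRNA signal (`protein_null_rna_detected`) and mRNA
`Not detected` with any IHC signal (`rna_null_protein_detected`); all
remaining off-diagonal cells are `discordant_other`. Unmatched genes
are counted per side and reported — never silently dropped.

**Independence test.** Pearson chi-square on the full 4×4 table,
including the `Not detected` row and column (the detection boundary is
part of the phenomenon under test, not a nuisance). All-zero rows and
columns are dropped before computing df = (r−1)(c−1); the statistic
sums (obs−exp)²/exp over retained cells; the p-value is the upper tail
of the chi-square distribution. A `validity_warning` is set when any
retained expected count is below 5. The df and warning are carried into
the JSON output so alternative table choices are auditable. A table
reducing to a single row or column is an error (the test is undefined),
not a silent p-value.

**Cross-platform validation.** Extreme-discordant pairs are re-examined
against platforms with complementary failure modes. Protein-null pairs
are counted at `nTPM > 0` (exclusive) and `nTPM ≥ 1` (inclusive), and
MS-validated when the gene's mean spectral count in the matching MS
compartment is ≥ 1; tubular IHC pairs match the MS
"tubulointerstitium" compartment (configurable mapping). RNA-null pairs
are counted at external `TPM > 0` and `TPM ≥ 1`. Genes absent from a
validation table are reported in an `unmatched` diagnostic, distinct
from present-but-below-threshold; a compartment with no validation data
at all reports *missing*, never 0. Validation percentages use the
compartment's total pair count as denominator. Nesting invariants
(strict ⊆ detected, MS-validated ⊆ detected, external-strict ⊆
external-detected ⊆ RNA-null) are enforced at assembly time and any
violation raises an internal-consistency error.

**Percentage rule.** Every count renders as `"N (P%)"`, with
P = 100·N/total rounded half-away-from-zero to two decimals, computed
in exact decimal arithmetic. `check_printed_percentage` recomputes a
printed percentage from its printed count and total under this rule and
raises when they disagree — in the published glomerular count table one
row ("3773 (33.46%)") fails this check (3773/11157 = 33.82%; the count
and percentage are mutually inconsistent, plausibly a digit
transposition), and the checker flags it rather than reproducing it.
The same published table's discordant counts differ from the
accompanying text (8475/6300 in the table vs 8472/6298 in prose); only
the table values sum to the printed totals, so the table is taken as
authoritative.

## The synthetic-data generator

Real inputs require large downloads with pinned upstream versions, so
the generator emulates their joint structure from a latent model with
recorded ground truth. Per gene, a latent pair (z_r, z_p) is standard
bivariate normal with correlation ρ (one z_p per compartment, each
correlated ρ with the shared z_r). Then:

- **Transcripts**: nTPM = 0 when Φ(z_r) < p_zero (latent thresholding,
  not an independent Bernoulli — so RNA non-detection co-occurs with
  protein non-detection when ρ > 0, as in real tissue); otherwise
  nTPM = exp(μ + σ·z′), where z′ is the conditional quantile of z_r
  above the threshold mapped back to a standard normal, making the
  positive marginal exactly lognormal(μ, σ) while staying monotone in
  z_r.
- **IHC**: category = position of z_p among the cutpoints
  Φ⁻¹(cumulative protein marginals); reliability drawn independently
  per gene (one antibody per gene).
- **MS**: negative-binomial spectral counts with mean exp(link·z_p);
  half of the IHC-`Not detected` genes are forced to zero counts,
  planting both MS-validated and MS-silent protein nulls; a small
  fraction of genes is absent from the MS table entirely (exercising
  the unmatched diagnostic).
- **External RNA**: TPM = nTPM·exp(ε) with small Gaussian ε, plus a
  planted fraction of RNA-null genes given positive external TPM drawn
  lognormal with most mass below 1 (so both the `TPM > 0` and the much
  rarer `TPM ≥ 1` validation rows are populated).

Defaults are the study conditions of the kidney datasets the pipeline
targets: `n_genes` 20 000, `p_zero_rna` = 3764/20162 ≈ 0.187, lognormal
μ = 1.84 and σ = 1.73 (back-solved so the positive-nTPM tertile
boundaries land near 3.0 and 13.3 nTPM), per-compartment protein
marginals equal to the published IHC category frequencies
(glomeruli ≈ 0.54/0.19/0.20/0.08, tubules ≈ 0.30/0.12/0.36/0.21), and
`overlap_frac` ≈ 0.55 of transcripts carrying IHC data. Quantities no
published table states were fixed once: reliability probabilities
(0.15, 0.25, 0.45, 0.15) for Enhanced/Supported/Approved/Uncertain —
a moderate `Uncertain` share typical of antibody panels — and ρ = 0.3,
a modest coupling consistent with the weak mRNA–protein level
correlations reported across human tissues.

**What the generator does not emulate.** Both compartments share one
gene-overlap set, so synthetic pair counts are equal across
compartments (real compartments differ in coverage). Antibody
cross-reactivity, batch structure, interobserver variability and
per-gene translation-efficiency differences are not modeled; passing
tests therefore demonstrate the correctness of the accounting,
filtering, discretization and testing machinery, not the biological
fidelity of any particular discordance rate.

**Ground-truth oracle.** The generator records, per gene × compartment,
membership, reliability, true nTPM, true protein category, MS count and
external TPM. `tally_truth` recomputes every summary count from this
table by direct boolean counting, re-deriving RNA categories from the
pipeline's *published* tertile thresholds — deliberately, because the
pipeline's empirical tertiles are sample-dependent and a truth tally
using population cutpoints would differ at the boundaries for reasons
that have nothing to do with correctness. `truth_check` returns one
message per disagreeing count.

## Numerical and design choices

- **Quantile convention**: the published tertile boundaries are rounded
  to one decimal and cannot disambiguate the upstream quantile method;
  published unequal tertile sizes (5481/5452/5465) imply ties or a
  different rule. The linear-interpolation convention is fixed and
  documented; exact replication of that split is not attempted.
- **Duplicate handling**: duplicate IHC (gene, tissue, cell type) rows
  keep the highest ordinal level (conservative toward detection,
  deterministic); duplicate quantitative keys are averaged by default
  and are an error in strict mode.
- **Perfect-correlation limit**: at ρ = 1 with matched marginals the
  two categories are monotone functions of the same latent variable;
  concordance approaches 1 as n grows but finite samples disagree at
  tertile boundaries (empirical vs population quantile), by at most one
  category. The test suite asserts exactly that, rather than an exact
  1.0 no finite sample attains.
- **Chi-square calibration**: under ρ = 0 fixtures the α = 0.05
  rejection rate over 1000 seeds at 2000 genes is required to lie in
  the exact binomial 99% interval around 0.05; cell expected counts at
  that size comfortably exceed the rule-of-thumb minimum.
- **Determinism**: one `numpy` PCG64 stream per generator call, fixed
  draw order, fixed output sort orders and no timestamps in data files,
  so identical seeds give byte-identical outputs and re-runs diff
  clean.
- **Problem sizes**: unit and property tests run at 400–2000 genes;
  calibration and convergence checks use 10–1000 seeds at 2000–20 000
  genes, sizes at which the checked asymptotics are already stable.

## Limitations

- The generator's ρ is a single global coupling; real mRNA–protein
  correlation varies per gene and pathway.
- The MS link (log-mean proportional to the protein latent) is a
  convenience, not a calibrated spectral-count model; only threshold
  crossings, not count magnitudes, are consumed downstream.
- The chi-square test is asymptotic; for very sparse tables the
  `validity_warning` should be heeded (no exact test is provided).
- Joining by gene symbol (when no stable identifier is present) is
  exact and case-insensitive; symbol aliasing across dataset vintages
  is out of scope.
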