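# hpaconcord

Concordance analysis of kidney mRNA and protein expression levels from
Human Protein Atlas (HPA)-style tables.

Bulk RNA-seq and antibody-based immunohistochemistry (IHC) measure gene
expression on very different scales: RNA-seq yields continuous,
genome-wide transcript abundance (nTPM), while IHC yields a
semi-quantitative four-level call — *Not detected*, *Low*, *Medium*,
*High* — per kidney compartment (glomeruli and tubules), limited by the
narrow dynamic range of chromogenic staining and the reliability of each
antibody. `hpaconcord` puts the two on a common ordinal footing and asks,
gene by gene, whether they agree — and when they disagree in the extreme
(protein invisible despite abundant mRNA, or an IHC signal with no
detectable transcript), re-examines those genes against
compartment-resolved mass-spectrometry (MS) proteomics and an external
compartment-resolved RNA-seq dataset. It is aimed at kidney researchers
who use HPA-style reference data and want a quantitative, auditable view
of how far its IHC protein calls can be trusted.

## Method

1. **Reliability filter.** IHC records with an "Uncertain" antibody
   reliability grade are excluded; only the "cells in glomeruli" and
   "cells in tubules" cell types are kept (exact-string match), giving
   one protein category per gene per compartment.
2. **Zero/tertile discretization.** For transcripts,
   `nTPM = 0 → Not detected`; positive values are cut at the empirical
   1/3 and 2/3 quantiles *t₁*, *t₂* of the positive distribution
   (linear interpolation between order statistics):
   `(0, t₁] → Low`, `(t₁, t₂] → Medium`, `(t₂, ∞) → High`.
   Tertiles are computed on the full kidney transcriptome before pairing.
3. **Pairing and contingency.** Genes present in both tables form one
   pair per compartment; pairs are tabulated into a 4×4 ordinal
   contingency matrix N with `N[i][j]` the number of pairs with mRNA
   category *i* and protein category *j*. Concordant pairs are the trace;
   every count is reported with its percentage of the compartment total.
4. **Independence test.** Pearson's chi-square on the full 4×4 table:
   `X² = Σᵢⱼ (Nᵢⱼ − Eᵢⱼ)²/Eᵢⱼ` with `Eᵢⱼ = Nᵢ₊N₊ⱼ/N₊₊`,
   df = (r−1)(c−1) after dropping all-zero rows/columns, with a warning
   when any expected count falls below 5.
5. **Cross-platform validation.** Protein-null pairs (protein *Not
   detected*, mRNA detected) are counted at `nTPM > 0` and `nTPM ≥ 1`,
   and validated when the gene reaches `mean spectral count ≥ 1` in the
   matching MS compartment (tubular IHC ↔ MS "tubulointerstitium");
   RNA-null pairs (mRNA *Not detected*, IHC signal) are counted at
   external `TPM > 0` and `TPM ≥ 1`. Nested counts are checked for
   monotone consistency and every percentage is recomputed from its
   count, so a published row whose percentage does not follow from its
   own count is flagged rather than reproduced.

A synthetic-data generator (`hpaconcord.synthetic_data`) draws all four
input tables from a latent bivariate-normal model with correlation ρ
between the transcript and protein latents, and records ground truth so
that every summary count can be tallied independently.

## Worked example

```bash
python examples/01_simulate_and_run.py
```

generates a 5 000-gene synthetic kidney dataset (ρ = 0.3) and runs the
full pipeline. Abridged output:

```
                                                     glomeruli        tubules
Number of reliable paired mRNA-protein measurements       2308           2308
pairs with concordant abundance levels             659 (28.55%)   742 (32.15%)
pairs with discordant abundance levels            1649 (71.45%)  1566 (67.85%)
no IHC signal but detected mRNA (nTPM > 0)         910 (39.43%)   486 (21.06%)
... and MS mean spectral count >= 1                110 (4.77%)     27 (1.17%)
no detectable mRNA but IHC signal                  124 (5.37%)   233 (10.10%)
... and external RNA-seq TPM > 0                    97 (4.20%)    194 (8.41%)

glomeruli: chi2 = 170.7, df = 9, p = 4.34e-32
ground-truth discrepancies: 0
```

Read: of 2 308 reliable mRNA–protein pairs per compartment, only ~29%
agree in exact ordinal level, yet the tiny chi-square p-value shows the
two platforms are strongly associated — disagreement is mostly
one-level, not random. 110 glomerular proteins invisible to IHC are
nonetheless robustly detected by MS. The final line reports that an
independent tally of the generator's ground truth reproduces every
summary count.

The other examples cover the desk-scale arithmetic on a published count
table (`02`), the tertile rule (`03`) and the validation joins (`04`).
A thin CLI wraps the same pipeline:

```bash
hpaconcord simulate --out sim/ --seed 7 --n-genes 5000
hpaconcord run --rna sim/rna.tsv --ihc sim/ihc.tsv \
               --ms sim/ms.tsv --ext sim/external_rna.tsv --out results/
```

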