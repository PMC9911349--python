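# lncexport

Most long non-coding RNAs (lncRNAs) stay in the nucleus; most mRNAs are
exported to the cytoplasm. When a protein-coding gene is born de novo from a
lncRNA locus, its transcript has to cross that nuclear-export boundary.
`lncexport` is a Python toolkit for quantifying this transition from
fractionation RNA-seq, pooled CRISPR read-outs and population polymorphism
data. It bundles, behind one consistent set of gene models and coordinates:

- **N/C ratio** — per-gene nuclear export from fractionated expression:
  genes with FPKM<sub>nuc</sub> + FPKM<sub>cyt</sub> < 0.2 are discarded and
  the rest scored as `log2((FPKM_nuc + 0.1) / (FPKM_cyt + 0.1))`, with
  z-score normalization for cross-dataset comparison and the complementary
  cyto/total ratio for single-gene assays.
- **PSI and ISOR** — per-intron percent-spliced-in
  (`junction / (junction + retention)` reads) and the gene-level isoform
  spliced-out ratio, `ISOR = Σ_i ℓ_i·PSI_i / exon length`: the spliced-out
  length per exonic length, a whole-gene splicing-efficiency score with an
  independent full-length-read estimator.
- **Maximum-entropy site models** — U1/5′-splice-site 9-mer scorers fitted
  by iterative proportional fitting to order-1 or order-2 positional
  marginals; log2-odds scores, strong-site densities per kilobase, and
  Δ-scores for variants (a PWM scorer is available as a fallback).
- **A CNN sequence classifier** — nuclear- vs cytosol-enriched transcripts
  (the extreme N/C tails) classified from one-hot sequence by a compact
  numpy convolutional network with 11-nt first-layer filters; motifs are
  extracted from first-layer activations as position-frequency matrices.
- **CRISPR mutation-effect tests** — allele-resolved 2×2 Fisher exact tests
  of export shift (mutant vs reference × nucleus vs cytoplasm) and splicing
  shift (junction vs retention × allele), Benjamini–Hochberg corrected,
  with the multi-mutation read discard rule, the top-50% |ΔU1| filter and
  splicing/export concordance summaries.
- **Population-genetic selection tests** — Nei–Gojobori-style pN/pS with
  pseudo-site frame projection, derived-allele-frequency spectra with
  bootstrap SDs, and a Monte-Carlo skewness test for the excess of rare
  derived alleles that marks purifying selection.
- **Co-expression conservation** — Pearson partner sets per focal gene and
  the fraction of partner pairs conserved across species.
- **A synthetic-data generator** — every input above, generated with known
  ground truth: planted U1 motifs, donor sites of controlled strength, a
  logistic export model `p_cyt = σ(b0 + b_u1·U1density + b_isor·ISOR)`,
  injected CRISPR effect sizes, neutral/constrained allele-frequency
  classes and two-species co-expression panels.

## Worked example

Simulate a cohort, quantify export and splicing, and train the classifier:

```bash
lncexport simulate --outdir demo --seed 4
lncexport nc-ratio --counts demo/counts.tsv --out demo/nc.tsv
lncexport isor --junctions demo/junctions.tsv --gtf demo/genes.gtf --out demo/isor.tsv
head -2 demo/nc.tsv demo/isor.tsv
```

```
gene_id  n_nuc  n_cyt  exonic_length  fpkm_nuc  fpkm_cyt  nc_ratio  passed_filter  nc_z
g00000   38     43     2502           2898.99   2917.87   -0.0094   True           0.0361
gene_id  isor    exonic_length  covered
g00000   0.4002  2502           True
```

Gene `g00000` has near-balanced fractions (N/C ratio −0.009 ≈ log2 1) and
splices out 0.40 exonic lengths of intron on average. Training the
classifier on a 300-sequence planted-motif task:

```bash
lncexport train-cnn --n-sequences 300 --seed 1 --out cnn.json --motifs-out motifs.meme
# test AUC 0.9333 on 30 held-out sequences
```

At the full 2,000-sequence benchmark (below) the held-out AUC reaches
0.999–1.0, and the top-ranked extracted filters reproduce the planted
GGTAAGT U1 motif (PFM correlation ≥ 0.8).

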