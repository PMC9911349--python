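# Methods

This note documents the statistical procedures, the generative model behind
the synthetic data, the defaults that matter, and the package's known
limitations.

## Coordinates and gene models

All in-memory coordinates are 0-based, half-open; GTF (1-based inclusive)
and VCF (1-based) are converted at the I/O boundary only. Multi-transcript
genes collapse to the union of their exons: N/C ratio, ISOR and U1 density
are gene-level quantities here, and isoform-level analysis is out of scope.
Minus-strand sequence access returns reverse-complemented, transcript-
oriented sequence, so every motif scan operates in the transcript's own
reading direction.

## Nuclear export quantification

FPKM is `reads / (exon_kb × mapped_reads/1e6)`, normalized per fraction
library (fractions are never pooled). Genes with
FPKM_nuc + FPKM_cyt < 0.2 are discarded per sample before any ratio is
formed; the N/C ratio is `log2((FPKM_nuc + 0.1)/(FPKM_cyt + 0.1))`. The
0.1 pseudocount bounds the ratio and keeps it finite at zero expression in
one fraction. Cross-dataset comparison uses z-scores (sample SD, ddof 1)
within a user-chosen grouping column — the grouping is a configuration key
because different studies normalize within species, tissue or batch. A
zero-variance group raises an error rather than emitting silent zeros.

## PSI and ISOR

PSI for one intron is `junction / (junction + retention)` where retention
reads are reads crossing the exon–intron boundary unspliced; intron-body
reads are not counted, which keeps PSI a two-outcome proportion amenable to
the Fisher tests used downstream. ISOR is the length-weighted PSI sum per
exonic length, `Σ ℓ_i·PSI_i / L_exon`. Two consequences are intentional:
intron-rich genes can exceed ISOR 1 (more than one exonic length spliced
out), and introns with zero coverage are skipped, never imputed as
unspliced. The full-length estimator averages per-read spliced-out length
over reads and equals the junction estimator exactly when per-intron
retention is independent and counts are noise-free; on sampled data the
two agree up to binomial noise in both estimators.

## Maximum-entropy site models

The U1-recognition site and the 5′ splice donor share one 9-mer model (3
exonic + 6 intronic positions, consensus CAG|GTAAGT). Order-1 models are
the closed-form product of positional marginals; order-2 models are fitted
by iterative proportional fitting over the full 4^9 joint table to all 36
pairwise marginals (tolerance 1e-4 on the worst marginal, at most 500
sweeps; the table is ~2 MB and fits comfortably in memory). Scores are
log2 P_model/P_background with a uniform background by default.

Fitting is exact (marginals are reproduced to machine precision at
convergence) unless a Laplace `pseudocount` is requested; the default
scanning model uses pseudocount 1 so that sites absent from training keep
finite scores. A "strong" site exceeds a threshold calibrated to a
quantile of background-sampled site scores; the default quantile is 0.95,
but density *contrast* analyses in the tests use 0.995 because a peaked
model assigns the 95th percentile a low absolute score and the resulting
5% background hit rate adds avoidable noise to per-gene densities. Variant
Δ-scores evaluate both alleles in the maximal-scoring window overlapping
the variant; variants with no clean full-width window are flagged
out-of-window and treated as neutral.

## The export classifier

Labels come from the extreme tails of the filtered N/C table (default top
and bottom 5%, sequences < 5,000 nt), encoded one-hot with ambiguous bases
as zero rows, split 8:1:1 stratified by class. The network is a compact
CNN written directly in numpy: conv(24 filters × 11 nt) → ReLU → max-pool 6
→ conv(32 × 5) → ReLU → masked global mean pooling → one logistic unit,
trained with Adam (lr 1e-2, batch 32, ≤ 20 epochs, early stopping on
validation loss with patience 4). Design choices:

- The 11-nt first-layer receptive field realizes the sliding-window view
  of the sequence; filters are directly interpretable as motifs.
- Global *mean* pooling makes the penultimate representation a per-filter
  motif density — the quantity the generative export model acts on; local
  max pooling in between preserves motif peaks.
- Variable lengths are handled by zero-padding to the batch maximum with
  masks at every layer, so padding never leaks into pooled statistics;
  batches are length-bucketed to limit wasted computation.
- Everything is seeded: weight init, shuffling and splits reproduce
  bit-identical results on a fixed thread count.

Motif extraction collects, per first-layer filter, all windows whose
activation reaches at least half (configurable) of the filter's maximum,
stacks them into an 11×4 position-frequency matrix and ranks filters by the
mean activation of contributing windows. Recovery is judged by the best
Pearson correlation of the planted 7-mer PWM slid across the extracted PFM.

## Mutation-effect tests

Reads carrying two or more mutations are discarded before tabulation (the
compound-effect rule); each retained read increments, for every mutation it
overlaps, the mutant or reference cell of that mutation in its fraction.
The export test is a two-sided Fisher exact test on
(mutant, reference) × (nucleus, cytoplasm); p-values sum hypergeometric
probabilities ≤ the observed table's (computed via log-gamma, with the
conventional 1 + 1e-7 tie tolerance). The odds ratio is the nuclear odds
of the mutant over the reference allele, so OR > 1 = nuclear-retained =
decreased export. BH correction is pooled across all mutations of an
assay; tables with a zero margin are untestable and excluded from the BH
family. The splicing test is the analogous Fisher test on junction versus
retention reads per allele and additionally requires |ΔPSI| > 0.05 (the
five-percentage-point rule). The top-50% |ΔU1| filter ranks by absolute
score change with deterministic id tie-breaks. Concordance couples
stronger splicing with increased export and weaker splicing with decreased
export, over mutations carrying both calls.

## Selection tests

pN/pS counts mutational opportunities per codon by equal-rate enumeration
of all nine single-nucleotide changes (no transition/transversion
weighting); stop-producing changes count as nonsynonymous, and the two
site counts sum to the CDS length. For non-coding orthologues, a pairwise
codon-level alignment projects the coding frame onto the orthologue
(pseudo-sites); variants in gapped columns are skipped and tallied. The
ratio is flagged undefined when no synonymous polymorphism exists, never
silently 0/0.

DAF spectra use 10 equal bins on (0,1), unfolded, with SDs from 1,000
bootstrap resamples of sites. The skewness statistic is the biased moment
ratio g1 = m3/m2^1.5. The Monte-Carlo test resamples focal-sized sets from
the synonymous (neutral) sites 10,000 times; because a spectrum leaning
toward rare derived alleles concentrates mass at low frequencies and
therefore *raises* g1, the purifying-selection ("left-skew") alternative
rejects for large observed g1, with the add-one-smoothed p-value
`(1 + #{null ≥ obs})/(n_boot + 1)`. A zero-variance focal spectrum (all
singletons) is maximal concentration and maps to the smallest attainable
p. The test is exactly calibrated when focal sites are exchangeable with
the neutral pool; with a small neutral background it inherits the mild
anti-conservativeness of any plug-in bootstrap null.

## Co-expression conservation

Partners of a focal gene are genes with Pearson q < 0.05 across
individuals, with p-values from the exact t transform (panels here have
≥ 30 individuals; a permutation mode is not provided) and BH correction
within each focal gene's family. Constant-expression genes are excluded
and tallied. The conservation fraction re-derives the orthologous focal
gene's partner set in the second species with the same procedure and
reports the fraction of mappable partners whose orthologue is significant
there; partners without orthologues leave the denominator and are tallied.
Group contrasts use the rank-sum test (signed-rank when paired).

## The synthetic-data generator

Each simulated gene occupies its own chromosome (100-nt flanks), with 2–4
exons of 200–700 nt and introns of 200–1,200 nt by default, i.i.d.
background sequence at configurable GC (default 0.5). Donor 9-mers of
"strong" (consensus) or "weak" strength are written at every exon–intron
boundary and set the intron's true splicing fraction (0.92 / 0.40). U1
7-mers (GGTAAGT, 10% per-base divergence) are planted at Poisson per-kb
rates in exons and introns. The export model is logistic:
`p_cyt = σ(b0 + b_u1·exonic U1 density + b_isor·true ISOR)` with defaults
(0.5, −0.8, +2.0) — exonic U1 retains transcripts, splicing exports them;
the coefficients are free parameters of the generator, chosen to give
realistic N/C ranges (±3 log2 units), not published estimates. Counts are
Poisson per gene (lognormal expression weights, σ = 0.4), binomial across
fractions, binomial junction/retention reads per intron, and independent
per-read intron retention for full-length reads.

The mutation assay draws 50/50 allele mixtures at configurable depth,
multiplies the mutant allele's nuclear odds by the injected effect and
shifts the targeted intron's PSI by the injected delta; a configured
fraction of mutant reads carries a second mutation to exercise the discard
rule, with the affected read ids recorded in the truth table. Population
classes draw derived-allele counts k ∈ {1..n−1} with weight k^−α (α = 1
is the standard neutral spectrum; larger α gives the rare-allele excess of
purifying selection; n = 100 chromosomes by default). Expression panels
use a one-factor block model (within-block correlation ≈ r, default 0.8)
over 134 and 35 individuals for the two species — the panel sizes of the
study design this emulates — with lineage-specific blocks correlated in
one species only.

The classifier benchmark task generates 4,000 two/three-exon genes whose
exonic U1 planting rate varies uniformly over 0.3–8 /kb, simulates
fraction counts at 300× mean depth under a steepened export model
(2.0, −1.0, +2.0), and labels the top and bottom quarter of the N/C
distribution — the synthetic analogue of labeling transcriptome extremes.
Because the tails differ strongly in planted density, class overlap is
negligible (Bayes error ≈ 0) and held-out AUC measures the network, not
the task's ambiguity.

What the generator does **not** emulate: read-level FASTQ output,
sequencing error, positional coverage bias, isoform diversity,
phylogenetic sequence evolution, linkage between sites, or expression
confounders in the panels. Passing tests therefore demonstrate
correctness of the statistical machinery and recoverability of planted
signal, not robustness to the full noise structure of real libraries.

## Problem sizes and determinism

Default test-suite problem sizes (2,000-sequence classifier benchmark,
240-gene contrast cohorts, 500-mutation calibration runs, 200-replicate
Monte-Carlo calibrations) run in under four minutes on one CPU. Every
stochastic component takes an explicit seed; the pipeline manifest records
parameter sets and SHA-256 output hashes, and re-running a configuration
reproduces identical hashes for all deterministic stages.

## Known limitations

- The PSI Fisher test treats introns independently; pooling junction
  evidence per gene is not implemented.
- The maxent scanner is single-threaded and intended for transcript-scale
  scans, not whole-genome scans.
- Orthology is consumed as a 1:1 map; paralogy is out of scope.
- Ancestral-allele polarity is consumed from the VCF AA tag; unpolarized
  variants are excluded, never imputed.
- The ISOR denominator uses the exon union of each gene; alternative
  isoform-resolved denominators are not offered.
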