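# Methods

This note documents the statistical models, the numerical choices and
the synthetic-data design behind `hervitope`, and what the passing test
suite does and does not establish about real data.

## Differential expression

The tumor-vs-peritumoral test is a self-contained negative-binomial
Wald test in the DESeq tradition, chosen over wrapping an external DE
engine so that every step is inspectable and fast enough for repeated
simulation studies. Counts K_ij for provirus i in sample j are modelled
as NB with mean s_j·q_{i,g(j)} and dispersion α_i, Var = μ + α μ².

- **Size factors** s_j: median-of-ratios to the per-provirus geometric
  mean, restricted to proviruses detected in every sample; library-size
  ratios as fallback. Size factors are defined up to a common scale —
  only ratios between samples are meaningful.
- **Dispersion** α_i: method of moments on normalized counts, pooled
  within groups, floored at 1e-8. No information sharing across
  proviruses (Cox–Reid/empirical-Bayes refinements are deliberately out
  of scope); under the simulation's shared-α design the floor plus
  pooling keeps the Wald test calibrated (observed type-I ≈ 0.057 at
  nominal 0.05, inside the accepted [0.03, 0.07] band).
- **Group means**: per-group Newton–Raphson on the log mean with Fisher
  scoring; steps clipped to ±5, log-means to ±30 so all-zero groups
  degrade gracefully instead of diverging.
- **Wald test**: z = log2FC / SE from the Fisher information;
  Benjamini–Hochberg across proviruses with all-zero rows excluded from
  the denominator and reported as NA.
- **Shrinkage**: a zero-centred normal prior whose variance τ² is a
  robust upper-tail estimate — (q99 of |log2FC| / 2.326)² minus the
  median sampling variance, floored at 0.0625. Each estimate is scaled
  by τ²/(τ² + SE²): strong effects are barely touched, noise-dominated
  ones are pulled hard toward zero, signs never flip, magnitudes never
  grow. P-values always come from the unshrunken statistic. This is a
  lighter-tailed prior than apeglm's; exact replication of external
  shrinkage estimators is a non-goal, and externally computed DE tables
  in the same schema can be plugged in anywhere downstream.

## CAH and cyt annotation

"Overexpressed twofold" is interpreted as shrunken |log2FC| ≥ 1 together
with padj < 0.05; a pure fold-change mode (`require_significance=False`)
is provided because the significance cutoff for this filter is a
genuinely open choice. Exclusion precedes inclusion: a provirus
overexpressed in *any* peritumoral tissue is removed before the
per-cancer union is taken, making the annotation idempotent and
order-independent.

The penalized association solves (1/2n)·deviance + λ‖β‖₁ by cyclic
coordinate descent (numba kernel; IRLS outer loop for the poisson
family), with the intercept unpenalized and **no predictor
standardization** — log2(CPM+1) inputs are already on a common scale.
λ is chosen by 10-fold cross validation minimizing squared prediction
error (gaussian) or deviance (poisson) on a 60-point log-spaced path
down to λ_max/100; fold assignment is a seeded permutation recorded in
the outputs. Path and fold fits use relaxed tolerances (1e-6, ≤200
sweeps, warm starts) because they only shape the CV curve; the reported
fit at λ_min is re-solved tightly. A provirus counts as associated only
with a strictly **positive** coefficient.

In the orchestrated pipeline the association design matrix is restricted
to the called CAHs: only CAHs are eligible for the cyt label, and the
restriction makes per-cancer models cheap enough to rerun across seeds.
The library-level `lasso_fit` accepts any design, and the test suite
verifies selection recovery on the full 200-provirus design as well
(mean recall 1.0, false selection ≈ 0.07 at noise sd = 0.5 × signal sd).

Criterion C compares mean log2-CPM in purified T (and NK) cells against
the remaining sorted PBMC classes; the threshold (default 2-fold, the
same as the CAH filter) is inclusive at the boundary, a documented
convention. The CYT score's gene pair is configurable (GZMA+PRF1
default, GZMB+PRF1 available) because both conventions are in use. The
ssGSEA implementation uses rank-magnitude weights to the power 0.25,
stable input-order tie-breaking, and defines the all-genes set to score
0; cell-type (Xcell-style) phenotype scores are consumed as input, not
recomputed.

## Epitope screening

- ORFs are stop-to-stop segments, no start codon required, minimum
  length 10 aa **inclusive** (configurable); codons containing N
  translate to X and terminate nothing. Coordinates are 0-based
  half-open on the forward strand; negative frames are read 5'→3' on the
  reverse complement.
- Homology uses full Smith–Waterman (Biopython `PairwiseAligner`) with
  BLOSUM62 and NCBI-convention affine gaps (a gap of length L costs
  11 + L, i.e. open −12 / extend −1 in first-residue terms) — on inputs
  this small, seeding heuristics buy nothing. E-values follow
  Karlin–Altschul, E = K·m·n·e^(−λS), with gapped BLOSUM62 constants
  λ = 0.267, K = 0.041 and m·n = query length × total kept-reference
  length. Identity is computed over all aligned columns, counting gap
  columns as mismatches, and the 90% threshold is inclusive; no minimum
  alignment coverage is enforced (the best local hit decides), which is
  flagged as a known permissiveness rather than silently tightened.
- Binding prediction is a pluggable interface: a rank-table lookup for
  externally computed percentile ranks, and a built-in anchor heuristic
  for HLA-A\*02:01 nine-mers (position 2 ∈ {L, M}, position 9 ∈
  {V, L, I}) that exists purely as a deterministic test stub and is not
  physiological. Strong binders are rank ≤ 0.5, inclusive. Peptides
  absent from a rank table are conservatively treated as non-binders.
- Relocation searches exact 9-mers in ORF-level translations with the
  minimum length relaxed to k, counts **distinct provirus ids**, and
  ranks by count with lexicographic tie-breaks. Counts are monotone
  nondecreasing as the scope widens (cyt ⊆ CAH ⊆ all).
- Proteome exclusion is exact substring matching — one mismatch anywhere
  keeps a peptide.

## Scores, survival, methylation

π = log2FC · log10(1/p) with p floored at 1e-300; the BH-adjusted p is
the default (published tables report adjusted values), raw-p mode is a
flag. Cumulative epitope scores are plain sums of π over containing
proviruses, optionally per peritumoral comparator. The provirus-set
survival score is the arithmetic mean of log2-CPM rows; terciles come
from a stable sort split into three near-equal groups (empirical 1/3 and
2/3 quantiles for distinct scores; boundary ties resolved by stable
sample order; a constant score collapses to one group with a warning).
The log-rank test is the k-group Mantel–Cox statistic (lifelines), and
Kaplan–Meier curves are exposed for plotting only. Methylation context
takes the 10 probes nearest the locus **midpoint** (edge-distance mode
available), averages β per sample and uses Spearman correlation by
default (the monotone, outlier-robust choice; Pearson by flag), with BH
across proviruses and labels demethylation/methylation at padj < 0.05.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes,
not real biology. Reference conditions, chosen once: 200 proviruses, one
cancer type with 100 tumor and 20 matched peritumoral samples, four
sorted-PBMC samples per class, 10 planted cancer-associated proviruses
at log2 effect +2 (the first 5 being the planted cyt set), shared NB
dispersion 0.1, mean 1e5 provirus-mapped reads per sample (lognormal
depth jitter, sd 0.2 in log), signature noise at 0.5 × the signal's
standard deviation. Peritumoral samples share per-provirus baselines
with their matched tumors; signatures are unit-weight sums of the
planted cyt proviruses' log2-CPM plus Gaussian noise, clipped at zero
for count-like phenotype scores. Sequences embed reverse-translated
reference-protein fragments (uniform synonymous codon choice — the
homology filter works on amino acids) bracketed by in-frame stop codons,
at a random frame and strand inside random background DNA, so each
embedding yields exactly one ORF equal to the fragment. Survival times
are exponential with hazard ∝ HR^score (HR = 0.6 per unit, protective)
under uniform administrative censoring; methylation β values decrease
with expression near designated loci and are Beta(2,2) elsewhere.

Every generator is bit-reproducible from `rng_seed` via derived
substreams. What the passing tests therefore show: the pipeline recovers
exactly the structure it assumes, at realistic effect sizes and noise,
with calibrated error rates. What they do not show: robustness to batch
effects, provirus-family multi-mapping ambiguity, phylogenetically
correlated sequences, non-NB overdispersion structure, or confounded
immune signatures — none of which the generator attempts to mimic.

## Problem sizes in the validation studies

Recovery studies average 10 seeded cohorts at the reference condition;
calibration uses 200 null replicates (100 proviruses, 20 vs 20 samples)
for the NB Wald test and 200 replicates of 50 + 50 subjects for the
log-rank test; log-rank power uses 100 replicates at hazard ratio 3 with
40 + 40 subjects and ~50% censoring. These sizes give Monte-Carlo
standard errors comfortably inside the accepted bands while keeping a
full validation run around a minute on a single core.

## Known limitations

- The NB test's per-feature moment dispersion is noisier than shared
  estimators at very small n; below ~8 samples per group calibration
  degrades.
- The anchor-heuristic binding stub must never be used for real
  candidate nomination.
- E-values use fixed Karlin–Altschul constants rather than
  composition-adjusted statistics.
- The cumulative score inherits whatever p-value convention the DE table
  used; mixing adjusted and raw π values across comparisons is the
  caller's responsibility.
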