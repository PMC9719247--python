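# Methods

## Coordinates and the promoter window

All coordinates are 0-based half-open (BED convention). The promoter
window of a transcript is `[tss − 1000, tss + 1000)`: exactly 2000 bp,
independent of strand. "Coverage around the TSS" is the *depth-summed*
weighted base coverage of that window — the sum over fragments of their
bp overlap with the window times their weight — which is what an
RPKM-like normalization that divides by the window length presupposes
(a fragment-count definition was considered and rejected on those
grounds). Normalization is `C × 10⁶ / (N × 2000)` with `N` the unweighted
total mapped read count; GC weights reshape coverage but never the
library size. Strand matters only for meta-profiles, where minus-strand
windows are mirror-flipped so positive offsets always mean downstream;
window sums are symmetric and therefore orientation-free.

Per-transcript values are collapsed to gene level by the arithmetic mean
over the gene's transcripts. The collapse rule is a package choice
(transcript-to-gene aggregation for this statistic has no canonical
definition); a transcript-level mode remains available by skipping the
collapse.

Input BAMs are assumed aligned and deduplicated upstream; reads flagged
as duplicates are dropped with a warning rather than silently counted.
Alignment, duplicate removal and copy-number/tumor-fraction estimation
are out of scope — tumor fraction enters only as a sample-sheet column.

## GC reweighting

A simplified binned correction replaces an external GC-correction tool:
fragments are binned by GC fraction (50 bins by default) and each bin's
weight is expected rate / observed rate, with the expectation taken from
a reference sample of genome GC content when supplied and from a uniform
rate across occupied bins otherwise (crude, but serviceable when no
genome reference exists). Weights are capped to [0.2, 5] so sparse bins
cannot blow up; empty bins keep weight 1. Correction is off by default.
Quality is judged functionally — the GC-vs-rate trend must shrink on
simulated biased data — not by bit-matching any external tool.

## Synthetic cohorts

The generator emulates the study conditions the pipeline targets:
low-coverage (~0.3×) single-end plasma WGS with mono-nucleosome fragment
sizes, two patient classes differing in promoter coverage at a
controllable fraction of genes, clinical covariates, and a per-sample
tumor fraction.

Gene truth: a configurable fraction (default 25%) of genes are
housekeeping-like with activity drawn U(0.8, 1), the rest U(0, 0.4);
`round(frac_diff × n_genes)` genes are flagged differential, given
activity U(0.4, 0.6) (headroom for class scaling) and a fold change `fc`
with direction (coverage increased or decreased in ALN-positive)
randomized per gene — consistent with differential genes moving in both
directions. Sample truth: binary ER/PR/Her2/Ki67, ordinal T-stage and
grade drawn from the overall marginal frequencies of the 330-patient
cohort design; age ~ N(51.4, 10²) years clipped to [25, 90]; tumor
fraction ~ Beta(2, 18) (mean 0.1 — low-burden early disease; the study
itself found tumor fraction nearly uninformative for ALN status, so only
its scale matters here).

Fragment-level path: per sample, `round(depth × L / 167)` fragments are
placed by rejection sampling from a flat midpoint intensity minus a
Gaussian-shaped depletion of relative depth `ndr_depth × activity`
(σ = 150 bp) at each TSS, with a faint phased-nucleosome cosine ripple
(period 190 bp) outside the depleted core. The fragment count is
deterministic at its expectation, so requested and realized coverage
agree exactly up to length jitter. Fragment lengths are truncated normal
(167 ± 15 bp, clipped to [50, 334]). Differential genes scale their
depletion per class by √fc in each direction. GC content comes from a
smooth sinusoidal landscape around 0.41; when `gc_bias_strength ≠ 0`
fragments are additionally thinned by a logistic function of GC, giving
the correction something real to remove. Defaults (167/15 bp, 150 bp NDR
scale, 190 bp spacing, 0.3×) are conventional cfDNA values; the depth and
class design mirror the study, the rest is not data-derived.

Matrix fast path: for classifier-scale experiments the gene-level matrix
is drawn directly — class means with ratio exactly `fc` split
symmetrically (±√fc) about a base mean that decreases with activity,
lognormal noise with coefficient of variation `noise_cv` (default 0.25;
`noise_cv=0` returns the means exactly, and the lognormal is
mean-parameterized so empirical class-mean ratios converge to `fc`).

What the simulator does **not** emulate: real sequence (no error model,
no real genome, no mappability or copy-number structure), paired-end
reads, duplicates, between-sample library-size variation, or correlation
between genes. Passing tests therefore demonstrate correctness of the
machinery and recoverability of injected signal under clean conditions —
not expected performance on real plasma data, where the printed
real-data AUCs (training 0.936, validation 0.808, pooled 0.897) are not
reproducible because no raw cohort data is deposited.

## Differential screen

Per feature: two-sided Wilcoxon rank-sum (exact null distribution when
the smaller group has ≤ 8 observations and no ties, otherwise normal
approximation with tie and continuity corrections; all-identical input
gives p = 1 by convention), Benjamini–Hochberg step-up FDR across
features, and a fold change defined as
`max(mean_pos/mean_neg, mean_neg/mean_pos)` on class means with a 10⁻⁶
pseudocount on both — so FC ≥ 1 always, direction is reported separately,
and zero means cannot divide by zero. Means (not medians) are used.
Significance = FC ≥ 1.5 and FDR ≤ 0.05. The screen defaults to gene
level; sidedness and the FC definition are package choices where the
convention was open.

## Classifier

All three models are linear on standardized features: SVM with linear
kernel and cost 1 (the conventional default), logistic regression without
penalty, and LDA; each is scored by its continuous decision value.
Standardization constants always come from the data the model is fitted
on (each LOOCV fold separately; the full training cohort for the frozen
validation model).

Ranking is recursive feature elimination: repeatedly fit the linear SVM
and eliminate the feature with the smallest |weight|, breaking ties by
eliminating the larger Welch-t p-value first; rank is the reverse
elimination order. This approximates importance ranking of the
SVM-RFE/t-statistic family; a one-shot |weight| ranking is available for
speed. Constant features rank last with a warning.

Backward selection starts from the top-k ranked features (k = 100 by
default, clipped to the feature count) and, in the default rank-ordered
mode, drops the lowest-ranked feature one at a time, recording the LOOCV
AUC at every size; the returned subset maximizes AUC with ties resolved
toward the smaller subset. A greedy mode (remove whichever feature most
improves the AUC, stop at no improvement) exists behind a flag; the
rank-ordered path is the default because it is O(k) LOOCV evaluations
and fully reproducible.

AUC is the Mann–Whitney concordance statistic (ties count ½); its
variance comes from DeLong placement values, the 95% CI is the normal
approximation clipped to [0, 1], and paired AUC comparisons use the
DeLong covariance of placements (identical score vectors give p = 1 by
convention; perfectly separated scores legitimately have zero DeLong
variance). Strata are compared with the unpaired normal-theory version.
The operating point is the Youden-optimal threshold (max sens + spec − 1,
ties toward higher specificity), a package choice where the threshold
rule was unstated. The "all cohorts" evaluation pools training LOOCV
scores with validation decision scores into one ROC (score pooling, not
AUC averaging). ALN-positive is the positive class throughout.

Validation hygiene: the frozen model carries its features,
standardization constants and coefficients from the training cohort only;
a byte-level test verifies that scrambling validation labels changes no
training artifact. Covariate combination appends encoded covariates
(binary 0/1, tumor fraction real) to the selected genes and re-evaluates
all 2^m − 1 non-empty combinations plus the gene-only baseline with
LOOCV; missing covariate values are an error, never imputed.

## Cohort statistics

The 7:3 split is stratified by class with round-half-up sizing
(`floor(0.7·n + 0.5)`), the unique rounding consistent with cohort sizes
113/49 and 118/50 from 162 and 168.

Balance tests per covariate: Wilcoxon rank-sum for continuous; for
categorical, a levels × cohort contingency table tested by Yates
chi-square (2×2), Pearson chi-square (larger), or Fisher's exact test
whenever any observed cell is below 5. The observed-cell rule (rather
than the textbook expected-count rule) is what matches the published
table's footnote assignments row for row. The Yates correction floors at
zero — each cell contributes `(|O−E| − min(0.5, |O−E|))²/E` — which is
required to reproduce a printed p of exactly 1 on a near-null 2×2 table.
The r×c Fisher test enumerates all tables with the observed margins and
sums the probabilities of those no more probable than the observed table
(the R convention, with a 10⁻⁷ relative tolerance), falling back to
Monte-Carlo sampling of margin-preserving tables (10⁶ draws) when the
enumeration would exceed a configurable cap. Age balance p-values from
the published table need raw ages, which are not printed; they are not
reproducible and not attempted.

## Problem sizes and determinism

Test and acceptance runs use desk-scale sizes chosen to make the
statistical assertions stable: null FDR control on twenty 15-vs-15
cohorts of 2000 genes; parameter recovery on five 330-sample cohorts of
600 genes (5% differential, fc = 2, noise CV 0.25) through the full
screen → rank → backward-select → LOOCV → validation chain; the
fragment-level run on thirty samples at 0.05× over a ~2 Mb chromosome
with 500 genes and deep (0.9) promoter depletion. Every stochastic
component takes an explicit seed; fragment simulation is deterministic
per (seed, sample index), and pipeline reruns with the same configuration
produce byte-identical tabular artifacts (each stamped with a config
hash).

## Known limitations

- Gene-level collapse by transcript mean is one of several defensible
  rules; results at transcript level can differ.
- The rank-ordered backward path explores only nested subsets of the
  initial ranking; the greedy mode is broader but O(k²) and still not
  exhaustive.
- The DeLong normal CI can be anti-conservative near AUC 1 with small
  cohorts (it is clipped, not transformed).
- The uniform-expectation GC fallback assumes the genome GC distribution
  is flat across occupied bins; supply a reference GC sample whenever one
  exists.
- The simulator's independence assumptions (genes, samples) make
  recovery tasks easier than real cohorts; treat recovery metrics as
  machinery checks, not performance claims.
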