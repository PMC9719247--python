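# cfpromoter

Promoter profiling of circulating cell-free DNA (cfDNA) for predicting
axillary lymph node (ALN) status in breast cancer — as a tested, reusable
Python pipeline with a built-in synthetic-data generator, so every stage
runs end to end without any external download.

Plasma cfDNA is released mainly by apoptotic cells; DNA wrapped around
nucleosomes survives digestion while exposed linker DNA does not, so
low-coverage whole-genome sequencing of plasma carries a *nucleosome
footprint* of the cells of origin. At actively transcribed genes the
promoter sits in a nucleosome-depleted region, so cfDNA coverage around
the transcription start site (TSS) drops as gene activity rises. This
package computes that per-transcript statistic, screens for genes whose
promoter coverage differs between ALN-positive and ALN-negative patients,
and builds classifiers from the differential genes.

It is aimed at computational biologists working on cfDNA fragmentomics and
liquid-biopsy classifiers who need the complete chain — coverage
extraction, normalization, differential screen, feature selection, and
cross-validated evaluation — in one place with the statistics pinned down
by tests.

## The statistic

For each transcript the promoter window (pTSS) is the ±1 kb region around
the TSS, half-open and exactly 2000 bp. With `C` the depth-summed cfDNA
coverage in that window, `N` the total mapped reads of the sample and
`L = 2000`, the normalized promoter profiling is the RPKM-like quantity

```
normalized promoter profiling = C × 10⁶ / (N × L)
```

Low values mark active (nucleosome-depleted) promoters. Downstream:

- **Differential screen** — per gene, a two-sided Wilcoxon rank-sum test
  between classes with Benjamini–Hochberg FDR across genes; significant
  when fold change ≥ 1.5 and FDR ≤ 0.05.
- **Classifier** — SVM-RFE-style feature ranking, top-100 selection,
  backward elimination along the ranking maximizing leave-one-out
  cross-validated AUC, for linear-kernel SVM, logistic regression and LDA;
  AUCs carry DeLong standard errors, 95% CIs and paired comparison tests.
- **Cohort statistics** — stratified 7:3 train/validation split and
  Table-1-style balance tests (Wilcoxon / Yates chi-square / Fisher exact,
  including an exact r×c Fisher test).

## Worked example

Simulate a 330-patient cohort (162 ALN-positive / 168 ALN-negative) in
which 5% of 600 genes carry a promoter-coverage fold change of 1.5, then
run the full modeling chain:

```python
import cfpromoter as cf

truth = cf.generate_cohort_truth(n_pos=162, n_neg=168, n_genes=600,
                                 frac_diff=0.05, fc=1.5, seed=7)
matrix = cf.simulate_profile_matrix(truth, noise_cv=0.8, seed=7)

train_ids, val_ids = cf.split_cohort(truth.samples, train_fraction=0.7, seed=7)
labels = truth.labels
train = cf.PromoterProfileMatrix(matrix.values.loc[train_ids], level="gene")

screen = cf.differential_screen(train, labels.loc[train_ids], fc_min=1.5, fdr_max=0.05)
hits = screen.loc[screen["significant"], "feature_id"].tolist()
print(f"differential genes: {len(hits)} of {truth.n_genes}")

model = cf.AlnClassifier(
    cf.PromoterProfileMatrix(train.values[hits], level="gene"),
    labels.loc[train_ids], model_type="svm",
)
results = model.fit(k_top=100)
print(results.summary())

validation = cf.PromoterProfileMatrix(matrix.values.loc[val_ids], level="gene")
ev = results.evaluate(validation, labels.loc[val_ids])
print(f"validation AUC {ev.auc:.3f} (95% CI {ev.ci95[0]:.3f}-{ev.ci95[1]:.3f})")
```

Output:

```
differential genes: 12 of 600
ALN-status promoter-profiling classifier
================================================
model:            svm (linear, standardized)
training samples: 231 (113 ALN-positive)
features ranked:  12 (rfe)
selected subset:  11 features
LOOCV AUC:        0.919 (DeLong 95% CI 0.885-0.954)
operating point:  sens 0.938, spec 0.797, acc 0.866 (Youden)
informative:      True
validation AUC 0.848 (95% CI 0.774-0.922)
```

The screen recovers 12 of the 30 injected genes at this noise level (FDR
control keeps false positives out; higher noise costs recall). The
11-feature SVM separates the classes with a LOOCV AUC of 0.919 on the 231
training samples and generalizes to the 99 held-out validation samples at
AUC 0.848 — the gap is the usual optimism of in-sample selection.

The same chain is available from the shell:

```bash
cfpromoter run --out results/demo --n-pos 162 --n-neg 168 --n-genes 600 --seed 7
cfpromoter report --dir results/demo
```

and stage by stage via `cfpromoter simulate | profile | diff | split |
train | evaluate` (fragment-level simulation, BAM/BED round-trips, GC
reweighting and TSS meta-profiles live in the `simulate`/`profile`
stages).

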