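# ckorgan

Organ-resolved analysis of cytokinin-dependent gene expression.

Cytokinin promotes growth in shoots and inhibits it in roots, and part of
that opposition plays out in organ-specific transcription. `ckorgan`
implements, as a tested and reusable pipeline, the analysis of a
two-organ × five-condition transcript-profiling design in *Arabidopsis
thaliana*: roots and shoots of seedlings that are mock-treated (BA0),
treated with 6-benzyladenine for 15 min / 2 h / 18 h (BA15, BA120,
BA1080), or constitutively cytokinin-deficient (CKX1, a *35S:CKX1*
cytokinin oxidase overexpressor), each condition measured on four
CATMA-style arrays (2 biological × 2 technical replicates, 40 arrays in
all) with common-reference hybridization yielding absolute log2
expression per array.

It is aimed at people re-analysing this kind of spotted-array experiment
or benchmarking organ-specificity calling on synthetic data with planted
ground truth.

## What it computes

1. **Detection filtering.** Per-gene counts of spots above background
   (AbB). Genes detected on < 4 arrays are "not expressed"; model fitting
   requires ≥ 10 detections; each analysis subset (induction: 32 arrays,
   deficiency: 16 arrays, sharing BA0) requires detection on ≥ 25 % of its
   arrays (8 and 4).
2. **Per-gene two-factor ANOVA.** For each gene,
   `value ~ organ + cytokinin + organ:cytokinin` is fitted by ordinary
   least squares on the gene's non-missing observations; type-II F-tests
   give p-values for the organ, cytokinin (or genotype) and interaction
   effects, corrected across genes by the Benjamini–Hochberg step-up
   ("q-values").
3. **Organ-specificity categorization.** Linear fold changes
   *r*(organ, *t*) = 2^(mean(organ,*t*) − mean(organ,BA0)) are gated at
   T = 2.5 (inclusive, both directions) and q ≤ 0.03; a decision list
   assigns each gene exactly one of *root-specific*, *shoot-specific*,
   *similar*, *differential*, *uncategorized*, *not regulated*,
   *not expressed*.
4. **Developmental-shift gene sets.** Genes whose expression moves toward
   the other organ's level: baseline root/shoot differential ≥ 2.5-fold,
   a ≥ 2.5-fold change toward the other organ (roots after 18 h of
   cytokinin; shoots under cytokinin deficiency), and at least one
   full-model q ≤ 0.03. The overlap of the two modes is partitioned by
   direction, and the fraction of members annotated with a subcellular
   localization code (uppercase `P` = plastid) serves as the
   "shootyness" diagnostic.
5. **Organ-effect normalization and ordination.** Per gene,
   norm(shoot, c) = raw(shoot, c) + mean_c raw(root) − mean_c raw(shoot)
   (roots unchanged), which zeroes the organ main effect exactly;
   covariance PCA of the 10 condition-mean profiles over a restricted
   gene set (AbB ≥ 10, min q ≤ 1e-4); and average-linkage support-tree
   clustering (correlation distance) with gene-resampled bootstrap
   supports, written as Newick.

A synthetic-data module generates the full design with planted gene
classes (organ-specific, similar, differential, three shift classes,
null, undetected) so every stage is testable without any download.

## Worked example

```python
import ckorgan as ck

design = ck.generate_design()                     # 40 arrays, 4 per cell
cfg = ck.SimulationConfig(n_genes=1000, seed=7)
matrix, truth, annotation = ck.simulate_dataset(cfg, design)

report = ck.apply_detection_filters(matrix, design)
eligible = report.index[report["induction_eligible"] == 1].tolist()
stats = ck.fit_all_genes(matrix, design, "induction", eligible)
ratios = ck.fold_change_ratios(ck.condition_means(matrix, design))
calls = ck.classify_induction(ratios, stats, report)
print(calls["category"].value_counts().to_string())

planted = truth.genes_of("root_specific")
print("root-specific recovery:",
      (calls.loc[planted, "category"] == "root_specific").mean())
```

prints

```
category
not_regulated     743
root_specific      87
not_expressed      50
similar            50
shoot_specific     50
differential       20
root-specific recovery: 1.0
```

The simulation planted 50 genes of each of the root-specific,
shoot-specific and similar classes, 20 differential, 60 shift genes, 50
undetected and 720 null genes. All 50 planted root-specific genes are
recovered; the 87 root-specific calls additionally contain the planted
shift genes whose root level changes at BA1080 — which is exactly how
those genes should appear in an induction-only analysis. The same
machinery runs from the shell:

```bash
ckorgan simulate --seed 7 --n-genes 1000 --out sim/
ckorgan fit --expression sim/expression.tsv --design sim/design.tsv \
        --subset induction --out stats.tsv
ckorgan run --config cfg.yaml        # full pipeline from a YAML config
```

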