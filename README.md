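# cellfp

Self-supervised single-cell feature profiling of protein localization from
fluorescence micrographs.

## What this is for

High-content imaging screens tag thousands of proteins with a fluorescent
reporter and image millions of single cells. Manually annotating what each
protein's localization pattern looks like does not scale, and supervised
classifiers can only rediscover the label vocabulary they were given.
`cellfp` implements a self-supervised alternative aimed at computational
biologists working with such screens: a convolutional network is trained on
a *pretext task* — predict which tagged protein a 64×64 single-cell crop
shows — and the activations of its second fully-connected layer are used as
a *single-cell feature profile* (scFP). Averaging a protein's scFPs gives
its *average feature profile* (aFP). The profiles, not the classifier, are
the product: proteins with similar subcellular morphology end up close in
profile space at every scale of organisation, from organelles down to
protein complexes.

On top of the profiles the package implements the associated analytics:

- **Benchmarking** of profile quality against annotation standards:
  ranked co-annotated-pair retrieval (average precision, max F1 with
  correlation distance = 1 − Pearson r) and clustering agreement (adjusted
  mutual information across dendrogram thresholds).
- **Hierarchy analysis**: average-linkage correlation dendrograms, an
  AMI-derivative elbow rule for picking biologically meaningful cutoffs,
  silhouette-selected sub-compartment clusters, t-SNE embeddings with
  Gaussian-KDE annotation.
- **Localization adaptation**: a multinomial logistic-regression probe on
  frozen scFPs (the linear evaluation protocol), coefficient-based feature
  importance, accuracy-vs-feature-count curves, and SmoothGrad gradient
  maps ∂f_i/∂x for interpreting individual features.
- **Heterogeneity calling**: per-protein classification into
  single-localizing, AND (two compartments in the same cell) or OR (either
  compartment, across cells) from per-crop localization probabilities, and
  association of localization changes with cell-cycle stage (CNN ensemble on
  the nuclear/cytosolic marker channels + Mann–Whitney U tests).
- **Complex discovery**: adaptive dendrogram thresholding over scFPs —
  plateau ("root") clusters scored by s = c·d/k — with k-means / DBSCAN /
  fixed-threshold hierarchical baselines.
- **Synthetic screens**: a generator of multi-channel micrograph fields
  with planted ground truth (localization archetypes, complexes, AND/OR
  heterogeneity, cell-cycle-dependent shuttling) so the whole workflow is
  testable end to end.

The neural-network core (conv blocks, batch norm, Adam with cosine decay,
input gradients) is implemented in numpy and verified against finite
differences; everything else builds on numpy/scipy/scikit-learn/
scikit-image/pandas/tifffile.

## Worked example

```python
from cellfp import make_protein_panel, generate_dataset, run_pipeline

report = run_pipeline({"seed": 1})
stages = report["stages"]
print("test accuracy:", round(stages["train"]["test_accuracy"], 3),
      "chance:", round(stages["train"]["chance"], 3))
print("heterogeneity verdicts:", stages["heterogeneity"]["verdicts"])
print("planted complexes recovered:", stages["complexes"]["recovered_complexes"])
```

This simulates a 12-protein screen (4 localization archetypes, 2 planted
3-member complexes, 2 AND and 2 OR proteins, one cell-cycle shuttler,
~100 cells per protein over 2 replicates × 4 fields of view), preprocesses
it into normalized 64×64 crops, trains a reduced network (2 conv blocks,
16-d feature layer, 30 epochs) and runs every analysis stage. Typical
output:

```
test accuracy: 0.636 chance: 0.083
heterogeneity verdicts: {'single': 9, 'AND': 2, 'OR': 1}
planted complexes recovered: 2
```

Accuracy far above the 1/12 chance level means the pretext task is learned;
it stays below 1.0 by construction, because members of a planted complex are
statistically exchangeable and cannot be told apart. Both planted complexes
are recovered as high-confidence root clusters. The verdict counts are close
to the planted composition (8 single, 2 AND, 2 OR): with ~100 cells per
protein, two borderline calls flip at this seed — an AND protein whose
mixed-cell fraction sits at 0.495 against the strict mixed-majority rule,
and the OR shuttler, whose nuclear crops the localization probe scores
least confidently.

The same pipeline is scriptable from the shell:

```bash
cellfp run-all --seed 1 --out runs/demo
cellfp simulate --seed 3 --out runs/sim-only
```

Stage outputs (scFP/aFP tables, cluster assignments, heterogeneity calls,
stage-localization links) are written as CSV/TSV with a provenance header
(config hash + seed).

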