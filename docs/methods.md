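# Methods

## The workflow in brief

`cellfp` implements a self-supervised protein-profiling workflow for
single-cell fluorescence micrographs. A convolutional network is trained on
a pretext task — predict which tagged protein a 64×64 single-cell crop
shows — with no localization labels at all. The penultimate
(second fully-connected) layer of the classifier is read out as a
*single-cell feature profile* (scFP); the per-protein mean of scFPs is the
*average feature profile* (aFP). Everything downstream operates on these
profiles: co-annotation benchmarking, dendrogram analysis, a linear
localization probe, AND/OR heterogeneity calling, cell-cycle association,
and protein-complex discovery by adaptive dendrogram thresholding.

Because the method's claims concern recovery of latent biological structure,
the package ships a synthetic micrograph generator with planted ground truth
(archetypes, complexes, heterogeneity types, cell-cycle dependence) so every
stage can be validated end to end without real data.

## Synthetic micrographs (`cellfp.synth`)

Cells are circles (radius 14 ± 1.5 px) placed without overlap in a
256×256 field; three channels are rendered: the tagged protein ("GFP"), a
nuclear marker (Gaussian blob, σ 3.5 px), and a cytosolic marker (soft cell
mask). A fourth page stores the noiseless GFP template, from which
per-crop ground-truth foreground masks are derived (template > 5% of its
in-crop maximum).

Localization archetypes are parametric templates in cell-local
coordinates: nuclear blob, cytoplasmic fill (nucleus-depleted), nucleolar
spot, punctate dots, peripheral ring, nuclear ring, ER-like mesh (perinuclear
ring plus radial strands), and mitochondrial-like filaments (momentum random
walks). Per-protein rendering parameters (dot counts, ring widths, blob
sigmas) are jittered inside each archetype so same-archetype proteins remain
distinguishable to the pretext task.

Cell-cycle stages follow resting-population frequencies
(G1 0.35, S 0.25, M/A 0.2, T 0.2) and drive morphology: a bud of growing
radius fraction (0 / 0.35 / 0.6 / 0.85 of the mother radius), an elongating
or divided nucleus in M/A, and a separate bud nucleus in telophase. The
cell-cycle classifier sees exactly these cues through the marker channels.

Key modelling choices:

- **Complex members are exchangeable.** Proteins sharing a `complex_id`
  share the archetype template parameters *and* the abundance draw. This is
  deliberate: planted complexes are defined as sets of proteins whose
  single-cell appearance is statistically indistinguishable, and any
  systematic intensity difference would both bias the dataset-wide
  5th-percentile filter against the dimmest member and hand the pretext task
  a shortcut for separating members.
- **AND-proteins split their pool by integrated intensity.** A protein
  present in two compartments in the same cell is rendered as a blend whose
  weights apply to the *total* (integrated) intensity of each compartment
  template, not to the template amplitude; otherwise a spatially extended
  pattern (cytoplasm) visually swamps a compact one (puncta) and the planted
  "AND" condition is not actually present in the image.
- **OR-proteins** draw one compartment per cell (secondary with probability
  0.4). The optional cell-cycle shuttler is an OR-protein whose compartment
  is a deterministic function of stage (nuclear except in M/A, cytoplasmic in
  M/A), modelled on nuclear/cytoplasmic shuttling transcription factors.
- **Noise** is additive Gaussian (σ = 0.05 in abundance units ≈ 5% of a
  typical foreground peak) with clipping at zero; per-protein abundance is
  log-normal (σ = 0.25). Both are modest, realistic values chosen once;
  the intensity filter, instance normalization and all analyses interact
  with them exactly as they would with camera noise and expression
  variation in real screens.

What the generator does *not* emulate: point-spread optics, 3-D structure,
illumination gradients, cell crowding/clumping, segmentation failure modes
beyond simple proximity, photobleaching, or biologically realistic texture.
Passing tests therefore demonstrate that the algorithms recover planted
structure under controlled conditions, not that they will perform equally on
real micrographs.

## Preprocessing (`cellfp.prep`)

Centers come from the nuclear channel: Otsu threshold → small-object
removal (< 9 px) → Euclidean distance transform → peak markers (min distance
6 px) → watershed; segment centroids closer than 10 px to the field border
are discarded. Crops are half-open 64-pixel windows `[c−32, c+32)`.
Filtering drops crops whose channel-0 total intensity falls below the
dataset-wide 5th percentile (ties kept) and crops whose channel-0 variance is
below `variance_floor` (default 1e−4; flat, background-dominated crops).
Proteins with fewer than 10 surviving crops are removed. The per-protein
8:1:1 train/val/test split shuffles with a protein-id-salted seed, so
assignment is independent of dataset ordering. Instance normalization
standardizes each channel of each crop to mean 0, variance 1; a constant
channel becomes zeros. Training-time augmentation draws uniformly from the
8 dihedral transforms (flips × 90° rotations).

## Protein-identity network (`cellfp.nn`, `cellfp.network`)

The backbone is a stack of convolutional blocks (3×3 conv, batch
normalization, ReLU), channel width doubling every second block, 2×2 max
pooling after every second block (after every block for very shallow
configurations, never shrinking the map below 4×4), followed by three
fully-connected layers. The second FC layer (pre-activation) is the feature
profile; a ReLU, dropout 0.05 and the classification layer sit above it.
Weights are initialized from a truncated normal (±2σ, σ = 0.1). Training
uses Adam (lr 1e−3) with cosine decay over the scheduled epochs,
cross-entropy loss, and batch size 128; weights are checkpointed every
epoch. The implementation is plain numpy (im2col convolutions,
explicit reverse-mode gradients); parameter gradients and input gradients
are verified against central finite differences in float64.

Checkpoint selection follows the saturation rule: stop at the first epoch
whose accuracy increments stayed below a threshold for 3 consecutive epochs.
The reference threshold is 0.5 percentage points; note that on a small test
split the increment is quantized at 100/n_test points per crop, so the
threshold only bites once the curve is genuinely flat. The curve used is
test accuracy by default (switchable to validation via
`early_stop_on="val"`).

The demo configuration (also used by the acceptance suite) is a reduced
network — 2 conv blocks, 8 base channels, 16-d feature layer — trained for
30 epochs on a 12-protein panel (4 archetypes, 2 planted complexes of 3,
2 AND and 2 OR proteins, one of them a cell-cycle shuttler, ~100 cells per
protein over 2 replicates × 4 fields). This trains in a few minutes on one
CPU.

At this problem size, aFPs are averaged over **all** of a protein's crops
rather than the test split only: a tenth of 100 crops gives per-protein
means too noisy to be useful, and the early-stopped network has had no
opportunity to memorize crop identity that averaging could leak.
Heterogeneity calling likewise uses all crops of a protein.

## Benchmarks (`cellfp.benchmarks`)

Co-annotation retrieval ranks all annotated aFP pairs by correlation
distance (1 − Pearson r). A pair is positive under the `exact` rule
(identical label sets; pathway/complex standards) or `half_overlap`
(|A∩B| ≥ 0.5·min(|A|,|B|); GO-style standards, switchable to
Jaccard ≥ 0.5). Scores: average precision and maximal F1 over cut points
(the operating point is unstated in the protocol, so the maximum is
reported, with a fixed-threshold variant available). Clustering quality:
average-linkage correlation dendrogram cut at similarity thresholds
0.10–0.95 (step 0.05), clusters of size < 2 dropped, AMI (scikit-learn,
arithmetic normalization) against the single-label protein subset; the
maximal AMI over thresholds is reported.

## Dendrogram cutoff and sub-compartments (`cellfp.hierarchy`)

The cutoff rule computes the AMI curve over correlation thresholds 0–1
(step 0.01) and scans downward from 1, choosing the first threshold where
the slope over a 20-step window, (AMI(t) − AMI(t + 0.2)) / 0.2, is below
0.1 in magnitude — the diminishing-returns elbow. If the rule never fires
the max-AMI threshold is returned with a warning. On a 12-protein panel the
curve is a step function and the window (0.2 in threshold units) can exceed
the width of the optimal plateau; this is a known small-sample limitation
of the windowed rule and the main reason the planted-partition recovery is
the most seed-sensitive of the acceptance properties.

Sub-compartment clustering builds one correlation/average-linkage tree per
localization group (≥ 3 profiles) and picks the distance threshold in
0.25–0.75 (step 0.05) maximizing the median correlation-silhouette
(b − a)/max(a, b) across groups.

t-SNE embeddings (perplexity 40 for aFPs, 200 for large scFP sets) are
annotated with per-label Gaussian KDEs (Scott's rule) after removing points
beyond two standard deviations of the mean on either embedded axis.

## Localization probe and gradient maps (`cellfp.locmap`)

The localization head is a multinomial logistic regression on frozen scFPs
of single-localizing proteins, trained with Adam (lr 1e−3) and
cross-entropy, checkpointed per epoch, selected by maximal validation
accuracy. The reference protocol trains 5 epochs; because an epoch here is
a few dozen updates rather than ~10⁴, the demo keeps lr and the selection
rule but runs 60 epochs with batch 32 so the optimizer receives a comparable
update budget. Feature importance assigns each feature to the class of its
maximal coefficient (ties to the lowest class index; "strong" above 5), and
the accuracy-vs-feature-count curve retrains the head on top-N features
(5 repeats, mean ± SD).

Gradient maps are SmoothGrad on individual features:
M̂_i(x) = (1/n) Σ ∂f_i/∂(x + ε), ε ~ N(0, σ²), with n = 100, σ = 0.05 in
normalized-intensity units; σ = 0, n = 1 gives the plain gradient, which is
verified against finite differences. A quantitative caveat: on these
synthetic crops the absolute gradient mass inside the true foreground mask
is low (≈ 0.1 for a punctate protein) for every feature — the
instance-normalized background is nonzero over ~94% of the crop and every
pixel keeps a linear gradient path through the flatten→dense layers of a
shallow network — so gradient maps should be read as relative highlighting,
not as segmentation.

## Heterogeneity and cell cycle (`cellfp.heterogeneity`)

For each protein the two most frequent localization classes (by mean LR
probability over its crops) define per-crop pairs (p₁, p₂). A crop is
low-confidence if p₁ + p₂ < α_conf (0.5); otherwise primary if
p₁ > p₂ + β (β = 0.5), secondary if p₂ > p₁ + β, mixed in between. With
category fractions c₁, c₂, m, k: undetermined if k exceeds 0.5 (the
unquantified "too many low-confidence" is operationalized as one half);
AND if m > c₁ + c₂; else OR if min(1, c₂) > 0.08 — implemented literally,
with a `min(c₁, c₂)` variant behind a switch since the literal expression
reduces to c₂; else single.

The cell-cycle classifier is an ensemble of three CNNs (default 4 conv
blocks + 2 FC layers; the demo uses a 2-block reduction) on the nuclear +
cytosolic channels, predicting G1/S/MA/T, trained with three-fold
cross-validation (one fold per member as validation), Adam 5e−4, dropout
0.05, and heavy augmentation (arbitrary-angle rotation, flips, ±2% zoom,
shifts up to 9 px). Member checkpoints maximize validation accuracy; the
ensemble probability is the member mean, and T and G1 are merged for
reporting (T/G1, S/G2, M/A). Stage–localization links use a two-sided
Mann–Whitney U test on per-crop merged stage *probabilities* (the test needs
ordinal data; hard labels would discard most of the information) between
primary- and secondary-assigned crops, reported below p = 1e−3.

## Complex discovery (`cellfp.complexes`)

scFPs are clustered (correlation, average linkage) and the dendrogram is
traced top-down in 0.05 steps starting just below the final merge. A *root
cluster* is the coarsest cluster (≥ 2 proteins) whose protein composition
survives its branch's next actual division with Jaccard ≥ 0.95 — levels at
which a branch does not divide are no-ops and are skipped, as is the
degenerate zero-distance level; once a root is accepted its branch is not
descended further, so roots are disjoint. Scores: cell ratio c = mean over
member proteins of the fraction of that protein's scFPs inside the cluster;
elbow point k = the correlation distance of the root's cut (floored at
1e−4); descendant ratio d = the fraction of descendant clusters (flat
clusters at the next two finer evaluated levels inside the root) that agree
with the root, where each protein is annotated to the root holding the
plurality of its scFPs and a descendant agrees when ≥ 50% of its scFPs
belong to proteins annotated to this root. (The naive reading — descendants'
scFPs lying inside the root — is vacuously true for hierarchical
descendants, so agreement is defined through protein annotation.) The final
score is s = c·d/k with a high-confidence cutoff of 0.6.

Baselines for comparison: k-means over k = 5…500 (step 5, clipped to the
sample count), DBSCAN over ε = 0.1…5 (step 0.1) on the precomputed
correlation-distance matrix, and flat dendrogram cuts at 0.05…0.5 (step
0.025); each family reports its best hyperparameter by median per-cluster
pairwise F1 against the complex standard. Pairwise F1 marks a pair of scFPs
positive when their proteins share a complex (proteins without annotations
are left out); per-cluster F1 takes the cluster's internal pairs as
predictions and the co-complex pairs touching the cluster as the relevant
truth.

## Numerical and degenerate-input policies

- Correlation distance of a constant profile is undefined: refused with the
  offending profile named.
- Percentile-filter ties at the boundary are kept; an all-identical dataset
  rejects nothing.
- Constant crops normalize to zeros (and are rejected upstream as
  background-dominated).
- AMI evaluations restrict to singly-annotated proteins; thresholds with
  fewer than two surviving proteins yield NaN and are skipped.
- All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; reruns with the same config and seed produce
  identical manifests, splits and profiles.

## Known limitations

- The windowed AMI-derivative cutoff is designed for curves with thousands
  of proteins; with 12 aFPs it can land below the optimal plateau when that
  plateau is narrower than the 20-step window.
- The accuracy-saturation early-stopping rule is quantized by the test-split
  size; on a 118-crop test set only exactly-flat stretches trigger it.
- Gradient maps on shallow networks are diffuse (see above).
- The numpy backbone is single-threaded apart from BLAS matmuls; it is
  sized for desk-scale experiments (thousands of crops), not screens with
  millions.
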