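# Methods

## Model and procedure

`normatlas` treats normal histology removal as a novelty-detection problem.
Patch feature vectors from slides known to contain only normal tissue are
pooled and used to fit a one-class classifier; at inference the fitted model
labels unseen patch vectors as inliers (normal) or outliers (abnormal).  The
training pool is assumed contaminated with a small fraction of non-normal
material — scanning artifacts, tissue folds, stain sediment, pen markings and
out-of-focus regions — and no cleaning is attempted: the one-class methods
absorb the assumption directly.  For the one-class SVM, ν upper-bounds the
fraction of training margin errors (default 0.05); the Isolation Forest uses
its automatic path-length offset (points shorter than the average-path score
are outliers), with 100 trees and subsamples of 256.

The retrieval engine follows the Yottixel design.  A slide's candidate
patches are clustered into 9 groups by k-means on 24-dim RGB histograms
(8 bins per channel, L1-normalized per channel) and `max(1, ceil(0.15 * n_c))`
patches per cluster are selected via a second k-means on patch centers,
keeping the member nearest each spatial centroid — about 15% of the patches,
spread over the slide.  Slide-to-slide distance is the median over query
patches of each patch's nearest Euclidean neighbor in the target bag
(direction query→target; a symmetrized mean of both directions is available
behind a flag but is not the default).  Even-count medians are the mean of the
two central values.  Retrieval is a linear scan; ranking ties break
lexicographically by slide id for reproducibility.

The three-setup experiment mirrors the intended use: the same slides are
indexed (1) with the plain mosaic, (2) with the mosaic pruned by an Isolation
Forest atlas, and (3) pruned by a one-class-SVM atlas.  Leave-one-patient-out
evaluation queries each indexed slide with its patient's slides excluded and
scores top-1 labels and top-3/top-5 majority votes.  A query slide whose whole
mosaic is pruned as normal is labeled "normal" with no search; an indexed
slide left without vectors is excluded from distance ranking (the alternative
— treating such entries as label-only "normal" sentinels — was considered and
rejected because a sentinel cannot be ranked by distance).

## Parameters

| parameter | default | meaning |
|---|---|---|
| patch_size | 1024 px | side of a square patch at the extraction power |
| overlap | 0.30 | fractional overlap between adjacent patches; stride = floor(1024 × 0.7) = 716 px |
| min_tissue | 0.75 | minimum tissue coverage to keep a patch (inclusive) |
| magnification | 20× | objective power of the extraction pixel space |
| annotation threshold | 0.50 | minimum annotated area to call a patch abnormal (inclusive) |
| n_color_clusters | 9 | mosaic color clusters |
| selection_fraction | 0.15 | per-cluster mosaic selection fraction |
| ν | 0.05 | assumed contamination of normal training slides |
| k | 1, 3, 5 | consensus sizes for retrieval voting |

Slides without a recorded objective power are rejected; a native power above
the target is downsampled by the ratio, never upsampled.

## Tissue segmentation

Background on a scanned slide is bright and unsaturated, while H&E-stained
tissue is saturated, so the mask is the saturation channel thresholded by
Otsu's method (with an absolute floor of 0.05 so nearly empty slides do not
threshold noise), plus very dark pixels (value ≤ 0.25: pen ink, dense stain).
Binary closing (disk radius 2) and removal of components under 64 mask pixels
clean the result.  The provider is deliberately interchangeable: any model
producing a binary mask with a scale factor can replace it.  Coverage
fractions are evaluated at mask resolution with floor/ceil footprint mapping;
exactness at full slide resolution is not required, which is why the grid
drops partial edge tiles instead of clamping them (the 75% coverage rule
would discard most clamped tiles anyway).

## Synthetic data: what it emulates

The feature generator encodes the statistical premise of the method rather
than histology itself:

* **Normal tissue is dense and multi-modal.**  Three mode centers sit on a
  circle in a random (seeded) 2-plane with pairwise separation exactly 3σ —
  distinct but compact morphologies.  Patches draw i.i.d. from a random mode
  plus isotropic N(0, σ²) noise (σ = 1, d = 16).
* **Abnormal tissue is displaced and heterogeneous.**  Each disease class has
  one abnormal center displaced 6σ from its anchor mode in a random direction
  (no closer to any other mode), and its patches scatter with 3× the normal
  standard deviation (`abnormal_spread = 3`).  The spread is essential, not
  cosmetic: a displaced cluster that is as *dense* as the normal modes is not
  an anomaly to an Isolation Forest — isolation scores respond to sparsity,
  and tumor morphology is in fact far more variable than normal tissue.
* **Artifacts are far outliers with shared structure.**  Normal slides
  receive `round(0.05 × n)` artifact vectors drawn around a small number of
  dataset-level artifact modes placed ≥ 10σ from every normal mode.  Shared
  modes reflect that pen ink, folds and blur look alike across slides; this
  is what lets normal slides still retrieve each other after pruning leaves
  them with artifacts only, while keeping every artifact an extreme outlier
  the atlas should flag.

Defaults are the study conditions: three classes (one normal, two disease
with 60% abnormal patches) of 20 slides each, 60 patches per slide, 20
additional normal slides for atlas training, one slide per patient.  Every
patch carries its true normal/abnormal flag and synthetic grid coordinates,
so pruning and retrieval can be audited exactly.

What the generator does *not* model — stain variation, spatial correlation of
feature vectors within a slide, class imbalance across patients, continuous
grades of differentiation, extractor-specific geometry of real embeddings —
limits what passing tests show: they demonstrate that the atlas lifecycle,
the pruning contract, the bag distance and the LOPO bookkeeping behave as
specified under the model's own assumptions, not that any particular feature
extractor separates real normal from abnormal histology.  On real data the
patch-level validation (annotation masks, the 50% rule, precision/recall/F1)
is the intended gate before trusting an atlas in the pipeline.

The slide-image generator produces smooth tissue blobs of correlated pink
noise on a white background with a disk-shaped lesion of controlled relative
area (chosen by quantile of distance within the tissue, so the planted
fraction is exact to one pixel); it exists to integration-test the
patching/masking/labeling path, not to imitate histology texture.

## Numerical choices

* **Stride rounding**: floor(patch_size × (1 − overlap)), guaranteeing at
  least the nominal overlap (716 px for 1024/30%).
* **Boundaries are inclusive**: tissue coverage ≥ min_tissue keeps a patch;
  annotated fraction ≥ 0.5 labels it abnormal.
* **Feature standardization**: per-dimension z-scoring is fitted on the
  training pool and stored in the atlas; RBF kernels are scale-sensitive and
  embedding dimensions vary in magnitude.  The Isolation Forest receives the
  same standardized input for consistency.  Near-zero scales are clamped to 1.
* **RBF bandwidth**: scikit-learn's "scale" heuristic, 1/(d · var), exposed in
  `AtlasConfig.kernel_scale`.
* **k-means determinism**: both clustering stages run on patches in canonical
  (y, x) order with a fixed seed and `n_init=10`, making mosaic selection
  deterministic and invariant to input order; spatial picks break distance
  ties by smaller (y, x).
* **Per-cluster selection count**: `max(1, ceil(f · n_c))` so no non-empty
  color cluster goes unrepresented (the original mosaic's rounding is
  unspecified; this floor is our choice, documented, not claimed original).
* **Degenerate metrics**: F1 with a zero denominator is 0; weighted F1 weights
  per-class F1 by true-class support.
* **One atlas per organ/site**, fitted on all normal patches pooled (not
  per-slide), recording the extractor id and refusing mismatched features;
  the same atlas is used at index and query time.
* **Color normalization** is exposed only as an optional hook in the feature
  registry; no method ships as default.
* **Seeding**: `run_pipeline` derives per-stage seeds from the single global
  seed (simulation = seed, mosaic = seed + 1, atlas = seed + 2); seed fields
  inside config subsections are accepted but overridden by the global seed.

## Problem sizes

The test suite and the acceptance script run the feature study at its default
size (60 labeled + 20 training slides, 60 patches each, d = 16), patch-level
validation on 1000 + 1000 held-out vectors, the distance oracle on 1000
random bag pairs, and image-path checks on 512–1536 px synthetic slides —
sizes chosen so the entire study re-runs from scratch in well under a minute
while keeping every statistical check comfortably powered.

## Known limitations

* The pruned pipeline's retrieval quality on the synthetic dataset *exceeds*
  the unpruned baseline because pruning strips the normal patches that blur
  between-class contrast; on real data the original study design anticipates
  performance being maintained rather than improved, with a known cost to the
  normal class (pruned normal slides are represented mainly by artifacts).
* Deep extractors (KimiaNet, DINO ViT/ResNet50) are interface-only; built-in
  extractors are deliberately trivial.
* The bag distance is asymmetric (query→target); symmetrization is available
  but unvalidated against the original engine.
* Wall-clock timing is recorded in logs only and never asserted — it is
  hardware-dependent.
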