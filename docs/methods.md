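# Methods

## Data model

A slide is an `H x W x 3` uint8 raster with a micrometers-per-pixel (MPP)
resolution; the magnification convention is 10x = 1.0 um/px (40x scanners at
~0.25 MPP, downsampled x4), configurable through `rescale_to_target`. Label
masks are single-channel integer rasters under a `ClassScheme`; the default
scheme ships 12 codes — 11 tissue classes (tumor, tumor stroma, benign
mucosa, submucosa, smooth muscle, adventitia, vessels, lymphoid,
ulceration/necrosis, mucin, bleeding) plus background — with `ignore_code =
255` for pixels excluded from loss and scoring. Tiling is 0-based, half-open
and row-major; the final tile start per axis is clamped to `dim - patch` so
edge pixels are covered without synthetic padding. Annotated training slides
tile with overlap (default stride = patch − overlap, 384 for 512 px patches
at full scale), unlabeled slides without overlap.

## Similarity assessment

Tumor patches (strictly more than 60% tumor area; manual masks on annotated
slides, tumor-locator predictions on unlabeled ones) are embedded and each
slide is summarized by the `k = 5` member vectors nearest to the K-means
centroids of its embedding cloud. Slide similarity is the mean over the full
`k x k` grid of pairwise metric values (25 comparisons at the default k);
cosine is the default metric, L1/L2 distances are negated so "most similar =
arg-max" holds for every metric. Ties in expert matching break to the
lexicographically smallest annotated id.

Two numerical choices deserve note:

* **Exact clustering at tiny n.** Lloyd's algorithm with k-means++ and 10
  restarts regularly misses the global minimum-SSE partition when n is close
  to k (observed on ~30% of random draws at n <= 8, k = 5). For n <= 10 the
  partition is therefore solved exactly by enumerating restricted growth
  strings; larger inputs use Lloyd (k-means++, 10 restarts, tol 1e-6, fixed
  seed). Representative selection per cluster is centroid-nearest with ties
  to the lowest row index, so the result is always a verbatim member of the
  slide's embedding set. `k_eff = min(k, #distinct vectors)`: slides with
  very little tumor collapse to fewer representatives instead of erroring.
* **Overlapping similarity tiling at toy scale.** At full scale a tumor
  region spans hundreds of 224 px patches, so plain tessellation leaves
  thousands of qualifying patches. On 256 px synthetic slides it can leave
  fewer than k; similarity patch extraction therefore defaults to stride =
  patch/2, restoring the patch-abundance regime. Pseudo-label prediction
  tiles remain non-overlapping.

Embeddings are not L2-normalized: cosine similarity is scale-invariant by
definition, and the negated L1/L2 metrics operate on raw vectors (documented
behaviour, relevant when comparing metrics).

## Encoders

The built-in encoder is a deterministic hand-crafted descriptor (d = 32):
per-channel 8-bin intensity histograms, each normalized to sum 1, plus an
8-bin magnitude-weighted gradient-orientation histogram of the luminance
channel (all-zero for gradient-free patches, which keeps uniform patches
distinguishable by colour alone). It is a pure function of pixel content and
separates the synthetic morphology styles; it is not a learned model and
makes no claim to histological feature quality. Foundation encoders (UNI,
Prov-Gigapath, ...) plug in through `external_encoder_adapter`, which probes
output length, finiteness and determinism at registration; their weights are
deliberately not part of this package.

## Model roles and backends

Each expert trains on one annotated case (deterministic 90/10 patch split,
`|val| = max(1, round(0.1 n))`); the supervised model pools all annotated
cases with the split applied at the pooled level; the tumor locator collapses
the scheme to tumor / non-tumor / background (by default only the tumor class
maps to "tumor"; `stroma_as_tumor` switches this) and is used solely to find
tumor patches on unlabeled slides. Class weights are inverse-frequency,
`w_c = N / (K n_c)` over the K observed classes, with unobserved classes at
the maximum observed weight. Training runs a fixed number of epochs (default
36, step-decay learning rate every 10 epochs, no early stopping) and keeps
the epoch with the best validation mean foreground Dice. All models of a
pool share one `init_checkpoint_id`; for the deterministic built-in backends
this token doubles as the shared initialization seed, which also makes the
whole pool build bit-reproducible.

Two backends ship, both sklearn-style estimators:

* `centroid` — per-class RGB centroid classifier. One pass, no
  hyper-parameters, deliberately *unimodal*: it cannot represent a class
  whose colour differs across cases.
* `softmax` — a per-pixel one-hidden-layer softmax network (numpy; Adam,
  class-weighted cross-entropy, StepLR schedule, per-patch pixel
  subsampling). Multimodal in colour space.

A full-scale convolutional encoder-decoder (EfficientNetB0 + UNet++ or
similar) is an optional backend behind the same registry and is not required
by any test. The default pipeline assigns the capacity-limited `centroid`
backend to the pseudo-labeling roles (experts, pooled supervised model) and
the `softmax` backend to the tumor locator and the final SSL model. This
capacity split is the package's way of emulating, at toy scale, the
phenomenon the method addresses: a pooled model that underfits tumor
heterogeneity while single-case experts specialize. With a single toy
backend everywhere the synthetic problem is either solved perfectly by
everyone or by no one, and the paradigm comparison degenerates.

## Pseudo-label fusion

Per pixel: if the matched expert predicts a tumor or tumor-stroma code, that
code wins; otherwise the supervised model's prediction stands. No confidence
values are consulted anywhere and thresholding hooks are deliberately absent.
Overlapping prediction tiles follow the same precedence (tumor codes already
written persist). Artifact pixels (binary masks supplied externally, e.g. by
a QC tool) become `ignore_code`; all-ignore patches are dropped from SSL
training since they carry no gradient. The traditional-SSL baseline is the
same code path with the supervised model as the only pool member, which makes
the one-annotated-slide degeneracy (swarm == traditional) structural.
Unlabeled slides on which the locator finds no qualifying tumor patch fall
back to supervised pseudo-labels and are recorded as unmatched — the
low-tumor-content failure mode.

## Evaluation

Per-class Dice `2|P∩R| / (|P|+|R|)` with reference-ignore pixels excluded
from both sets; empty-empty classes are skipped (undefined), never imputed —
imputing 1.0 would inflate rare-class means. Sensitivity and PPV follow the
same conventions. Aggregation: mean over units within a dataset, macro-mean
across datasets, then mean ± sample (n−1) standard deviation across
replicates. The paired t-test runs on per-unit combined tumor + tumor-stroma
scores, `t = mean(d)/(sd(d)/sqrt(n))` with a two-sided p from the t
distribution (df = n − 1); an all-zero difference vector returns t = 0,
p = 1, a constant non-zero one is degenerate and raises.

## Synthetic study conditions

Each synthetic slide is a flat-colour class layout (background border,
submucosa, a benign-mucosa block, a styled tumor region with a tumor-stroma
ring) with exact masks by construction. A "morphology style" is a tumor base
colour plus an oriented sinusoidal stripe texture and bounded uniform colour
jitter; styles stand in for inter-case tumor heterogeneity and are separable
by the built-in encoder. Defaults: 256 px slides, 144 px tumor (≥25% of the
tissue, so the 60% filter always retains ≥ k patches at the 64 px similarity
patch size), 4 styles, 4 annotated + 16 unlabeled slides, 8 held-out slides
for scoring — a scaled-down version of the 10-annotated / 200-unlabeled
full-scale condition, sized so the complete three-paradigm comparison runs in
minutes on one CPU. A config flag can mix two styles in one slide to probe
mid-range similarity behaviour.

Noise is uniform (bounded) rather than Gaussian, and both shipped palettes
were chosen by margin arithmetic so every class-colour margin exceeds the
worst-case noise displacement. Pixel decisions of a centroid model are then
deterministic, and the two study conditions behave structurally:

* **separable** — all four tumor styles lie far from every non-tumor colour
  and within the pooled tumor centroid's decision region: the pooled model
  and every expert label all pixels correctly, both SSL paradigms receive
  identical pseudo-labels, and their final models coincide exactly.
* **confusable** — style 0's tumor colour is a near neighbour of the global
  benign-mucosa colour but far from the pooled tumor centroid: the pooled
  model deterministically mislabels that style's tumor as benign (the
  experts, whose tumor prototype is the style colour itself, do not).
  Traditional SSL therefore loses one of four styles in its pseudo-labels,
  while similarity matching routes those slides to the right expert.

What passing these tests does and does not show: the synthetic cohorts
validate the *machinery* — tiling, filtering, representative selection,
matching, fusion, training orchestration, scoring — and the *mechanism* by
which expert matching beats a pooled pseudo-labeler under heterogeneity.
They do not emulate stain variation, scanner differences, annotation noise,
morphological texture, or class boundaries of real H&E tissue, so synthetic
Dice levels say nothing about accuracy on real slides.

## Known limitations

* Pixel-feature toy backends ignore spatial context; real deployments should
  register a convolutional backend.
* The built-in encoder is colour/gradient-based; styles distinguished only
  by higher-order texture would require an external encoder.
* Single pseudo-label pass (no self-training rounds), matching the method;
  pseudo-labeled and labeled patches are equally weighted in SSL training.
* Proprietary pyramidal WSI formats are out of scope; slides enter as
  PNG/TIFF rasters with MPP metadata.
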