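# Methods

## Scope and coordinate conventions

A scan is a four-level image pyramid (40×, 20×, 10×, 5×; 40× ≈ 0.25
µm/px). All coordinates are 0-based, half-open rectangles with the origin
top-left, expressed at the patch's own magnification; conversion to
base-level coordinates multiplies by `40 / magnification`. Annotations are
GeoJSON polygons in base-level pixel coordinates (holes supported); the
native scanner annotation formats are out of scope, as is reading
proprietary slide containers — pyramids are directories of PNG/JPEG levels
or in-memory arrays.

## Hierarchical patch labeling

Patches are 256×256 px on a stride-128 lattice; edge patches not fully
inside the scan are dropped (classifiers need fixed-size inputs; no
padding). Coverage of a patch by a class is the area of the intersection
between the patch square and the union of that class's regions, divided by
the patch area, computed by exact polygon clipping (shapely). Pixel
rasterization appears only as an independent oracle in the tests.

At 40× a patch is labeled iff exactly one class reaches coverage ≥ 0.75
(inclusive; a 1e-9 slack absorbs float area arithmetic). Two or more
classes at threshold — possible only when regions of different classes
overlap — leave the patch unlabeled, as does no class at threshold. At
20×/10×/5× the patch footprint is tiled by 4/16/64 base-level 256-px
sub-patches (the physical footprint, independent of image resampling), each
labeled by the base rule, and the most severe label wins. A patch whose
sub-patches are all unlabeled is unlabeled; a partially labeled list still
yields the most severe labeled value, maximizing data retention.

Severity is a strict total order. Gleason grades are ordinal and rank
above every non-cancer class; among non-cancer classes the package uses
BG < T < N < A. Only cancer-over-normal dominance matters for the grading
semantics; the non-cancer order completes the total order so merging is
well defined, and it is configurable (`order=` argument).

Two binary settings map classes to cancerous/non-cancerous: S1 counts all
grades R1–R5 as cancerous; S2 counts R3–R5 (grades 1–2 are rarely reported
clinically). The setting is always explicit.

## Valid-tissue segmentation

The scan is downsampled by 8 with block averaging (edge replication for
non-divisible dimensions, output `ceil(dims/8)`). The default mask is Otsu
thresholding on the grayscale image — H&E tissue is darker than the white
slide background — with tissue on the darker side, followed by a 3×3
morphological closing to fill pinholes. A blank (zero-variance) image
yields an all-background mask with a warning.

The alternative is a small fully convolutional network: a stack of 3×3
'same' convolutions with ReLU (defaults: 10 layers of 64 filters) and a
final 1-channel sigmoid output, trained on 21×21 patches with per-pixel
binary targets using Adam (defaults: 600 epochs, learning rate 1e-4, L2
weight decay 1e-4). It is implemented in numpy (forward and backward
convolutions via sliding-window einsum) so it trains at desk scale; tests
use a reduced, logged configuration (3 layers × 8 filters, 5–8 epochs,
learning rate 0.02), which separates the synthetic two-texture task with
pixel accuracy > 0.99.

Mask-to-grid coupling: a grid patch is valid tissue iff ≥ 50 % of its
footprint, projected into mask pixels, is tissue. The 50 % threshold is a
package choice (configurable); nothing in the grading protocol pins it.

## Patch classification

Preprocessing: 256×256 inputs are cropped to 224×224 — random crop with
random horizontal flip and rotation by a multiple of 90° in training,
central crop (offset 16,16) in evaluation — then normalized per family:
CNN-style mean subtraction (123.680, 116.779, 103.939), or ViT-style
scaling to [0,1] and standardization with mean (0.485, 0.456, 0.406) and
std (0.229, 0.224, 0.225). Training augmentation is seeded and
bit-reproducible.

Backbones are pluggable behind `fit` / `predict_proba` on 224×224 inputs;
the training defaults (SGD, 50 epochs, learning rate 1e-4 decayed ×0.1
every 20 epochs, batch 32, weight decay 5e-4, dropout 0.5 where the
backbone has dropout) are carried in `TrainConfig` and overrides are
logged. The deep architectures themselves are configuration, not code: the
repository ships only a reference backbone — a multinomial logistic model
on six per-patch color statistics (RGB means and standard deviations),
fitted by minibatch SGD honoring the epoch/learning-rate/batch fields.
It exists to make the pipeline executable and testable; it can only
separate classes that differ in mean color, which the synthetic textures do
by construction. No class resampling or loss weighting is applied by
default.

Inference evaluates the central 224 crop of each 256 grid patch, keeping
one map cell per stride-128 grid position; this reconciles 224-px model
inputs with the 256/128 extraction grid using a single grid. Non-tissue
cells carry a uniform vector and `valid_mask = False`.

## Map ensembling

Rescaling block-averages probability vectors over r×r cell blocks (integer
per-axis ratios enforced) with valid-mask OR; averaging is the cell-wise
arithmetic mean. Both are convex on the simplex, so normalization is
preserved exactly and rescaling commutes with averaging — the reason
block-averaging was chosen over label voting. Class groups merge by
probability summation over a partition of the class list.

Median filtering operates on the binarized cancer/non-cancer map (argmax
of the group-merged vector): each valid cell takes the majority of the
valid cells in its 3×3 neighborhood, with reflection padding at borders
(avoids border-class bias) and invalid cells excluded from every
neighborhood. Because exclusion can leave an even neighbor count, an exact
tie keeps the original value; invalid cells are never modified. The filter
can run on the ensembled map (default) or per member before majority
voting (`filter_per_member`), since either order is defensible; with an
even member count a tied vote falls back to the ensembled call.

Grid geometry note: stride-128 grids at different magnifications are not
integer multiples of one another for general scan sizes, so
multi-magnification ensembles either use compatible (dyadic) grids — as the
synthetic tests do — or require the caller to crop to compatible shapes.

## Scan-level diagnosis

`p_c` is the percentage of valid tissue patches whose (group-merged) argmax
class is cancerous, with patches whose argmax is BG excluded from the
denominator along with segmentation-excluded background — both exclusions
because neither kind of patch is tissue evidence. An optional
cancer-probability threshold replaces the argmax call. With no valid
tissue patches `p_c` is undefined (NaN) and propagates as an abstention
with a warning.

The rule outputs NC if `p_c ≤ T_L`, C if `p_c ≥ T_U`, IHC otherwise; both
boundaries are inclusive toward the definite calls, and thresholds are in
percent (default T_L = 0.5, T_U = 7). The sweep grid defaults to T_L ∈
{0, 0.1, …, 2} and T_U ∈ {2, 3, …, 15}. Widening the abstention interval
can only shrink the decided set (set inclusion), which the tests assert
exactly. Metrics: overall accuracy and macro accuracy (unweighted mean of
per-class recalls over classes with ≥ 1 true instance).

## Rater agreement

Diagnosis labels are encoded NC → 0, IHC → 1, C → 2; IHC ("uncertain,
further examination required") sits between the definite calls, and
Spearman's coefficient depends only on this order — any strictly monotone
re-encoding gives identical values, which a test verifies numerically.
Correlations use mid-ranks for ties (scipy); the test oracle is an
independent mid-rank Pearson implementation. Reported matrices are rounded
half away from zero to 2 decimals; zero-variance columns yield flagged NaN
entries.

The packaged cohort (`data/diagnosis_cohort_46.csv`) is a transcription of
a published 46-scan prostate-biopsy evaluation with nine expert raters, the
automated system's cancer-tissue percentage and its output label. Applying
the default rule to the percentage column reproduces the recorded system
label on all 46 scans. Recomputing the full pairwise Spearman matrix
from these labels reproduces the originally reported coefficients exactly
for all pairs among seven of the nine raters; pairs involving the two
remaining raters or the system column differ from the original report by
0.01–0.03 at 2-decimal precision, a discrepancy of the source tables that
recomputation cannot resolve (no label encoding, correlation variant, or
small transcription perturbation removes it). The package reports the
values computed from the packaged labels.

## Synthetic data

The generator emulates the *structure* of annotated scans, not their
appearance. A scan is a white slide (value 250) with one axis-aligned
tissue sheet whose area share equals `tissue_fraction` exactly (up to
integer rounding), textured as tissue background; class regions are
non-overlapping integer rectangles inside the sheet, filled with
class-specific mean colors plus Gaussian noise (sd 6). Mean colors are
mutually separable so the reference classifier can succeed; rectangles with
integer corners make coverage arithmetic exact for the tests. An optional
placement margin spaces regions so that no 256-px patch can be labeled by
the union of two regions (a gap ≥ 128 px suffices), which the
distribution-recovery test uses to keep patch-label shares an unbiased
estimate of the configured class mix. Lower pyramid levels are rendered by
block averaging; the truth tissue mask is the sheet rasterized at 1/8.
Defaults: 1280×1280 px at 40×, tissue fraction 0.6, five regions of
256–448 px, and a region-class mix proportional to the class shares seen in
annotated prostate cohorts (normal tissue dominating, Gleason 3–4 the most
frequent grades, grades 1–2 rare). What passing tests on these scans does
*not* show: robustness to stain variation, blur, non-rectangular lesions,
or classes separable only by morphology.

Synthetic probability maps place a connected cancer blob (random BFS
growth) covering the requested cell fraction; cell vectors are Dirichlet
with concentration `1 + sharpness²` on the true class, so the argmax
recovers the truth with probability → 1 as sharpness grows and exactly at
`sharpness = ∞`. At the default sharpness 5 the recovered cancer ratio is
within 2 points of the configured fraction.

Synthetic cohorts draw `p_c` for cancerous and non-cancerous scans from
separate log-normals (defaults: median 13 %, σ_log 0.7 for cancerous;
median 0.3 %, σ_log 1.0 for non-cancerous; prevalence 0.5), mirroring the
strongly bimodal percentages seen in screening cohorts, clipped to
[0, 100]. All generators are deterministic given their seed.

## Test problem sizes

The suite runs on synthetic scans of 512–1280 px (strip scans of
2560×640 px for the distribution-recovery check, 150 of them ≈ 440
regions, putting the ±0.05 band at ≈ 2.5 standard errors), six to ten
training scans for classifier tests, and a 20-scan end-to-end cohort; the
FCN trains in reduced configuration. These sizes keep the full suite in
the low minutes on one CPU while leaving every statistical tolerance at
two or more standard errors.

## Known limitations

- The reference backbone is color-based; it is a harness for the pipeline,
  not a pathology model.
- Integer-ratio rescaling restricts which grids can be ensembled (above).
- The median filter's tie rule (keep the original value) is one of several
  defensible choices for masked even-count neighborhoods.
- Whether annotation coordinates are base-level pixels or physical µm is
  fixed here as base-level pixels.
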