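# wsidiag

Patch-based analysis of prostate whole-slide images (WSIs): hierarchical
Gleason-grade patch labeling across a magnification pyramid, valid-tissue
segmentation, pluggable patch classification producing class-probability
maps, multi-model / multi-magnification map ensembling with spatial median
filtering, an abstaining scan-level diagnosis rule with threshold trade-off
analysis, and Spearman rater-agreement statistics.

The package is aimed at computational-pathology researchers who want the
full pipeline from annotated slides to a scan-level call as reusable,
testable components. Deep backbones are deliberately *pluggable
configuration* rather than shipped weights; a small reference classifier and
a synthetic slide generator make every stage runnable and testable on a
laptop.

## The pipeline

**Patch labeling.** Patches of 256×256 px are taken with stride 128 at
40×/20×/10×/5×. At the base level (40×, ~0.25 µm/px) a patch is labeled
with class *c* ∈ {BG, T, N, A, R1–R5} iff *c* is the only class whose
annotated regions cover ≥ 0.75 of the patch area. A lower-magnification
patch is subdivided into the 4/16/64 base-level patches tiling its physical
footprint; the **most severe** sub-label wins (Gleason grades R1 < … < R5
rank above all non-cancer classes). Example: sub-labels [N, R3, R3, R4]
grade the 20× patch R4.

**Tissue segmentation.** On the scan downsampled 8×, either Otsu
thresholding (default; H&E tissue is darker than the slide background) or a
small fully convolutional network produce a binary valid-tissue mask; a
patch enters classification iff ≥ 50 % of its footprint is tissue.

**Probability maps and ensembling.** A classifier evaluates the central
224×224 crop of every valid grid patch, yielding an H×W grid of class
probability vectors per scan and magnification. Maps from different models
and magnifications are combined by block-average rescaling to the coarsest
grid followed by cell-wise averaging; class groups (e.g. cancerous =
R1…R5) merge by probability summation; binarized maps can be smoothed with
a masked 3×3 median filter.

**Scan-level diagnosis.** The scan statistic is

p_c = 100 · #(valid patches with cancerous argmax) / #(valid non-BG patches)

and the abstaining rule with thresholds T_L < T_U (percent) outputs
**NC** if p_c ≤ T_L, **C** if p_c ≥ T_U, and **IHC** (abstain, needs
further work-up) otherwise. `threshold_sweep` maps the accuracy/coverage
trade-off over a (T_L, T_U) grid.

**Rater agreement.** Scan-level diagnoses by several raters and the rule
are encoded ordinally (NC < IHC < C) and compared pairwise with Spearman's
rank correlation. A transcribed 46-scan cohort with nine expert raters
ships with the package.

## Worked example

```python
>>> import wsidiag as w

>>> # hierarchical label of a 20x patch whose four 40x sub-patches
>>> # carry N, R3, R3 and R4
>>> w.merge_sublabels([w.ClassLabel.N, w.ClassLabel.R3,
...                    w.ClassLabel.R3, w.ClassLabel.R4]).value
'R4'

>>> # synthetic scan -> tissue mask -> classifier -> diagnosis
>>> pyramid, annotations, _ = w.generate_scan(w.SynthConfig(seed=1))
>>> manifest = w.extract_dataset([pyramid], {pyramid.scan_id: annotations},
...                              {pyramid.scan_id: "train"}, magnifications=(40,))
>>> loader = lambda s, m, x, y: pyramid.crop(m, x, y, 256)
>>> clf = w.train_classifier(manifest, loader,
...                          w.TrainConfig(epochs=8, learning_rate=0.01, seed=0))
>>> mask = w.otsu_tissue_mask(w.downsample_scan(pyramid.levels[40], 8),
...                           pyramid.scan_id)
>>> pmap = w.predict_probability_map(pyramid, 40, clf, mask)
>>> p_c = w.cancer_ratio(pmap)
>>> round(p_c, 1), w.abstain_diagnose(p_c, w.DiagnosisRule(0.5, 7.0))
(25.8, 'C')
```

25.8 % of the scan's valid tissue patches were called cancerous; being
above the upper threshold of 7 %, the scan is diagnosed cancerous.

The same steps are available from the shell via the `wsidiag` CLI
(`extract`, `segment`, `predict`, `ensemble`, `diagnose`, `sweep`,
`agreement`, `synth`), e.g.

```bash
wsidiag agreement --out matrix.csv
```

writes the 10×10 pairwise Spearman matrix (nine raters plus the rule) for
the packaged 46-scan cohort.

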