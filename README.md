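# adipo

Adipocyte morphometry and the adipocyte index (AI) for blubber histology.

Energetic reserves of large, free-roaming marine mammals are hard to
measure non-lethally: blubber lipid percent from small biopsy samples is
error-prone, and gross morphology is unavailable on live animals. Because
adipocyte *number* is fixed in adulthood, adipocyte *size* tracks stored
energy. This package implements an image-analysis pipeline for
H&E-stained blubber sections that supports both measurement routes and
the statistics used to compare them:

* **segmentation** — intensity thresholding of calibrated grayscale
  images into lipid-filled adipocyte vs darker intervacuolar matrix;
  connected-component labelling; per-cell areas under a circular model
  (`d = 2·sqrt(k·s²/π)`, `area = π(d/2)²` for `k` pixels at `s` µm/px),
  with border-touching cells excluded and a 100-cell minimum per sample;
* **adiposity metrics** — the adipocyte index `AI = total area /
  adipocyte area` (≥ 1, higher = leaner; the strict intervacuolar ratio
  `AI − 1` is available by configuration), geometric means, spherical
  volumes `V = (4/3)π(area/π)^{3/2}`, cohort summaries and reductions;
* **stats** — Shapiro–Wilk, Levene, 2.2×IQR outlier screen, VIF,
  pooled-variance t-tests (log10 AI), Pearson correlations, and binary
  logistic regression (early vs late migration cohort) with backward
  likelihood-ratio selection, Nagelkerke R² and Hosmer–Lemeshow
  calibration, run as a seven-model battery (A–G) over the metric
  combinations with listwise deletion;
* **synthetic histology** — disc-packed tissue images with exact label
  masks and cohort metric tables with controlled means, correlations
  (Gaussian copula) and missingness, so every stage is testable against
  known ground truth.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
from adipo import (TissueSpec, generate_tissue_image, binarize,
                   segment_image, mean_adipocyte_area,
                   compute_adipocyte_index)

spec = TissueSpec(seed=1)                      # 1024 px² at 0.5 µm/px
img, truth = generate_tissue_image(spec)
mask, labels, cells = segment_image(img, img.max_intensity // 2)
print(f"complete cells: {cells.n_complete_cells}")
print(f"mean area: {mean_adipocyte_area(cells, 100):.1f} um^2")
ai = compute_adipocyte_index(mask)
print(f"AI: {ai.value:.4f} (true {truth.true_ai:.4f})")
```

prints

```
complete cells: 346
mean area: 385.4 um^2
AI: 1.7096 (true 1.7036)
```

346 interior adipocytes averaged 385.4 µm² in cross-section, and the
thresholded image gives AI 1.7096 against a rendered truth of 1.7036 —
the 0.006 gap is the effect of the default intensity noise and
nucleus-mimicking specks on a fixed mid-range threshold.

The cohort side, from the command line:

```sh
adipo simulate --table --seed 1 --out demo/
adipo stats --table demo/metrics.csv --out demo/stats/
```

```
model A: n=77, retained=adipocyte_area_um2 lipid_percent, Nagelkerke R2=0.705
model B: n=139, retained=ai lipid_percent, Nagelkerke R2=0.358
model C: n=77, retained=lipid_percent adipocyte_area_um2, Nagelkerke R2=0.705
model D: n=83, retained=adipocyte_area_um2, Nagelkerke R2=0.603
model E: n=77, retained=adipocyte_area_um2, Nagelkerke R2=0.585
model F: n=77, retained=ai, Nagelkerke R2=0.344
model G: n=77, retained=lipid_percent, Nagelkerke R2=0.020
```

Each model predicts the migration cohort from a different metric subset;
`n` is the listwise-deletion sample size fixed by which metrics each
simulated biopsy carries (77 with all three, 139 with AI+lipid, 83 with
area+AI), and Nagelkerke R² summarises predictive power. Full
coefficient tables (B, SE, Wald p, odds ratio `exp(B)`, 95% CI) and
Hosmer–Lemeshow fit statistics are written as CSV with JSON twins.

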