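# tsrzone

Zonal tumor–stroma ratio (TSR) quantification for calibrated two-class
(tumor/stroma) histology images, plus the cohort-level statistics that go
with it.

Given a calibrated RGB image and two boundary polylines (the epithelial
origin and the invasive edge), the pipeline:

1. classifies pixels into tumor vs stroma (H-DAB optical-density
   deconvolution with a DAB threshold, or a trainable filter-bank +
   random-forest classifier with scribble refinement);
2. builds two 1-mm bands by Euclidean distance to each polyline on its
   tumor side — the *inner tumor* band below the epithelial origin and the
   *invasive front* (ITF) band above the invasive edge;
3. selects, per band, the three 1.15 × 0.68 mm image fields (0.78 mm²)
   with the lowest tumor area fraction among sliding-window candidates
   whose centre lies in the band and whose four border strips all contain
   tumor (overlap between fields allowed);
4. computes the per-field TSR (tumor area / field area × 100 %), averages
   the three fields per band, dichotomizes at 50 % (≥ 50 % = tumor-high)
   and labels the slide pattern (high_high / high_low / low_low /
   low_high);
5. offers association tests (Yates-corrected chi-square for 2×2, Pearson
   for r×c), paired t-test, Spearman correlation, Kaplan–Meier/log-rank,
   univariate/multivariate Cox models for four survival endpoints
   (OS/DFS/MFS/RFS), and logistic models for perineural-invasion risk.

Because no real slides or patients ship with the package, a
`synthetic` module generates ground-truthed pseudo-IHC phantoms (brown
tumor nests on blue-gray stroma with controllable per-band density) and
exponential proportional-hazards survival cohorts, and packages the
reference study's printed baseline count tables as fixtures.

## CLI

```sh
# write a phantom slide (TIFF + mask PNG + GeoJSON curves) and a cohort CSV
tsrzone simulate --out-dir demo --cohort-n 50 --seed 1

# full per-slide workflow -> JSON report with fields, TSRs, groups, pattern
tsrzone pipeline demo/phantom.tiff demo/curves.geojson --out demo/report.json

# individual stages
tsrzone segment demo/phantom.tiff --out demo/mask.png
tsrzone zones demo/phantom.tiff demo/curves.geojson --out-dir demo
tsrzone fields demo/phantom.tiff demo/curves.geojson --out demo/fields.csv

# reproduce the association tests on the packaged count tables
tsrzone stats --fixtures table1 --out demo/table1_stats.csv
```

Configuration (band width, field size, stride, border margin, thresholds,
seed) can be given as a JSON file via `--config`; command-line flags
override file values, which override defaults.

## Layout

| module | contents |
| --- | --- |
| `tsrzone.core` | shared domain types (images, masks, curves, bands, fields, records, results) |
| `tsrzone.synthetic` | phantom generator, cohort simulator, printed-table fixtures |
| `tsrzone.segmentation` | OD transform, H-DAB deconvolution, threshold and trainable classifiers |
| `tsrzone.zonation` | distance-to-polyline rasters and 1-mm band extraction |
| `tsrzone.fields` | constrained sliding-window field selection |
| `tsrzone.tsr` | TSR computation, dichotomization, pattern, pipeline orchestration |
| `tsrzone.stats` | association, paired, rank, survival and logistic statistics |
| `tsrzone.io` / `tsrzone.cli` / `tsrzone.config` | readers/writers, configuration, CLI |
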