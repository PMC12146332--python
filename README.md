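# seedlapse

Quantify seed **germination potential** from time-lapse Petri-dish imagery.

The pipeline: per-frame Pascal VOC bounding-box annotations select each seed,
the crop is binarized at a fixed intensity threshold (default 120), white
(foreground) pixels are counted per time point, the resulting growth series
is fitted with five candidate regression families (exponential, linear,
logarithmic, power, polynomial) and scored by R², and the first derivative of
the winning cubic is read as the instantaneous germination rate. A synthetic
time-lapse generator with exact analytic ground truth makes every stage
testable offline, and standard detection metrics (IoU matching,
precision/recall, AP, mAP over an IoU grid) score detector output against the
annotations.

## CLI

One subcommand per stage (`seedlapse --help` for details):

```bash
# Render a synthetic 48 h time lapse (30-min frames) with VOC annotations
seedlapse simulate data/ --n-seeds 4 --seed 1

# Salt-and-pepper augmentation at a 0.2 replacement probability
seedlapse augment data/images aug/ --factor 0.2 --seed 1

# Deterministic 7:2:1 train/test/val file lists
seedlapse split data/images splits/ --ratios 7,2,1 --seed 0

# Measure per-seed white-pixel growth series over hours 24-48
seedlapse measure --images data/images --annotations data/annotations \
    --out series.csv

# Fit all families per dish, select by R²; differentiate the winning cubic
seedlapse fit series.csv --out fits.csv
seedlapse potential series.csv --out potential.csv

# Score detector TSV output (image_id label conf xmin ymin xmax ymax)
seedlapse evaluate --ground-truth data/annotations --detections dets.tsv \
    --out report.json

# Everything end to end, config-driven, with a reproducibility manifest
seedlapse run-all --config run.yaml
```

`run-all` writes `series.csv`, `fit_report.csv`, `derivative_report.csv`,
`rate_report.csv` and a `manifest.json` recording the fully resolved
configuration and its hash; reruns with an identical config are bit-identical.

## Library layout

| module                  | contents                                                         |
| ----------------------- | ---------------------------------------------------------------- |
| `seedlapse.voc_io`      | VOC XML read/write, bounding boxes, seeded 7:2:1 dataset split   |
| `seedlapse.augment`     | `sp_noise` salt-and-pepper corruption                            |
| `seedlapse.simulate`    | synthetic germination scenes with exact foreground ground truth  |
| `seedlapse.morphometry` | crop / grayscale / binarize / count, growth-series assembly      |
| `seedlapse.fitting`     | family fits, dual-form R², selection, polynomial differentiation |
| `seedlapse.metrics`     | IoU, greedy matching, PR curves, AP/mAP, germination rate        |
| `seedlapse.pipeline`    | `RunConfig` + `run_pipeline` orchestration                       |

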