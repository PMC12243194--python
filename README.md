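# grainray

Non-destructive prediction of three rice grain quality traits from a single
2D X-ray radiograph of paddy grains in a fixed-grid sample holder:

* **chaffiness** — grains without a filled kernel, flagged by Mahalanobis
  distance from the non-chaffy cluster in PCA space (threshold 17);
* **chalky rice kernel percentage (CRK%)** — a linear SVM hyperplane trained
  on de-husked kernels, applied to whole grains after a "virtual de-husking"
  feature-space shift;
* **head rice recovery percentage (HRR%)** — five recovery classes
  (100/80/60/40/20 %), assigned per grain by a max-probability rule over
  calibrated one-vs-rest linear decision functions.

The processing chain is: background estimation from the grey-value histogram
mode → Lambert–Beer normalization `-ln(I/I0)` → dual watershed grain
segmentation with morphological opening → eight blob descriptors f1–f8 per
grain → z-score scaling + 3-component PCA → trait models.

Because no real scans ship with the package, an analytic **phantom module**
renders synthetic radiographs of ellipsoidal husk+kernel grains (Beer–Lambert
parallel-beam projection onto a 14-bit detector, additive Gaussian noise)
with exact per-grain ground-truth tables. All tests and experiments run
against these phantoms.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the release criteria (phantom recovery
experiments, brute-force geometry oracles, closed-form checks).

## CLI

```sh
grainray simulate --n-grains 100 --chaffy 0.15 --noise-sd 30 \
    --out scene.tif --truth truth.csv
grainray normalize --image scene.tif --i0 auto --out att.tif
grainray segment --image scene.tif --labels-out labels.tif --csv-out segs.csv
grainray features --image scene.tif --out features.csv
grainray fit-embedding --features features.csv --subset chaffiness --out emb.json
grainray train --trait chaffy --features features.csv --truth matched.csv \
    --embedding-out emb.json --model-out model.json
grainray predict --trait chaffy --features features.csv \
    --embedding emb.json --model model.json --out report.json
grainray evaluate --pred pred.csv --truth obs.csv
grainray run-all --out-dir run --seed 1        # full simulate→train→predict
grainray fixtures --out-dir fixtures --seed 0  # canonical fixture suite
```

`run-all` accepts a YAML config (`--config`); flags override the file, and
every run writes back a frozen `resolved_config.yaml`.

## Layout

```
src/grainray/
  phantom.py        synthetic radiographs + ground truth
  preprocessing.py  radiograph I/O, background mode, -ln(I/I0)
  segmentation.py   dual watershed + opening, GrainSegment
  features.py       blob descriptors f1..f8, minimum enclosing circle
  embedding.py      z-scaler + 3-component PCA, trait feature subsets
  trait_models.py   chaffiness / chalkiness / HRR classifiers, metrics
  pipeline.py       orchestration, training helpers, fixture suite
  cli.py            click command group
```
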