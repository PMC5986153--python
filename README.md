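# retoct

Retinal SD-OCT phenotyping: graph-based layer segmentation, clinically
motivated structural feature extraction, and normal / AMD / DME
classification under a repeated stratified cross-validation protocol.

The pipeline has four stages:

1. **Segmentation** (`retoct.segmentation`) — the twelve retinal interfaces
   are traced per B-scan by a shortest-path search over chains of Canny edge
   pixels. Chain traversal is free; jumping between chains costs a weighted
   sum of the Euclidean gap, the slope mismatch against a reference boundary,
   and a "non-associativity" penalty measuring how poorly the chain's
   bright/dark context matches the target interface. Boundaries are detected
   in a fixed high-to-low contrast order so earlier ones bound the search
   region of later ones; a cross-B-scan median correction repairs per-scan
   failures.
2. **Features** (`retoct.features`) — ten scalars per eye: hyper-reflective
   intra-retinal spot (HIS) volume, drusen volume (first-order fit of the
   ELM-to-RBC span + a 1.3 intensity-ratio gate), curviness of the MZ-EZ and
   OPL-ONL boundaries (deviation-sum × significant-peak-count, α=3, δ=5),
   and mean / 70th-percentile thickness of the retina, the EZ–RBC complex
   and the RPE band.
3. **Classification** (`retoct.classification`) — stratified 15-fold
   cross-validation repeated 10 times, per-fold hyperparameter tuning on an
   inner validation split, metrics pooled per repeat and reported as
   mean (SD). Registry: random forest, logistic regression, linear/RBF SVM,
   AdaBoost, naive Bayes, classification and regression trees.
4. **Phantoms** (`retoct.phantom`) — synthetic volumes with exactly known
   layer geometry, drusen bumps, HIS spots and noise, so the whole pipeline
   is testable without clinical data.

## CLI

```sh
retoct simulate --n-per-class 15 --seed 7 --out cohort/
retoct segment cohort/phantom_000_normal.tiff --out boundaries.json
retoct features cohort/phantom_000_normal.tiff --boundaries boundaries.json \
       --label normal --out features.csv
retoct evaluate features.csv --algo rf --k 15 --repeats 10 --classes 3 --seed 7
retoct run cohort/labels.csv --out-dir results/   # end-to-end
```

`--config pipeline.yaml` overrides any default (Canny parameters, edge
weights, search-region margins, feature thresholds, CV protocol); see
`retoct.config.PipelineConfig`.

## Library

```python
from retoct import phantom, segmentation, features
from retoct.classification import LabeledCohort, repeated_kfold_cv

vol, truth = phantom.generate_phantom(phantom.PhantomSpec(noise_sd=6.0, seed=1))
boundaries = segmentation.segment_volume(vol)
fv = features.extract_features(vol, boundaries)
```

## Volume format

Multi-page 8-bit grayscale TIFF (one page per B-scan) or a directory of
natural-sorted PNGs, with voxel dimensions `(axial µm/px, lateral µm/px,
inter-B-scan µm)` supplied via a JSON sidecar (`<name>.tiff.json`) or
`--voxel-dims`. Boundary sets are JSON; feature tables are CSV.
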