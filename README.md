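# lamegait

Classifying sheep behaviour — and detecting lame gait — from tri-axial
accelerometer signals.

Lameness is a common, costly disease symptom in sheep flocks, traditionally
detected by visual inspection of gait. Animal-borne accelerometers (ear tag,
neck collar, or foreleg mount) record the amplified, asymmetric "head-bob"
acceleration signature of an animal avoiding weight on one limb, which makes
lame walking separable from sound walking, grazing, standing, and lying.
`lamegait` implements the full epoch-based classification pipeline for such
studies, plus a synthetic gait-signal generator so that every stage is
testable without field data.

## The pipeline

1. **Segmentation** — an annotated record sampled at 12 Hz is cut into
   mutually exclusive 10 s epochs (120 samples), keeping only windows whose
   samples all carry one non-reserved behaviour label.
2. **Features** — 14 metrics per epoch, on raw gravity-inclusive samples in g:
   per-axis means `Ax, Ay, Az` and extrema `MaxX..MinZ`; movement variation
   `MV = (1/T) Σ(|Δx|+|Δy|+|Δz|)`; signal magnitude area
   `SMA = (1/T) Σ(|x|+|y|+|z|)`; average intensity
   `AI = (1/T) Σ √(x²+y²+z²)`; entropy `S = (1/T) Σ (1+Tsᵢ) ln(1+Tsᵢ)` with
   `Tsᵢ = xᵢ+yᵢ+zᵢ`; energy `E = (1/T) Σ (xᵢ²+yᵢ²+zᵢ²)²`.
3. **Feature ranking** — a from-scratch random forest (500 trees, mtry = 4,
   Gini splits, bootstrap resamples) ranks the 14 features by mean decrease
   in Gini; the top 3 feed the classifier.
4. **Classification** — quadratic discriminant analysis: class-specific
   Gaussians (μ_k, Σ_k, π_k), assignment by the log-domain discriminant
   δ_k(v) = −½ ln det Σ_k − ½ (v−μ_k)ᵀ Σ_k⁻¹ (v−μ_k) + ln π_k.
5. **Validation** — leave-one-epoch-out cross-validation, a predicted × observed
   confusion matrix, and per-class one-vs-rest sensitivity, specificity,
   accuracy, and precision.

Two analysis variants are supported: **Analysis I** keeps lame grazing and
lame walking alongside the sound behaviours; **Analysis II** drops lame
grazing, which is heavily confused with sound grazing.

## Worked example

```sh
lamegait simulate --out study --seed 3 --deployment ear
lamegait extract --accel study/animal01_ear_accel.csv \
    --annotations study/animal01_ear_annotations.csv --out feats.csv
lamegait rank  --matrix feats.csv --seed 1 --out rank.json
lamegait loocv --matrix feats.csv --features MV,AI,Ay --out cm.csv
lamegait report --confusion cm.csv --out perf.json
```

or end to end in one step on the default synthetic ear study:

```sh
lamegait run --analysis II --deployment ear --seed 2 --ntree 50 --out run.json
```

which prints the selected features and the per-class performance table, e.g.

```
selected features: SMA, MaxY, MinX
                 TP  FP  FN    TN  sensitivity  specificity  accuracy  precision  prediction_accuracy
sound_grazing   342   0   0  1234          100          100       100        100                  100
...
```

Here every class is perfectly recovered: the default synthetic behaviours
are well separated, so leave-one-out validation is diagonal. `sensitivity`
is the fraction of a class's observed epochs that were correctly classified
(identical to the per-observed-class prediction accuracy), `precision` the
fraction of epochs predicted as that class that truly were.

The same machinery reproduces published reference results. For the collar
deployment's sound-grazing column of the reference confusion matrix:

```python
from lamegait.datasets import reference_confusion_matrix
from lamegait.validation import performance, pct

rep = performance(reference_confusion_matrix("collar", "II"))
g = rep.per_class["sound_grazing"]
print(pct(g.sensitivity), pct(g.precision))   # -> 95 91
```

i.e. sensitivity 283/(283+13+2) = 95% and precision 283/(283+26+2) = 91%.

## Layout

- `lamegait.synthetic` — behaviour signal model and study generator
- `lamegait.io` — record/annotation CSV parsing, epoch segmentation
- `lamegait.features` — the 14 per-epoch metrics and the feature matrix
- `lamegait.ranking` — `GiniImportanceForest` and ranking helpers
- `lamegait.qda` — `GaussianQDA` classifier
- `lamegait.validation` — LOOCV, confusion matrices, performance reports
- `lamegait.datasets` — published reference confusion matrices
- `lamegait.cli` — `lamegait` command-line entry point

See `docs/methods.md` for the model assumptions, parameter choices, and
limitations.
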