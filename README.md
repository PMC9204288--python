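# randheads

Closed-form randomized neural-network classification heads over CNN image
features, with five-fold cross-validation, confusion-matrix metrics and
Grad-CAM explainability.

Three single-hidden-layer heads share a frozen random hidden layer
(uniform [-1, 1] weights and biases, sigmoid activation) and are trained
in closed form by an SVD pseudo-inverse (minimum-norm least squares,
optional ridge):

* **SNN** — hidden activations plus a trainable output bias, solved
  jointly on a ones-augmented design matrix;
* **ELM** — hidden activations only;
* **RVFL** — hidden activations concatenated with direct (shortcut)
  links from the inputs.

The heads consume 128-dimensional features tapped at the linear FC128
output of a modified CNN backbone (`[FC128, ReLU, BatchNorm, FC2,
softmax, classification]` replaces the original classifier). Pretrained
ImageNet backbones are an optional external dependency; the bundled
backbone is a small frozen random convolution-pool network
(`ToyConvBackbone`) so the whole pipeline runs on one CPU with no
downloads. Fine-tuning trains the added head layers with cross-entropy
SGD (defaults: mini-batch 10, 4 epochs, learning rate 1e-4, 400 hidden
nodes).

## Library quick start

```python
import numpy as np
import randheads as rh

# synthetic two-cluster features
X, Y = rh.generate_feature_table(n_pos=50, n_neg=50, dim=8,
                                 class_separation=6.0, seed=0)
labels = np.argmax(Y.values, axis=1)

# 5-fold cross-validation of the ELM head
reports, agg = rh.cross_validate_features(X.values, labels, "elm", seed=0)
print(agg.as_dict(rounded=True))

# full image pipeline on synthetic lesion images
spec = rh.SyntheticSpec(n_pos=30, n_neg=10, image_size=64,
                        lesion_radius_range=(6, 12), seed=5)
data = rh.generate_images(spec)
reports, agg = rh.run_cv_pipeline(data, rh.FineTuneConfig(seed=5), "snn")
```

## Command-line interface

The `randheads` command exposes `simulate`, `extract`, `train-head`,
`crossval` and `explain`. Options may also be given in a flat YAML file
via `--config`; explicit flags win. Every command writes a
reproducibility manifest next to its outputs.

```sh
# synthetic image folder (pos/ + neg/ PNGs)
randheads simulate --out data/ --n-pos 30 --n-neg 10 --image-size 64 --seed 5

# fine-tune the built-in extractor and export FC128 features
randheads extract --data data/ --out features.csv --seed 5 \
    --save-extractor extractor.npz

# train one head on the exported features
randheads train-head --features features.csv --head snn --out model.npz

# five-fold cross-validation (fold rows + Avr/Std rows, CSV + JSON)
randheads crossval --data data/ --head elm --out cv/ --seed 5

# Grad-CAM overlays and raw heatmaps
randheads explain --data data/ --extractor extractor.npz --out cams/
```

## Conventions

* Positive class = label 1 (unhealthy); metrics are percentages, full
  precision internally, displayed half-up at 2 decimals.
* Fold aggregation uses the arithmetic mean and the **population**
  standard deviation (divisor k).
* k-fold splitting is seeded and stratified by default.
* Prediction ties break toward the lowest class index.
* All generators and trainers are deterministic given their seed.
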