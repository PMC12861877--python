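# twincross

Twin cross-learning for imbalanced lesion-patch detection on textured
images. The package implements, end to end on synthetic endoscopy-like
textures:

- **Synthetic channels** (`twincross.synthetic`) — smoothed-random-field
  textures with elliptical lesions, mask-coverage patch labels, exact
  benign/malignant quotas, floor-based 7:2:1 splits and controllable label
  noise. Four built-in channel profiles (GU, GRS, GPs, GB) mirror the
  reference imbalances.
- **GLCM patch features** (`twincross.features`) — non-overlapping P×P
  patch decomposition, normalized symmetric co-occurrence matrices
  (32 gray levels), a 22-value texture vector (11 statistics ×
  2 distances, angle-averaged), per-image feature-map fusion, and a
  median-split odds-ratio univariate screen.
- **Double-threshold sample selection** (`twincross.thresholds`) — scores
  are split by a (t_low, t_high) pair into negative samples / uncertain /
  reliable positives; a coarse-to-fine, reward-gated grid search tunes the
  pair by training a backbone on each candidate partition and measuring
  validation F1.
- **Twin four-class fusion** (`twincross.fusion`) — identity /
  horizontal-mirror branch pair, {P+, P−, N+, N−} labels, and the fused
  binary decision with a group-max confidence score.
- **Cross-learning with a noise-filter policy** (`twincross.learning`) —
  positive-only and negative-only loops at a 1:10 core/opposite ratio; a
  logistic retain/remove policy filters suspected-noise instances each
  epoch and is trained REINFORCE-style from α-scaled trailing-mean F1
  differences; multi-channel orchestration with size-balanced per-channel
  learning rates.
- **Metrics** (`twincross.metrics`) — confusion-matrix bundle (accuracy,
  precision, recall, specificity, F-measure, FNR, FPR), rank-based
  ROC/AUC, channel macro-averages, and dataset summary tables with exact
  binomial balance tests.
- **Pipeline + CLI** (`twincross.pipeline`, `twincross.cli`) — YAML
  config, per-stage sub-seeding, and artifact writers for every stage.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: exact
printed-arithmetic targets, AUC and grid-search oracle equivalence,
threshold recovery on Beta score mixtures, noise-filter efficacy over
10 seeds, and the invariant suites.

## CLI

```bash
# generate a synthetic channel (PNG patches + CSV manifest)
twincross simulate --channel GU --seed 7 --out runs/sim --noise 0.2

# full pipeline from a YAML config
twincross run-all --config config.yaml

# individual stages
twincross features --config config.yaml
twincross search --config config.yaml --rounds 8 --init-low 0.5 --init-high 0.8
twincross train --config config.yaml --channels GU,GRS --epochs 20
twincross report --out runs/out
```

A minimal `config.yaml`:

```yaml
channels:
  - {name: GU, n_benign: 100, n_malignant: 100, image_size: 96}
patch_size: 16
search: {rounds: 2}
training: {epochs: 10, backbone: logistic}
seed: 7
out_dir: runs/out
```

Runs are fully reproducible from `(config, seed)`; rerunning the same
config yields a byte-identical `report.json`.

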