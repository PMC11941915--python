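# granarywatch

Monitoring and early-warning toolkit for granary temperature-sensor grids.
It covers the full chain from raw long-format sensor records to risk alerts:

* **grid_core** — domain types (daily 3D temperature grids, granary series,
  six storage states) and CSV/JSON series I/O.
* **sim** — a synthetic granary generator: seasonal ambient forcing, daily
  heat relaxation with ground-coupled floor, sensor noise / error codes /
  dropouts, and injectable storage-state events (mildew, condensation,
  aeration, new grain addition, empty), so every downstream stage trains and
  tests without external data.
* **preprocess** — sentinel/range cleaning, pooled Z-score outlier removal,
  temporal mean imputation, spline resize to the unified 10×6×4 grid, and
  train-partition standardization.
* **water_potential** — the absolute-water-potential feature (kJ/kg) used as
  the forecaster's second input channel (pluggable formula, per-variety
  coefficient sets shipped as flagged placeholders).
* **augment** — axis-flip quadrupling and a 3D GAN for minority-class
  expansion, with exact-count rebalancing.
* **classifier** — a 3D DenseNet six-way storage-state classifier (dense
  blocks, compression transitions, global average pooling), trained with
  Adam + class-weighted cross-entropy, stratified 70/15/15 split, early
  stopping.
* **forecaster** — a two-channel 3DCNN-LSTM that maps a 35-day window of
  temperature + water-potential grids to the next 10 daily grids
  (per-frame conv embedding → stacked LSTM → output head with persistence
  skip); includes brute-force convolution/LSTM reference oracles and a
  single-channel ablation mode.
* **risk_alert** — forecast → classify chain producing per-horizon-day
  states, first-alert day, lead time, and hotspot voxel localization.
* **metrics** — classification metrics (per-class/macro/micro P/R/F1,
  confusion matrix), MAE/RMSE, series diagnostics (moments, ACF,
  Durbin–Levinson PACF), relative-improvement arithmetic, channel ablation.
* **nn** — a compact NumPy reverse-mode autograd engine (conv3d, pooling,
  LSTM, batch norm, Adam) that backs all three models; no deep-learning
  framework is required.

## CLI

The `granarywatch` entry point wires the pipeline (exit codes: 0 ok,
2 config error, 3 data error):

```sh
granarywatch simulate --config sim.yaml --out series_dir/ --seed 1
granarywatch preprocess --in series_dir/ --out grids.csv --stats stats.json
granarywatch train-classifier --config densenet.yaml --out cmodel/ --per-class 200
granarywatch train-forecaster --config forecaster.yaml --out fmodel/
granarywatch classify --series series_dir/ --classifier cmodel/ --out states.csv
granarywatch forecast --series series_dir/ --model fmodel/ --out forecast.csv
granarywatch alert --series series_dir/ --forecaster fmodel/ --classifier cmodel/ --out report.json
granarywatch evaluate --pred states.csv --truth labels.csv --out metrics.json
granarywatch report --dir run_dir/
```

`sim.yaml` may carry any `SimConfig` field plus an `events` list, e.g.:

```yaml
n_days: 120
events:
  - {state: mildew, start_day: 90, duration: 20, center: [6, 3, 2]}
```

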