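# apforecast

Multi-beat forecasting of irregular cardiac action potentials with
recurrent networks and reservoir computing.

Cardiac cells paced at short or irregular intervals develop *alternans*
— long–short oscillations of action potential duration (APD) that
precede dangerous arrhythmias. Predicting the voltage trace several
beats ahead would open the door to preemptive control. This package
builds that forecasting study end to end, entirely in silico: it
simulates irregular action-potential time series with mechanistic cell
models, converts them into forecasting datasets, trains five recurrent
forecasters, and scores their closed-loop multi-beat predictions. It is
aimed at researchers in cardiac dynamics and nonlinear time-series
prediction who want a reproducible, desk-scale testbed.

## What it contains

**Data generators** (`apforecast.ionic_models`)

* Fenton–Karma three-variable model (Beeler–Reuter fitting), paced with
  cycle lengths drawn from Normal(320, 50) ms using 2-ms stimuli of
  magnitude 0.4 — stochastic irregular alternans with APDs spanning
  ≈200 ms, forward Euler at 0.1 ms.
* Noble (1962) Purkinje model whose anionic conductance follows the z
  variable of a time-rescaled chaotic Lorenz system (σ=10, ρ=28, b=8/3,
  right-hand sides × 0.001; g(0)=0, g(60)=0.2) — autonomous, chaotically
  timed beats, no stimulus channel.
* Corrado–Niederer Mitchell–Schaeffer two-variable model — the hybrid
  forecaster's simplified "knowledge-based" cell.

**Preprocessing** (`apforecast.dataset`) — rescaling to [0, 1],
voltage-adaptive undersampling (keep a point iff |ΔV| ≥ dv since the
last kept point, or Δt > dt_max), beat-onset detection, stimulus-channel
reconstruction, spline artifact removal, and beat-aligned
warmup/train/test splits.

**Forecasters** (`apforecast.esn_forecasters`, `apforecast.gated_rnn`)

* Echo state networks with the leaky reservoir update
  h_t = (1−α) h_{t−1} + α tanh(W_in x_t + W h_{t−1}) and a ridge-regressed
  linear readout y_t = W_out [x_t; h_t; 1]; baseline Erdős–Rényi,
  clustered (sparsely coupled sub-reservoirs), and physics-informed
  hybrid (Mitchell–Schaeffer voltage as an extra input channel)
  variants.
* LSTM and GRU sequence-to-sequence regressors in numpy with exact BPTT
  gradients and Adam (≤ 30 epochs).

All five share one protocol: learn V_{t+1} from (stimulus_t, V_t)
[plus V_KB for the hybrid], then forecast the test horizon recursively
with each prediction fed back as the next voltage input.

**Evaluation** (`apforecast.evaluation`) — RMSE on the resampled test
grid, per-beat APD extraction (threshold 0.3, interpolated crossings)
and absolute APD error with onset matching, seed-averaged grid search,
and a method-comparison harness. ESN scores are averaged over 10
reservoir seeds.

## Worked example

```python
from apforecast.experiments import make_fk_dataset, run_forecaster

split, protocol = make_fk_dataset(seed=1)   # 100 beats, CL ~ N(320, 50)
print(f"dataset: {len(split.beat_onsets)} beats, "
      f"{len(split.full)} resampled samples, {split.n_test_beats} test beats")

report = run_forecaster("esn", split, n_neurons=100, seed=0)
print(f"closed-loop RMSE: {report.rmse:.4f} (normalized voltage)")
print(f"median |APD error|: {report.apd_median_error:.2f} ms")
print(f"max    |APD error|: {report.apd_max_error:.2f} ms over "
      f"{len(report.apd_abs_error)} beats")
```

prints

```
dataset: 100 beats, 6554 resampled samples, 19 test beats
closed-loop RMSE: 0.0298 (normalized voltage)
median |APD error|: 0.75 ms
max    |APD error|: 2.80 ms over 19 beats
```

i.e. this reservoir (100 neurons, tuned defaults) reproduces all 19
held-out action potentials with sub-3-ms duration error while running
closed-loop — no ground-truth voltage is revealed during the forecast.
`run_forecaster` accepts `"lstm"`, `"gru"`, `"esn"`, `"clustered_esn"`,
or `"hybrid_esn"`; hyperparameters are keyword overrides.

A thin CLI wraps the same pipeline for config-driven runs:

```sh
apforecast simulate -c config.yaml -o out/   # dataset series + sidecar
apforecast run      -c config.yaml -o out/   # train, forecast, report
apforecast compare  -c config.yaml -o out/ --sizes 100
```

## Layout

```
src/apforecast/
  ionic_models.py     # FK, Noble-Lorenz, Mitchell-Schaeffer simulators
  dataset.py          # SampledSeries, resampling, onsets, splits
  esn_forecasters.py  # reservoirs, ridge readout, closed-loop forecasts
  gated_rnn.py        # numpy LSTM/GRU with BPTT + Adam
  evaluation.py       # RMSE, APD errors, grid search, comparisons
  experiments.py      # study pipelines (datasets + runners)
  cli.py              # YAML-driven command line
docs/methods.md       # models, parameters, design choices, limitations
```

See `docs/methods.md` for the governing equations, parameter tables,
numerical choices, and known limitations.
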