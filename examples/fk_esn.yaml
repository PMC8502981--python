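# Baseline ESN on the randomly paced Fenton-Karma dataset.
# Usage: apforecast run -c examples/fk_esn.yaml -o out/
dataset:
  model: fk
  seed: 1
  n_beats: 100
  n_warmup_beats: 10
  n_train_beats: 71
  resample:
    dv_threshold: 0.03
    dt_max: 20.0
method:
  kind: esn
  n_neurons: 100
  seed: 0
evaluation:
  apd_threshold: 0.3
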