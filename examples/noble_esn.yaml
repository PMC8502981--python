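# Univariate ESN on the chaotic Noble-Lorenz dataset.
dataset:
  model: noble
  seed: 1
  n_train_beats: 65
  n_test_beats: 14
method:
  kind: esn
  n_neurons: 100
  seed: 0
evaluation:
  apd_threshold: 0.3
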