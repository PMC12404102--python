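# Demo pipeline: tiny phantoms, short training. Runs in ~1 minute on a laptop.
seed: 7
out: ripc_demo_run
phantom:
  n_per_class: [4, 4, 4]
  grid: [48, 48, 32]
  spacing: 0.7
convert:
  M: 1024
  L: 6
  mode: segmented
train:
  epochs: 5
  K: 128
  channels: 4
  profile: tiny
  batch_size: 8
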