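# Desk-scale configuration: the full pipeline on 96x96 synthetic phantoms,
# sized for a single CPU. The built-in defaults instead mirror the reference
# clinical regime (batch 16, 100 epochs, lr 1e-4), which assumes far more
# data and compute.
seed: 11
n_labeled: 60
n_unlabeled: 40
n_test: 20

network:
  base_width: 8

lr:
  lr1: 0.002   # transferred layers; random layers get beta(n_labeled) * lr1

pretrain:
  stage: pretrain
  optimizer: adam
  lr: 0.001
  epochs: 20
  batch_size: 8
  crop_size: 64
  seed: 3

segment:
  stage: segment
  optimizer: adamw
  epochs: 40
  batch_size: 4
  seed: 5
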