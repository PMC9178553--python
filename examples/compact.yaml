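# Desk-scale configuration: the compact model and its training recipe.
model:
  hidden_size: 32
  fcn_hidden: [64, 64]
  cnn_channels: [8, 16, 16]
  merge_dim: 64
  head_hidden: 128
  dropout: 0.0
training:
  max_epochs: 30
  batch_size: 64
  mask_infeasible_loss: true
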