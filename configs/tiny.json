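{
  "model": {
    "backbone_depth": 18,
    "hidden_dim": 64,
    "num_queries": 20,
    "encoder_layers": 2,
    "decoder_layers": 2,
    "attention_heads": 8
  },
  "train": {
    "transformer_lr": 0.001,
    "backbone_lr": 0.0001,
    "epochs": 150,
    "lr_drop_epoch": 120,
    "batch_size": 32,
    "dropout": 0.0,
    "seed": 0,
    "backbone_depth": 18,
    "freeze_backbone": true,
    "aux_loss": true,
    "augment": false
  }
}
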