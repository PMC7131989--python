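# Multilayer perceptron
id: sklearn/mlp
default:
  hidden_layer_sizes: [32]
  max_iter: 500
  alpha: 0.0001
combos:
  - id: wide
    params: {hidden_layer_sizes: [128]}
  - id: deep
    params: {hidden_layer_sizes: [32, 32]}
  - id: alpha0.01
    params: {alpha: 0.01}
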