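# Gradient-boosted decision trees
id: sklearn/gradient_boosting
default:
  n_estimators: 100
  learning_rate: 0.1
combos:
  - id: lr0.01
    params: {learning_rate: 0.01}
  - id: depth5
    params: {max_depth: 5}
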