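# Random forest
id: sklearn/random_forest
default:
  n_estimators: 100
combos:
  - id: trees50
    params: {n_estimators: 50}
  - id: trees200
    params: {n_estimators: 200}
  - id: sqrt_depth5
    params: {max_depth: 5}
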