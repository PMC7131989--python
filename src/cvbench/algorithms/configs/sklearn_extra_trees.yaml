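# Extremely randomized trees
id: sklearn/extra_trees
default:
  n_estimators: 100
combos:
  - id: trees200
    params: {n_estimators: 200}
  - id: depth5
    params: {max_depth: 5}
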