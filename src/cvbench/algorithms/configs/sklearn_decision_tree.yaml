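# Single decision tree
id: sklearn/decision_tree
default: {}
grid:
  max_depth: [3, 5, null]
  criterion: [gini, entropy]
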