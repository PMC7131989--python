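# Stochastic gradient descent, logistic loss
id: sklearn/sgd
default:
  alpha: 0.0001
combos:
  - id: alpha0.01
    params: {alpha: 0.01}
  - id: elasticnet
    params: {penalty: elasticnet, l1_ratio: 0.5}
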