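# Logistic regression (liblinear solver); l1_ratio 0 = ridge, 1 = lasso
id: sklearn/logistic_regression
default:
  C: 1.0
  l1_ratio: 0
grid:
  C: [0.1, 1.0, 10.0]
  l1_ratio: [0, 1]
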