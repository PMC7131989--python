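# Support vector machine with probability estimates
id: sklearn/svm
default:
  C: 1.0
  kernel: rbf
combos:
  - id: C0.1
    params: {C: 0.1}
  - id: C10
    params: {C: 10.0}
  - id: linear
    params: {kernel: linear}
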