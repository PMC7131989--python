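# Gaussian naive Bayes
id: sklearn/gaussian_nb
default:
  var_smoothing: 1.0e-09
combos:
  - id: smooth1e-6
    params: {var_smoothing: 1.0e-06}
  - id: smooth1e-3
    params: {var_smoothing: 1.0e-03}
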