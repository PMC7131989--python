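# Gradient boosting via xgboost
id: xgboost/xgboost
default:
  n_estimators: 100
  max_depth: 6
combos:
  - id: depth2
    params: {max_depth: 2}
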