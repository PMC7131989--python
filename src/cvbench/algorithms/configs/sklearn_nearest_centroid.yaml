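# Nearest centroid (discrete predictions only; wrapped one-hot)
id: sklearn/nearest_centroid
default: {}
combos:
  - id: shrink0.2
    params: {shrink_threshold: 0.2}
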