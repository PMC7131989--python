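# k-nearest neighbors
id: sklearn/knn
default:
  n_neighbors: 5
grid:
  n_neighbors: [1, 5, 15]
  weights: [uniform, distance]
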