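# logistic regulation (r=1, gamma=1, F=1-m) on a short periodic habitat
domain: {dim: 1, lengths: [1.0], boundary: periodic}
demography:
  gamma: {name: constant, params: [1.0]}
  r: {name: constant, params: [1.0]}
  F: {name: logistic_F}
  theta: 5.0
  N: 50.0
  kernels:
    gamma: {family: gaussian, scale: 0.3}
    r: {family: gaussian, scale: 0.3}
    F: {family: gaussian, scale: 0.3}
dispersal: {sigma2: 1.0}
run: {T: 1.0, record_every: 0.25, density: 1.0}
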