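# top-hat competition + short-range dispersal: unstable band in (pi, 2*pi)
stability:
  phi0: 1.0
  F0p: -1.0
  sigma2: 0.0025
  kernel_F: {family: tophat, scale: 1.0}
  kernel_gamma: {family: gaussian, scale: 1.0}
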