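# Fisher-KPP front from a Heaviside initial condition
pde: {dx: 0.2, length: 400.0, edge: 20.0}
run: {T: 150.0, dt: 0.008, record_every: 1.0}
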