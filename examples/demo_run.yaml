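# End-to-end demo: generate a control/300 nM pair from the default
# calibrated state-binding model and recover the dissociation constants.
model:
  v_half: -75.2
  slope: 7.9
  drug_conc: 300.0
  kd_rest: 360.0
  kd_inact: 50.0
noise:
  sd: 0.0
  seed: 42
protocol:
  v_min: -130.0
  v_max: -20.0
  v_step: 5.0
run:
  outdir: statenav_out
  control_drift: 0.0
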