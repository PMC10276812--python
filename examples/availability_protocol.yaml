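# Steady-state availability step: equilibrate at -100 mV, 5-s prepulse to
# -70 mV, read availability at the start of the +10 mV test pulse.
label: steady-state availability at -70 mV
epochs:
  - [-100, 0]
  - [-70, 5000]
  - [10, 10]
measure_epochs: [1]
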