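# Central-stimulus propagation on a reduced microstructured sheet
# (two-variable model for speed; switch to model: bdk with dt_o: 0.0001
# for the full ionic dynamics).  Run:  micromyo run --config examples/central_stimulus.yaml
mesh:
  units_x: 2
  units_y: 4
model: test
dt_p: 0.05
dt_o: 0.05
duration: 8.0
stimuli:
  - type: central
    amplitude: 500.0
    duration: 2.0
    half_width_um: 60.0
probes:
  - [40, 36]
  - [120, 36]
snapshot_every_ms: 2.0
output_dir: out/central
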