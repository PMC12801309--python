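# Demo pipeline: CD+ stacked on a terminal base pair of a 12-bp duplex,
# short noisy trajectory, helical-parameter and binding-mode reports.
seed: 5
out_dir: cdnakit_run
cd:
  layers: [2, 3, 3, 3, 2]
  group: NH3+
  count: 9
na:
  sequence: ACGTACGTACGT
pose:
  mode: terminal_stack
trajectory:
  frames: 20
  sigma: 0.02
analyses: [helix, modes, contacts, shape]
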