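# Default desk-scale run: corrugated well (T=10, A=5) at reduced size.
# Physics defaults (desk profile) live in the package; only the geometry,
# population and output cadence are set here.
well:
  width_um: 40
  height_um: 20
  period_um: 10
  amplitude_um: 5
population:
  n_cells: 70
  strain_mix:
    neutralA: 1.0
output:
  directory: out
  snapshot_every: 4.0
seed: 1
profile: desk
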