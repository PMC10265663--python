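# Synthetic ring-opening sweep: five degrees of ring opening, dry systems.
# Run with:  polytherm run --config examples/study.yaml
seed: 1
output_dir: study_output
stages: [tg, tensile, diffusivity, hbonds, ffv, xrd]
systems:
  - label: ro0
    ro_fraction: 0.0
  - label: ro25
    ro_fraction: 0.25
  - label: ro50
    ro_fraction: 0.5
  - label: ro75
    ro_fraction: 0.75
  - label: ro100
    ro_fraction: 1.0
params:
  diffusivity: {n_particles: 30, n_frames: 200}
  hbonds: {n_bonds: 150, n_frames: 400}
  ffv: {n_atoms: 30, resolution: 0.03}
  xrd: {n_cells: 3}
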