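# Full synthetic pipeline: unextracted onion-epidermis scene at 10 keV.
# Any omitted section falls back to the package defaults; unknown keys
# are rejected. Run with:
#   celltex run --config examples/demo_config.yaml --seed 1 --outdir demo
beam:
  energy_keV: 10.0
  incidence_deg: 0.15
scene:
  preset: unextracted
  sigma_chi_deg: 20.0
rocking:
  n_frames: 11
  half_range_deg: 0.75
polefigure:
  match_chi_deg: 7.5
  weighting: sin_chi
  chi0_deg: 34.0
seed: 1
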