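# Synthetic reflective diSPIM run: bead phantom, symmetric 45-degree mirror,
# joint dual-view generalized Richardson-Lucy reconstruction.
objective:
  na: 1.1
  tilt_deg: 45.0
sheet:
  fwhm_um: 1.6
mirror:
  theta_deg: 45.0
  reflectivity: 1.0
grid:
  shape: [32, 16, 32]
  pitch_um: 0.1
phantom:
  kind: bead
  positions_um: [[0.7, 0.0, 0.7]]
deconvolution:
  mode: dual
  iterations: 6
  psf_model: gaussian
  wavelength_um: 0.525
  psf_shape: [21, 11, 11]
seed: 1
output_dir: scratch/example_run
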