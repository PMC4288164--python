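# Demo pipeline configuration: seven 2-AP probe sites of a structured RNA
# at 20C, two-component intensity decays, biexponential anisotropy.
# Run:  tcspcfit pipeline --config examples/demo_config.yaml
seed: 20260921
outdir: pipeline_out
condition: 20C
grid:
  n_channels: 1024
  dwell_ns: 0.04
  t0_channel: 64
irf_fwhm_ns: 0.04
peak_counts: 10000
n_components: 2
r0: 0.31
quencher_concentrations_mM: [0, 25, 50, 100, 150, 200]
quench_noise_sd: 0.02
sites:
  "6":  {alphas: [0.6, 0.4], taus_ns: [0.3, 2.2], betas: [0.5, 0.5], phis_ns: [0.4, 5.6], kq: 4.7}
  "10": {alphas: [0.5, 0.5], taus_ns: [0.5, 3.2], betas: [0.4, 0.6], phis_ns: [0.5, 5.4], kq: 7.0}
  "24": {alphas: [0.5, 0.5], taus_ns: [0.4, 3.0], betas: [0.45, 0.55], phis_ns: [0.4, 4.9], kq: 20.4}
  "27": {alphas: [0.55, 0.45], taus_ns: [0.35, 2.6], betas: [0.6, 0.4], phis_ns: [0.3, 3.4], kq: 20.3}
  "35": {alphas: [0.5, 0.5], taus_ns: [0.5, 3.1], betas: [0.6, 0.4], phis_ns: [0.3, 3.5], kq: 4.2}
  "38": {alphas: [0.65, 0.35], taus_ns: [0.3, 2.0], betas: [0.55, 0.45], phis_ns: [0.35, 3.7], kq: 8.9}
  "41": {alphas: [0.6, 0.4], taus_ns: [0.4, 2.4], betas: [0.7, 0.3], phis_ns: [0.25, 3.2], kq: 6.8}
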