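# Demonstration pipeline: every stage on synthetic data.
# Run:  actinmech run --config examples/demo.yaml --out demo_out
seed: 0
outdir: actinmech_demo
stages:
  simulate:
    wlc:
      n_nodes: 800
      b: 55.0
      lp_um: 12.21
      n_frames: 150
      rho: 0.0
    helix:
      n_subunits: 13
      rise: 27.5
      twist: -166.15
      radius: 25.0
      sigma_xyz: 0.5
      n_frames: 200
    filament:
      n_subunits: 5
      rise: 27.5
      twist: -166.15
      sigma_xyz: 0.3
      n_frames: 20
      n_residues: 375
    profiles:
      wt_rest:
        centre: 100.0
        sigma: 5.5
        amplitude: 1000.0
        slope: -0.5
        intercept: 300.0
        noise_sd: 10.0
      wt_act:
        centre: 98.2
        sigma: 5.5
        amplitude: 1400.0
        slope: -0.5
        intercept: 300.0
        noise_sd: 10.0
      mut_rest:
        centre: 100.0
        sigma: 5.5
        amplitude: 600.0
        slope: -0.5
        intercept: 300.0
        noise_sd: 10.0
        second:
        - 100.5
        - 9.5
        - 400.0
      mut_act:
        centre: 98.2
        sigma: 5.5
        amplitude: 600.0
        slope: -0.5
        intercept: 300.0
        noise_sd: 10.0
        second:
        - 100.5
        - 9.5
        - 400.0
    speeds:
      wt:
        weights:
        - 1.0
        means:
        - 2.6
        sds:
        - 0.5
        n: 150
      mut:
        weights:
        - 0.58
        - 0.42
        means:
        - 2.5
        - 4.5
        sds:
        - 0.4
        - 0.4
        n: 150
  mechanics: {}
  geometry:
    cutoff: 8.0
    representation: ca
    ddof: 0
  xray:
    centre_px: -900.0
    windows:
    - 3
    - 4
    flanks:
      left:
      - 40
      - 60
      right:
      - 140
      - 160
    pairs:
    - label: wt
      rest: wt_rest
      act: wt_act
    - label: mut
      rest: mut_rest
      act: mut_act
    fold_bands:
    - label: wt_activation
      a: wt_rest
      b: wt_act
      band:
      - 85
      - 115
  motility:
    threshold: 3.5
    n_restarts: 8
  stats:
    alpha_normality: 0.05
    compare:
    - label: wt_vs_mut
      x: wt
      y: mut
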