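# End-to-end demo: umbrella sampling of a 3-keto steroid in a raft-like
# bilayer potential (low central barrier, deep desorption wall), WHAM with
# bootstrap errors, feature extraction, and the two-step flip-flop rate model.
#
#   steroflip run examples/cnone_raft_pipeline.yaml --out-dir out/
out_dir: cnone-raft-run
stages:
  - name: umbrella
    kind: umbrella
    seed: 11
    potential:
      z_eq: 1.7          # nm, equilibrium head-group position
      dG_center: 6.4     # kJ/mol, barrier at the bilayer midplane
      dG_desorb: 65.4    # kJ/mol, desorption plateau in water
    k_bias: 750.0        # kJ/mol/nm^2
    run_time: 90.0       # ns per window
    equilibration_time: 10.0
  - name: pmf
    kind: wham
    input: umbrella
    seed: 12
    n_boot: 200
  - name: features
    kind: features
    input: pmf
    water_region: 3.0    # |z| >= 3 nm is bulk water
  - name: kinetics
    kind: kinetics
    input: features
    t_d_range: [1.0, 40.0]   # ns, center-to-equilibrium return time range
    mode: approx             # k_flip = k_f / 2
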