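# End-to-end synthetic demo: simulate a two-state tracking experiment,
# detect transient confinement, estimate a photobleach-corrected lifetime
# and compute membrane packing numbers.  Run with:
#
#   slbkit run examples/demo_config.yaml
#
seed: 1
output_dir: slbkit_demo_out
stages:
  - name: simulate_tracks
    params:
      n_molecules: 50
      n_frames: 600
      d_free: 0.2          # um^2/s
      d_trapped: 0.002     # um^2/s
      k_bind: 0.3          # 1/s
      k_unbind: 1.5        # 1/s
      frame_interval: 0.051  # s
  - name: confine
    params:
      p_thresh: 1000.0     # um^-2
      t_thresh: 0.25       # s
  - name: lifetime
    params:
      simulate:
        k_off_true: 0.05         # 1/s
        bleach_rate: 4.0         # 1/s during exposure
        integration_time: 0.05   # s
        n_molecules_per_interval: 5000
  - name: packing
    params:
      footprint_nm2: 30.0
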