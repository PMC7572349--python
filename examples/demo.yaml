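# Demo pipeline config: small synthetic cohort with one known strong effect.
# Run with:  cmnet run-all --config examples/demo.yaml --out demo-run
top_k: 30
k_f: 5
alpha: 0.5
r: 0.01
classify: true
seed: 7
output_dir: demo-run
synthetic:
  n_group_a: 40
  n_group_b: 40
  n_rois: 10
  measurements: [cortical_thickness, sulcal_depth]
  hemispheres: [lh]
  baseline_sd: 1.0
  seed: 7
  injected_effects:
    - {measurement: cortical_thickness, roi_index: 2, group: female, mean_shift: 3.0}
    - {measurement: sulcal_depth, roi_index: 2, group: female, mean_shift: 3.0}
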