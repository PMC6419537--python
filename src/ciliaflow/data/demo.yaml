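# Demo run: a small synchronized-release experiment, end to end.
# Two replicates, five cells per condition, release times 0 / 0.5 / 1 h,
# coarser lateral sampling so the whole run stays in the minutes range.
seed: 0
output_dir: ciliaflow_demo
channels: [gfp, surface_apical, surface_basolateral, cilium]
imaging:
  voxel_size: [0.3, 0.2, 0.2]
simulate:
  n_cells: 5
  times_h: [0.0, 0.5, 1.0]
  replicates: 2
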