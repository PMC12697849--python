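# Full synthetic pipeline: 4 virtual specimens with a 2x2 tumor block,
# calibration standards at pH 2..9, ratiometric prediction, map rendering
# and the diagnostic report.
seed: 1
out_dir: acidmap-run
simulate:
  n_specimens: 4
  grid_rows: 6
  grid_cols: 6
  pitch_mm: 3.0
  tumor_block: [1, 1, 2, 2]   # rows 1-2 x cols 1-2
  calibration_levels: [2, 3, 4, 5, 6, 7, 8, 9]
  calibration_replicates: 3
predict:
  method: ratiometric          # or "model" to train the network first
map:
  threshold: 6.845
evaluate:
  threshold: 6.845
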