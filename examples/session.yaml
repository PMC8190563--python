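# Demo session for `pccr run`: four-point calibration, a pupil light-step
# with artifact assessment, then two fixation targets.
seed: 1
optics:
  magnification: 39.7
  frame_rate: 395.0
  artifact_coefficient: 0.02      # pupil decentration on the left eye, mm/mm
calibration:
  half_width_deg: 4.0
  point_frames: 160
artifact:
  enabled: true
  dark_frames: 400
  bright_frames: 200
  post_frames: 240
  screen_grey: 150
segments:
  - {duration_frames: 400, target_x_px: 0, target_y_px: 0, label: fix_center}
  - {duration_frames: 400, target_x_px: 70, target_y_px: -50, label: fix_off}
  - {duration_frames: 400, target_x_px: 0, target_y_px: 0, blinks: [100], label: fix_blink}
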