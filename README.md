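# pccr

Binocular pupil-center/corneal-reflection (PC-CR) video eye tracking as a
tested software pipeline. A built-in model-eye simulator stands in for the
camera hardware and supplies exact ground truth, so every stage — detection,
calibration, real-time quality analysis, pupil-artifact-corrected vergence
and evaluation metrics — can be exercised and verified end to end.

## What is in the box

| Module | Purpose |
| --- | --- |
| `pccr.simulate` | Model-eye frame renderer and protocol simulator: dark pupil disc, saturated corneal-reflection (CR) disc displaced per the Hirschberg ratio (1 mm per ~12 deg), eyelid blinks, pupil light responses, minimum-jerk saccades, binocular fixation at different depths, seeded noise. |
| `pccr.detect` | Per-frame detection: pupil by thresholding at 0.6 x mean ROI brightness + centre of mass (radius = sqrt(area/pi)); CR by a fixed threshold of 250; sub-pixel PC-CR vectors with ROI tracking. |
| `pccr.calibrate` | Automated four-point per-eye calibration: fixation-stability trigger (running SD < 0.5 deg over 25 samples), 100-sample averages, least-squares affine map, linear extrapolation, absolute vergence in arcmin. |
| `pccr.quality` | Running noise statistics (SD and mean absolute successive difference over the latest 25 samples), blink detection (running pupil-size SD > 0.2 mm), pupil-decentration artifact regression and vergence correction. |
| `pccr.metrics` | Precision RMS (inter-sample distances) and SD, accuracy, one-second epoching, velocity-threshold saccade detection and event metrics (latency, duration, amplitude, peak velocity). |
| `pccr.io_cli` | Frame streams (multi-page TIFF, PNG directories), the per-frame recording CSV, the pipeline orchestrator and the CLI. |

Conventions used throughout: pixels are 0-based with x rightward and y
downward; gaze is in degrees with positive horizontal = rightward and
positive vertical = upward; vergence is positive for convergence. Default
optics: 39.7 pixel/mm (25.2 um/pixel), 640x480 8-bit frames at 395 Hz,
60 mm interpupillary distance, screen at 540 mm.

## CLI

All commands live under a single `pccr` entry point:

```bash
pccr simulate --protocol proto.yaml --config config.yaml --seed 1 --out frames/
pccr detect   --frames frames/left.tif --config config.yaml --out det_left.csv
pccr qc       --trace det_left.csv --config config.yaml --out qc.csv
pccr calibrate --frames-left frames/left.tif --frames-right frames/right.tif \
               --targets targets.yaml --config config.yaml --out model.json
pccr track    --frames-left ... --frames-right ... --model model.json --out rec.csv
pccr pupil-artifact --trace rec.csv --out artifact.json
pccr metrics  --trace rec.csv --out metrics.json
pccr run      --config examples/session.yaml --seed 1 --out out/
```

`pccr run` executes the whole chain (simulate -> detect -> calibrate ->
track -> QC -> metrics) from one config; see `examples/session.yaml`.
Identical `(config, seed)` pairs produce byte-identical outputs, and a
`manifest.json` records seed, config hash and versions.

### File formats

* **Frame streams** — one multi-page 8-bit grey TIFF per camera
  (`left.tif`, `right.tif`); a directory of PNG frames is accepted on read.
* **Truth CSV** (simulator) — `frame_index, time_s, eye, gaze_h_deg,
  gaze_v_deg, pupil_mm, vergence_deg, blink`.
* **Detection CSV** — `frame_index, time_s, camera_id, pupil_x, pupil_y,
  pupil_area, pupil_mm, cr_x, cr_y, cr_area, valid`.
* **Recording CSV** (one row per frame) — `computer_time, frame_number,
  pupil_left_mm, pupil_right_mm, x_left_px, x_right_px,
  vergence_raw_arcmin, vergence_corrected_arcmin, target_x, target_y, ttl,
  blink`. Rows flagged as blinks carry zeros in all measured data columns;
  `ttl` is 1 only on frames where a new target appears.
* **Calibration model** — JSON with per-eye 2x2 gain, offset, stored
  calibration points and residuals.

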