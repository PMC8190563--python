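"""End-to-end orchestration: simulate -> detect -> calibrate -> track -> QC.

A single structured config drives a full reproducible session: a four-point
calibration block, an optional pupil light-step block for the
pupil-decentration assessment, and arbitrary fixation segments.  Outputs
are the per-frame gaze recording, the calibration report, a QC table, a
metrics report and a run manifest (seed, config hash, versions).
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from .. import __version__
from ..calibrate import (
    CalibrationModel,
    acquire_point,
    compute_vergence,
    fit_calibration,
)
from ..detect import DetectionConfig, run_detection
from ..metrics import accuracy, precision_epoched
from ..quality import assess_pupil_artifact, correct_vergence, detect_blink, rolling_stats
from ..simulate import (
    EYES,
    OpticalConfig,
    Protocol,
    Segment,
    Simulation,
    cyclopean_target_deg,
    simulate_protocol,
)
from .recording import GazeRecording, RECORDING_COLUMNS, write_recording

__all__ = ["run_pipeline", "PipelineResult", "build_protocol"]


def _deg_to_screen_px(deg: float, cfg: OpticalConfig) -> float:
    return math.tan(math.radians(deg)) * cfg.screen_distance_mm / cfg.screen_pixel_pitch_mm


def build_protocol(config: dict, cfg: OpticalConfig) -> tuple[Protocol, dict]:
    """Expand a pipeline config into a concrete protocol.

    Returns the protocol plus a layout dict mapping stage names to segment
    index ranges.
    """
    segments: list[Segment] = []
    layout: dict[str, Any] = {}

    cal = config.get("calibration", {})
    if "targets_deg" not in cal and "half_width_deg" not in cal:
        raise ValueError("config.calibration must define 'half_width_deg' "
                         "or explicit 'targets_deg'")
    point_frames = int(cal.get("point_frames", 160))
    if "targets_deg" in cal:
        targets = [tuple(t) for t in cal["targets_deg"]]
    else:
        h = float(cal["half_width_deg"])
        targets = [(-h, h), (h, h), (h, -h), (-h, -h)]
    layout["calibration"] = (0, len(targets))
    for i, (gx, gy) in enumerate(targets):
        segments.append(Segment(
            duration_frames=point_frames,
            target_x_px=_deg_to_screen_px(gx, cfg),
            target_y_px=-_deg_to_screen_px(gy, cfg),
            label=f"cal{i}",
        ))

    art = config.get("artifact", {})
    if art.get("enabled", False):
        k0 = len(segments)
        dark = int(art.get("dark_frames", round(1.0 * cfg.frame_rate)))
        bright = int(art.get("bright_frames", 30))
        post = int(art.get("post_frames", round(0.6 * cfg.frame_rate)))
        grey = float(art.get("screen_grey", 150))
        segments.append(Segment(duration_frames=dark, screen_grey=0,
                                label="artifact_dark"))
        segments.append(Segment(duration_frames=bright, screen_grey=grey,
                                label="artifact_bright"))
        segments.append(Segment(duration_frames=post, screen_grey=0,
                                label="artifact_post"))
        layout["artifact"] = (k0, k0 + 3)

    k0 = len(segments)
    for i, seg in enumerate(config.get("segments", [])):
        seg = dict(seg)
        seg.setdefault("label", f"seg{i}")
        segments.append(Segment(**seg))
    layout["task"] = (k0, len(segments))
    return Protocol(segments), layout


@dataclass
class PipelineResult:
    cfg: OpticalConfig
    simulation: Simulation
    detections: dict[str, pd.DataFrame]
    model: CalibrationModel
    recording: GazeRecording
    gaze: dict[str, np.ndarray]          # per-eye (n, 2) calibrated gaze, deg
    artifact: Optional[object]
    metrics: dict
    manifest: dict
    paths: dict[str, Path] = field(default_factory=dict)


def _pcr_array(det: pd.DataFrame) -> np.ndarray:
    """(n, 2) PC-CR vectors with NaN rows for invalid frames."""
    pcr = np.column_stack([
        det["pupil_x"].to_numpy() - det["cr_x"].to_numpy(),
        det["pupil_y"].to_numpy() - det["cr_y"].to_numpy(),
    ])
    pcr[det["valid"].to_numpy() == 0] = np.nan
    return pcr


def _mask_blinks(x: np.ndarray, blink: np.ndarray, margin: int = 1) -> np.ndarray:
    """NaN out blink samples plus ``margin`` samples on each side."""
    from scipy import ndimage

    out = np.array(x, dtype=float)
    mask = ndimage.binary_dilation(blink, iterations=margin) if margin else blink
    out[mask] = np.nan
    return out


def run_pipeline(config: dict | str | Path, seed: int | None = None,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Run a complete session from a structured config.

    Fully reproducible from ``(config, seed)``; ``seed`` overrides any seed
    in the config.  When ``outdir`` is given, all artifacts are written
    there.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = dict(config)
    if seed is not None:
        config["seed"] = int(seed)
    seed = int(config.get("seed", 0))

    cfg = OpticalConfig.from_dict(config.get("optics", {}))
    det_cfg = DetectionConfig(magnification=cfg.magnification,
                              **config.get("detection", {}))
    protocol, layout = build_protocol(config, cfg)

    sim = simulate_protocol(protocol, cfg, seed)
    detections = {eye: run_detection(sim.frames(eye), det_cfg) for eye in EYES}
    pcr = {eye: _pcr_array(detections[eye]) for eye in EYES}

    # --- calibration -------------------------------------------------------
    cal_lo, cal_hi = layout["calibration"]
    seg_of_frame = sim.truth_for("left")["segment"].to_numpy()
    eyes_cal = {}
    for eye in EYES:
        points = []
        for k in range(cal_lo, cal_hi):
            in_seg = np.where(seg_of_frame == k)[0]
            target = cyclopean_target_deg(protocol.segments[k], cfg)
            samples = (pcr[eye][i] if np.all(np.isfinite(pcr[eye][i])) else None
                       for i in in_seg)
            points.append(acquire_point(samples, target, cfg,
                                        timeout=len(in_seg)))
        eyes_cal[eye] = fit_calibration(points)
    model = CalibrationModel(eyes=eyes_cal,
                             screen_distance_mm=cfg.screen_distance_mm)

    # --- gaze mapping, blinks, vergence -----------------------------------
    gaze = {eye: np.atleast_2d(pcr[eye]) @ eyes_cal[eye].gain.T + eyes_cal[eye].offset
            for eye in EYES}
    pupil_mm = {eye: detections[eye]["pupil_mm"].to_numpy() for eye in EYES}
    blink = detect_blink(pupil_mm["left"]) | detect_blink(pupil_mm["right"])
    verg_raw = compute_vergence(gaze["left"][:, 0], gaze["right"][:, 0], cfg)

    # --- pupil-artifact assessment ----------------------------------------
    artifact = None
    verg_corr = verg_raw.copy()
    if "artifact" in layout:
        a_lo, _ = layout["artifact"]
        sel = (seg_of_frame == a_lo + 1) | (seg_of_frame == a_lo + 2)
        with warnings.catch_warnings():
            # frames with both eyes lost are legitimately all-NaN
            warnings.simplefilter("ignore", category=RuntimeWarning)
            pup = np.nanmean(np.column_stack([pupil_mm["left"],
                                              pupil_mm["right"]]), axis=1)
        pup_fit = _mask_blinks(pup[sel], blink[sel])
        verg_fit = _mask_blinks(verg_raw[sel], blink[sel])
        artifact = assess_pupil_artifact(pup_fit, verg_fit)
        verg_corr = correct_vergence(verg_raw, pup, artifact)

    # --- recording ---------------------------------------------------------
    truth_l = sim.truth_for("left")
    x_px = {eye: np.tan(np.radians(gaze[eye][:, 0])) * cfg.screen_distance_mm
            / cfg.screen_pixel_pitch_mm for eye in EYES}
    rec_df = pd.DataFrame({
        "computer_time": truth_l["time_s"].to_numpy(),
        "frame_number": truth_l["frame_index"].to_numpy(),
        "pupil_left_mm": pupil_mm["left"],
        "pupil_right_mm": pupil_mm["right"],
        "x_left_px": x_px["left"],
        "x_right_px": x_px["right"],
        "vergence_raw_arcmin": verg_raw,
        "vergence_corrected_arcmin": verg_corr,
        "target_x": truth_l["target_x_px"].to_numpy(),
        "target_y": truth_l["target_y_px"].to_numpy(),
        "ttl": truth_l["ttl"].to_numpy(),
        "blink": blink.astype(int),
    })
    # any residual NaN sample is unusable: flag and zero it like a blink row
    nan_rows = rec_df[["pupil_left_mm", "pupil_right_mm", "x_left_px",
                       "x_right_px"]].isna().any(axis=1)
    rec_df.loc[nan_rows, "blink"] = 1
    recording = GazeRecording(rec_df)

    # --- per-segment metrics ----------------------------------------------
    metrics_report: dict[str, Any] = {}
    t_lo, t_hi = layout["task"]
    for k in range(t_lo, t_hi):
        seg = protocol.segments[k]
        sel = seg_of_frame == k
        tgt = cyclopean_target_deg(seg, cfg)
        entry: dict[str, Any] = {"target_deg": list(tgt)}
        for eye in EYES:
            g = np.array(gaze[eye][sel])
            g[_settle_mask(int(sel.sum()), cfg)] = np.nan
            g[:, 0] = _mask_blinks(g[:, 0], blink[sel])
            g[:, 1] = _mask_blinks(g[:, 1], blink[sel])
            acc = accuracy(g, tgt)
            entry[eye] = {
                "precision_rms_h": precision_epoched(g[:, 0], cfg.frame_rate),
                "precision_rms_v": precision_epoched(g[:, 1], cfg.frame_rate),
                "precision_sd_h": precision_epoched(g[:, 0], cfg.frame_rate, kind="sd"),
                "precision_sd_v": precision_epoched(g[:, 1], cfg.frame_rate, kind="sd"),
                "accuracy_deg": acc.mean_offset_deg,
                "mean_gaze_deg": [np.nanmean(g[:, 0]), np.nanmean(g[:, 1])],
                "n_valid": acc.n,
            }
        metrics_report[seg.label] = entry

    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest(),
        "pccr_version": __version__,
        "numpy_version": np.__version__,
        "n_frames": protocol.n_frames,
    }

    result = PipelineResult(cfg=cfg, simulation=sim, detections=detections,
                            model=model, recording=recording, gaze=gaze,
                            artifact=artifact, metrics=metrics_report,
                            manifest=manifest)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        result.paths["recording"] = write_recording(recording,
                                                    outdir / "recording.csv")
        model.save(outdir / "calibration.json")
        result.paths["calibration"] = outdir / "calibration.json"
        qc = rolling_stats(pcr["left"], cfg=cfg)
        qc["blink"] = blink.astype(int)
        qc.to_csv(outdir / "qc.csv", index=False, float_format="%.6g")
        result.paths["qc"] = outdir / "qc.csv"
        report: dict[str, Any] = {"metrics": metrics_report}
        if artifact is not None:
            report["artifact"] = {
                "slope_arcmin_per_mm": artifact.slope,
                "intercept_arcmin": artifact.intercept,
                "slope_se": artifact.slope_se,
                "p_value": artifact.p_value,
                "significant": artifact.significant,
                "reference_pupil_mm": artifact.reference_pupil,
                "n": artifact.n,
            }
        (outdir / "metrics.json").write_text(
            json.dumps(_jsonable(report), indent=2))
        result.paths["metrics"] = outdir / "metrics.json"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        result.paths["manifest"] = outdir / "manifest.json"
    return result


def _settle_mask(n: int, cfg: OpticalConfig) -> np.ndarray:
    """Mask for the saccadic transition at a segment start (plus margin)."""
    mask = np.zeros(n, dtype=bool)
    mask[:min(cfg.saccade_frames + 3, n)] = True
    return mask


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj
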