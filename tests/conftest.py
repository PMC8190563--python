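"""Shared fixtures.

The expensive rendered sessions (calibration grids, blink and light-step
runs) are session-scoped so unit, property and acceptance tests reuse the
same streams.
"""

from __future__ import annotations

import numpy as np
import pytest

from pccr.calibrate import acquire_point, fit_calibration
from pccr.detect import DetectionConfig, run_detection
from pccr.io_cli.pipeline import _deg_to_screen_px, _pcr_array
from pccr.simulate import (
    OpticalConfig,
    Protocol,
    Segment,
    cyclopean_target_deg,
    simulate_protocol,
)

CAL_CORNERS = [(-4.0, 4.0), (4.0, 4.0), (4.0, -4.0), (-4.0, -4.0)]


def recover_saccade_amplitude(amplitude: float, *, n_events: int = 60,
                              frame_rate: float = 395.0,
                              noise_sd_deg: float = 0.02,
                              seed: int | None = None) -> tuple[int, float]:
    """Simulate minimum-jerk saccades of a programmed amplitude in a noisy
    gaze trace, detect them with the velocity-threshold detector and return
    (number matched to truth, mean recovered amplitude)."""
    from pccr.metrics import detect_events_velocity, event_metrics

    rng = np.random.default_rng(seed if seed is not None else int(amplitude * 10))
    nsac = max(3, int(round((0.010 + 0.0025 * amplitude) * frame_rate)))
    gap = 120
    pos, truth = [0.0], []
    for k in range(n_events):
        start = len(pos) + gap
        pos += [pos[-1]] * gap
        target = pos[-1] + (amplitude if k % 2 == 0 else -amplitude)
        tau = np.arange(1, nsac + 1) / nsac
        s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
        pos += list(pos[-1] + (target - pos[-1]) * s)
        truth.append((start, start + nsac))
    pos += [pos[-1]] * gap
    x = np.asarray(pos) + rng.normal(0, noise_sd_deg, len(pos))
    trace = np.column_stack([x, np.zeros_like(x)])
    events = detect_events_velocity(trace, frame_rate, velocity_threshold=15.0)
    matched = []
    for lo, hi in truth:
        hits = [e for e in events if e[0] <= hi and e[1] >= lo]
        if hits:
            on = min(h[0] for h in hits)
            off = max(h[1] for h in hits)
            em = event_metrics(trace, (max(on - 4, 0),
                                       min(off + 4, len(x) - 1)), frame_rate)
            matched.append(em.amplitude_deg)
    return len(matched), float(np.mean(matched)) if matched else float("nan")
GRID_TARGETS = [(gx, gy) for gy in (-2.7, 0.0, 2.7) for gx in (-2.7, 0.0, 2.7)]


@pytest.fixture(scope="session")
def default_cfg() -> OpticalConfig:
    return OpticalConfig()


@pytest.fixture(scope="session")
def noiseless_cfg() -> OpticalConfig:
    return OpticalConfig(noise_sd=0.0, gradient_sd=0.0)


def _grid_protocol(cfg: OpticalConfig, point_frames: int = 160,
                   grid_frames: int = 100) -> Protocol:
    px = lambda d: _deg_to_screen_px(d, cfg)
    segs = [Segment(point_frames, px(gx), -px(gy), label=f"cal{i}")
            for i, (gx, gy) in enumerate(CAL_CORNERS)]
    segs += [Segment(grid_frames, px(gx), -px(gy), label=f"grid{i}")
             for i, (gx, gy) in enumerate(GRID_TARGETS)]
    return Protocol(segs)


def run_grid_session(cfg: OpticalConfig, seed: int) -> dict:
    """Calibrate on the +/-4 deg corners, then map gaze on a 3x3 test grid.

    Returns per-eye fitted calibrations, per-segment mapped-gaze sample
    arrays and the cyclopean truth targets.
    """
    protocol = _grid_protocol(cfg)
    sim = simulate_protocol(protocol, cfg, seed)
    seg_of = sim.truth_for("left")["segment"].to_numpy()
    out = {"sim": sim, "cfg": cfg, "eyes": {}, "targets": {}}
    for eye in ("left", "right"):
        det = run_detection(sim.frames(eye),
                            DetectionConfig(magnification=cfg.magnification))
        pcr = _pcr_array(det)
        points = []
        for k in range(4):
            idx = np.where(seg_of == k)[0]
            target = cyclopean_target_deg(protocol.segments[k], cfg)
            samples = (pcr[i] if np.all(np.isfinite(pcr[i])) else None
                       for i in idx)
            points.append(acquire_point(samples, target, cfg, timeout=len(idx)))
        cal = fit_calibration(points)
        gaze_by_seg = {}
        for k in range(4, 4 + len(GRID_TARGETS)):
            idx = np.where(seg_of == k)[0][20:]   # drop saccade + settling
            gaze_by_seg[k - 4] = np.atleast_2d(pcr[idx]) @ cal.gain.T + cal.offset
            out["targets"][k - 4] = np.array(
                cyclopean_target_deg(protocol.segments[k], cfg))
        out["eyes"][eye] = {"cal": cal, "gaze": gaze_by_seg, "pcr": pcr,
                            "detections": det}
    return out


@pytest.fixture(scope="session")
def grid_session_noisy(default_cfg):
    return run_grid_session(default_cfg, seed=11)


@pytest.fixture(scope="session")
def grid_session_noiseless(noiseless_cfg):
    return run_grid_session(noiseless_cfg, seed=0)


@pytest.fixture(scope="session")
def blink_session(default_cfg):
    """One eye, 10 programmed blinks over ~4.5 s of fixation."""
    onsets = tuple(100 + 170 * i for i in range(10))
    protocol = Protocol([Segment(1800, 0, 0, blinks=onsets, label="fix")])
    sim = simulate_protocol(protocol, default_cfg, seed=21)
    det = run_detection(sim.frames("left"),
                        DetectionConfig(magnification=default_cfg.magnification))
    return {"sim": sim, "detections": det, "onsets": onsets}


@pytest.fixture(scope="session")
def artifact_session():
    """Binocular light-step session with a decentration artifact on the left
    eye; reduced frame rate keeps the rendered stream short."""
    cfg = OpticalConfig(frame_rate=150.0, artifact_coefficient=0.02)
    px = lambda d: _deg_to_screen_px(d, cfg)
    segs = [Segment(140, px(gx), -px(gy), label=f"cal{i}")
            for i, (gx, gy) in enumerate(CAL_CORNERS)]
    segs += [
        Segment(150, 0, 0, screen_grey=0, label="dark"),
        Segment(225, 0, 0, screen_grey=150, label="bright"),
        Segment(90, 0, 0, screen_grey=0, label="post"),
    ]
    protocol = Protocol(segs)
    sim = simulate_protocol(protocol, cfg, seed=5)
    seg_of = sim.truth_for("left")["segment"].to_numpy()
    eyes = {}
    for eye in ("left", "right"):
        det = run_detection(sim.frames(eye),
                            DetectionConfig(magnification=cfg.magnification))
        pcr = _pcr_array(det)
        points = []
        for k in range(4):
            idx = np.where(seg_of == k)[0]
            target = cyclopean_target_deg(protocol.segments[k], cfg)
            samples = (pcr[i] if np.all(np.isfinite(pcr[i])) else None
                       for i in idx)
            points.append(acquire_point(samples, target, cfg, timeout=len(idx)))
        cal = fit_calibration(points)
        eyes[eye] = {"gaze": np.atleast_2d(pcr) @ cal.gain.T + cal.offset,
                     "pupil_mm": det["pupil_mm"].to_numpy()}
    # regression window: stimulus onset to 600 ms after offset
    window = (seg_of == 5) | (seg_of == 6)
    return {"sim": sim, "cfg": cfg, "eyes": eyes, "window": window}
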