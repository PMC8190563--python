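"""Model-eye video simulator for a binocular PC-CR tracker.

Generates 8-bit monochrome eye-camera frame streams together with exact
per-frame ground truth, replacing the camera hardware so that detection,
calibration and analysis stages can be exercised end to end.

Coordinate and sign conventions (used throughout the package):

* Image pixels are 0-based, ``x`` rightward, ``y`` downward.
* Gaze angles are in degrees, positive horizontal = rightward,
  positive vertical = upward.
* Vergence is positive for convergence (near targets).
* Screen coordinates are pixels relative to the screen centre,
  ``x`` rightward, ``y`` downward (as seen by the participant).

The eye model is purely 2-D image-plane geometry: a dark pupil disc, a
bright corneal-reflection (first Purkinje image) disc whose displacement
relative to the pupil centre follows the Hirschberg ratio, and an eyelid
occluder.  The corneal reflection moves by ``gaze / hirschberg_ratio``
millimetres relative to the pupil centre, so for a noiseless frame

    (cr_centroid - pupil_centroid) / magnification * hirschberg_ratio

recovers the true gaze angle.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "OpticalConfig",
    "EyeStateTruth",
    "Segment",
    "Protocol",
    "Simulation",
    "vergence_from_distance",
    "cr_displacement",
    "pupil_response",
    "render_eye_frame",
    "simulate_protocol",
    "minimum_jerk",
]

EYES = ("left", "right")

TRUTH_COLUMNS = [
    "frame_index",
    "time_s",
    "eye",
    "gaze_h_deg",
    "gaze_v_deg",
    "pupil_mm",
    "vergence_deg",
    "blink",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Optical geometry and rendering parameters of the simulated set-up.

    Defaults reproduce the nominal bench geometry: 39.7 pixel/mm video
    magnification (25.2 um/pixel), a Hirschberg ratio of 12 degrees of eye
    rotation per millimetre of relative Purkinje-image displacement,
    640x480 frames at 395 Hz, and a 60 mm interpupillary distance with the
    screen at 540 mm.
    """

    magnification: float = 39.7          # pixel per mm in the image plane
    hirschberg_ratio: float = 12.0       # deg of eye rotation per mm of CR-vs-PC shift
    frame_width: int = 640
    frame_height: int = 480
    frame_rate: float = 395.0            # Hz
    pupil_grey: float = 20.0
    background_grey: float = 120.0
    cr_grey: float = 400.0               # pre-saturation radiance; clipped to 255 in the
                                         # frame, so noise cannot unsaturate the CR core
    cr_diameter_mm: float = 0.58
    noise_sd: float = 6.0                # additive per-pixel Gaussian noise, grey levels
    gradient_sd: float = 0.16            # per-frame random shading gradient, grey/pixel
    gradient_window_px: float = 160.0    # Gaussian window of the shading gradient
    edge_width_px: float = 2.5           # anti-aliased edge ramp width of rendered discs
    ipd_mm: float = 60.0                 # interpupillary distance
    screen_distance_mm: float = 540.0
    screen_pixel_pitch_mm: float = 0.283
    pupil_motion_mm_per_deg: float = 0.15  # image-plane pupil translation per deg of gaze
    # pupil light-response kinetics (plumbing, configurable)
    pupil_baseline_mm: float = 6.0
    pupil_constricted_mm: float = 4.0
    pupil_latency_s: float = 0.25
    pupil_tau_s: float = 0.4
    bright_screen_grey: float = 100.0    # screen grey at/above which the pupil constricts
    # pupil-decentration artifact emulation
    artifact_coefficient: float = 0.0    # mm of pupil-centre shift per mm of pupil diameter
    artifact_reference_mm: float = 4.0
    artifact_eyes: tuple[str, ...] = ("left",)
    # blink / saccade kinematics
    blink_down_frames: int = 40
    blink_up_frames: int = 40
    blink_aperture_threshold: float = 0.6
    saccade_frames: int = 12
    max_gaze_deg: float = 20.0

    def __post_init__(self) -> None:
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.ipd_mm <= 0:
            raise ValueError("ipd_mm must be positive")
        if not (self.cr_grey > 250 > self.background_grey > self.pupil_grey >= 0):
            raise ValueError(
                "grey levels must satisfy cr_grey > 250 > background_grey "
                "> pupil_grey >= 0"
            )

    @property
    def um_per_px(self) -> float:
        """Image-plane sampling pitch in micrometres per pixel."""
        return 1000.0 / self.magnification

    @property
    def deg_per_px(self) -> float:
        """Nominal gaze angle per pixel of PC-CR displacement."""
        return self.hirschberg_ratio / self.magnification

    @property
    def arcmin_per_px(self) -> float:
        return self.deg_per_px * 60.0

    @property
    def frame_shape(self) -> tuple[int, int]:
        return (self.frame_height, self.frame_width)

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalConfig":
        d = dict(d)
        if "artifact_eyes" in d:
            d["artifact_eyes"] = tuple(d["artifact_eyes"])
        return cls(**d)


@dataclass
class EyeStateTruth:
    """Ground-truth eye state for one frame of one eye."""

    frame_index: int
    eye: str
    gaze_h: float                    # degrees, + rightward
    gaze_v: float                    # degrees, + upward
    pupil_diameter_mm: float
    pupil_center_offset_mm: float = 0.0   # horizontal decentration vs anatomical axis
    eyelid_aperture: float = 1.0
    blink: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.pupil_diameter_mm < 10.0):
            raise ValueError("pupil_diameter_mm must be in (0, 10) mm")
        if not (0.0 <= self.eyelid_aperture <= 1.0):
            raise ValueError("eyelid_aperture must be in [0, 1]")
        if self.eye not in EYES:
            raise ValueError(f"eye must be one of {EYES}")


@dataclass
class Segment:
    """One protocol segment: a fixation target held for a number of frames.

    The target is either a screen position (pixels from screen centre) or a
    midline depth target at ``target_distance_mm``.  ``blinks`` lists blink
    onset frames relative to the segment start.
    """

    duration_frames: int
    target_x_px: float = 0.0
    target_y_px: float = 0.0
    target_distance_mm: float | None = None
    screen_grey: float = 0.0
    blinks: tuple[int, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        if int(self.duration_frames) != self.duration_frames or self.duration_frames <= 0:
            raise ValueError("duration_frames must be a positive integer")
        self.duration_frames = int(self.duration_frames)
        self.blinks = tuple(int(b) for b in self.blinks)


@dataclass
class Protocol:
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol must contain at least one segment")

    @property
    def n_frames(self) -> int:
        return sum(s.duration_frames for s in self.segments)

    @classmethod
    def from_dict(cls, d: dict | list) -> "Protocol":
        segs = d["segments"] if isinstance(d, dict) else d
        return cls([Segment(**dict(s)) for s in segs])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Protocol":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# geometry / kinetics primitives
# ---------------------------------------------------------------------------

def vergence_from_distance(distance_mm, cfg: OpticalConfig | None = None, *,
                           ipd_mm: float | None = None):
    """Binocular vergence angle (degrees) for a midline target at ``distance_mm``.

    ``2 * atan((ipd/2) / distance)``: strictly decreasing in distance and
    approaching zero (parallel gaze) at infinity.
    """
    if ipd_mm is None:
        ipd_mm = (cfg or OpticalConfig()).ipd_mm
    d = np.asarray(distance_mm, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distance must be positive")
    out = 2.0 * np.degrees(np.arctan((ipd_mm / 2.0) / d))
    return float(out) if np.isscalar(distance_mm) else out


def cr_displacement(gaze_deg, cfg: OpticalConfig | None = None):
    """Displacement (mm) of the corneal reflection relative to the pupil
    centre for an eye rotation of ``gaze_deg`` degrees (Hirschberg ratio)."""
    hr = (cfg or OpticalConfig()).hirschberg_ratio
    out = np.asarray(gaze_deg, dtype=float) / hr
    return float(out) if np.isscalar(gaze_deg) else out


def pupil_response(t, baseline: float, constricted: float, latency: float,
                   tau: float, stim_duration: float = math.inf):
    """Pupil diameter (mm) at time ``t`` (s) after light-stimulus onset.

    First-order exponential approach from ``baseline`` toward ``constricted``
    starting ``latency`` seconds after onset, relaxing back toward baseline
    the same latency after stimulus offset.  Continuous in ``t``.
    """
    if not (baseline > constricted > 0):
        raise ValueError("require baseline > constricted > 0")
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.asarray(t, dtype=float)
    d = np.full(t.shape, baseline, dtype=float)
    t_on = latency
    t_off = latency + stim_duration
    going = (t >= t_on) & (t < t_off)
    d[going] = constricted + (baseline - constricted) * np.exp(-(t[going] - t_on) / tau)
    if np.isfinite(t_off):
        d_off = constricted + (baseline - constricted) * np.exp(-stim_duration / tau)
        back = t >= t_off
        d[back] = baseline + (d_off - baseline) * np.exp(-(t[back] - t_off) / tau)
    return float(d) if d.ndim == 0 else d


def minimum_jerk(tau):
    """Minimum-jerk position profile, 0 -> 1 over normalised time in [0, 1]."""
    tau = np.clip(np.asarray(tau, dtype=float), 0.0, 1.0)
    out = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=8)
def _gradient_ramps(cfg: OpticalConfig) -> tuple[np.ndarray, np.ndarray]:
    """Windowed unit-gradient ramps, cached per config."""
    h, w = cfg.frame_shape
    xr = np.arange(w) - (w - 1) / 2.0
    yr = np.arange(h) - (h - 1) / 2.0
    window = np.exp(-(yr[:, None] ** 2 + xr[None, :] ** 2)
                    / (2.0 * cfg.gradient_window_px ** 2))
    return xr[None, :] * window, yr[:, None] * window


def _paint_disc(img: np.ndarray, cx: float, cy: float, radius: float,
                value: float, edge_width: float) -> bool:
    """Alpha-composite an anti-aliased disc onto ``img``.

    The edge is a linear coverage ramp of width ``edge_width`` pixels, which
    gives sub-pixel centroid placement and realistic threshold sensitivity.
    Returns True when the disc lies fully inside the frame.
    """
    h, w = img.shape
    r_out = radius + edge_width / 2.0
    x0 = max(int(math.floor(cx - r_out)) - 1, 0)
    x1 = min(int(math.ceil(cx + r_out)) + 2, w)
    y0 = max(int(math.floor(cy - r_out)) - 1, 0)
    y1 = min(int(math.ceil(cy + r_out)) + 2, h)
    if x0 >= x1 or y0 >= y1:
        return False
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - cx, yy - cy)
    cov = np.clip((radius + edge_width / 2.0 - dist) / edge_width, 0.0, 1.0)
    img[y0:y1, x0:x1] = img[y0:y1, x0:x1] * (1.0 - cov) + value * cov
    in_bounds = (cx - r_out >= 0 and cx + r_out < w and
                 cy - r_out >= 0 and cy + r_out < h)
    return in_bounds


def render_eye_frame(truth: EyeStateTruth, cfg: OpticalConfig,
                     rng: np.random.Generator | int | None = None
                     ) -> tuple[np.ndarray, dict]:
    """Render one 8-bit eye-camera frame from a ground-truth eye state.

    Returns ``(image, meta)`` where ``meta`` flags whether pupil and CR were
    rendered fully inside the frame.  Noise has two seeded components: i.i.d.
    per-pixel Gaussian noise of SD ``noise_sd`` and a random per-frame linear
    shading gradient of SD ``gradient_sd`` grey levels per pixel, which is
    what gives the detected pupil centroid its realistic 0.2-0.5 px
    frame-to-frame dispersion.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    m = cfg.magnification
    h, w = cfg.frame_shape
    cx0 = (w - 1) / 2.0
    cy0 = (h - 1) / 2.0

    # anatomical pupil axis translates with gaze; CR leads it per Hirschberg
    anat_x = cx0 + cfg.pupil_motion_mm_per_deg * truth.gaze_h * m
    anat_y = cy0 - cfg.pupil_motion_mm_per_deg * truth.gaze_v * m
    pupil_x = anat_x + truth.pupil_center_offset_mm * m
    pupil_y = anat_y
    cr_x = anat_x + cr_displacement(truth.gaze_h, cfg) * m
    cr_y = anat_y - cr_displacement(truth.gaze_v, cfg) * m

    img = np.full((h, w), cfg.background_grey, dtype=np.float64)
    pupil_r = truth.pupil_diameter_mm * m / 2.0
    pupil_ok = _paint_disc(img, pupil_x, pupil_y, pupil_r,
                           cfg.pupil_grey, cfg.edge_width_px)
    if cfg.cr_diameter_mm > 0:
        cr_r = cfg.cr_diameter_mm * m / 2.0
        cr_ok = _paint_disc(img, cr_x, cr_y, cr_r, cfg.cr_grey, cfg.edge_width_px)
    else:                               # pupil-only render (test/inspection aid)
        cr_ok = False

    # eyelid: occludes (1 - aperture) of the frame from the top
    lid_rows = int(round((1.0 - truth.eyelid_aperture) * h))
    if lid_rows > 0:
        img[:lid_rows, :] = cfg.background_grey

    if cfg.noise_sd > 0:
        img += rng.normal(0.0, cfg.noise_sd, size=img.shape)
    if cfg.gradient_sd > 0:
        # per-frame shading gradient, Gaussian-windowed around the eye so the
        # frame periphery stays clean; this is what moves the detected pupil
        # centroid by the realistic 0.2-0.5 px from frame to frame
        # amplitudes truncated at 2.5 sigma: extreme shading draws would push
        # pupil-interior pixels across the detection threshold, which real
        # illumination drift does not do
        lim = 2.5 * cfg.gradient_sd
        gx, gy = np.clip(rng.normal(0.0, cfg.gradient_sd, size=2), -lim, lim)
        ramp_x, ramp_y = _gradient_ramps(cfg)
        img += gx * ramp_x + gy * ramp_y

    meta = {
        "pupil_in_bounds": bool(pupil_ok),
        "cr_in_bounds": bool(cr_ok),
        "pupil_center_px": (pupil_x, pupil_y),
        "cr_center_px": (cr_x, cr_y),
    }
    return np.clip(img, 0, 255).astype(np.uint8), meta


# ---------------------------------------------------------------------------
# protocol simulation
# ---------------------------------------------------------------------------

def target_gaze(segment: Segment, eye: str, cfg: OpticalConfig) -> tuple[float, float]:
    """Per-eye gaze angles (deg) for a segment's fixation target.

    Screen targets are converted via each eye's horizontal offset from the
    screen centre; midline depth targets produce symmetric convergence.
    """
    eye_x = -cfg.ipd_mm / 2.0 if eye == "left" else cfg.ipd_mm / 2.0
    if segment.target_distance_mm is not None:
        if segment.target_distance_mm <= 0:
            raise ValueError("target_distance_mm must be positive")
        gaze_h = math.degrees(math.atan2(-eye_x, segment.target_distance_mm))
        gaze_v = 0.0
    else:
        tx_mm = segment.target_x_px * cfg.screen_pixel_pitch_mm
        ty_mm = segment.target_y_px * cfg.screen_pixel_pitch_mm
        gaze_h = math.degrees(math.atan2(tx_mm - eye_x, cfg.screen_distance_mm))
        gaze_v = math.degrees(math.atan2(-ty_mm, cfg.screen_distance_mm))
    return gaze_h, gaze_v


def cyclopean_target_deg(segment: Segment, cfg: OpticalConfig) -> tuple[float, float]:
    """Screen target angles as seen from the cyclopean (midpoint) eye.

    These are the angles a calibration references: both eyes are assigned the
    same screen-referenced target, the per-eye convergence being absorbed by
    the calibration offset.
    """
    tx_mm = segment.target_x_px * cfg.screen_pixel_pitch_mm
    ty_mm = segment.target_y_px * cfg.screen_pixel_pitch_mm
    return (math.degrees(math.atan2(tx_mm, cfg.screen_distance_mm)),
            math.degrees(math.atan2(-ty_mm, cfg.screen_distance_mm)))


def _eyelid_profile(n_frames: int, blink_onsets: Sequence[int],
                    cfg: OpticalConfig) -> np.ndarray:
    """Eyelid aperture trace for a stream: 1.0 except during blinks, where the
    lid descends linearly over ``blink_down_frames`` and re-opens over
    ``blink_up_frames``."""
    ap = np.ones(n_frames)
    down, up = cfg.blink_down_frames, cfg.blink_up_frames
    for onset in blink_onsets:
        for i in range(down):
            j = onset + i
            if 0 <= j < n_frames:
                ap[j] = min(ap[j], 1.0 - (i + 1) / down)
        for i in range(up):
            j = onset + down + i
            if 0 <= j < n_frames:
                ap[j] = min(ap[j], (i + 1) / up)
    return ap


class Simulation:
    """Result of :func:`simulate_protocol`.

    Holds the per-frame truth log (one row per frame per eye) and regenerates
    deterministic frame streams on demand, so arbitrarily long sessions never
    need to be held in memory.
    """

    def __init__(self, protocol: Protocol, cfg: OpticalConfig, seed: int,
                 truth: pd.DataFrame):
        self.protocol = protocol
        self.cfg = cfg
        self.seed = seed
        self.truth = truth
        self.n_frames = protocol.n_frames

    def truth_for(self, eye: str) -> pd.DataFrame:
        return self.truth[self.truth["eye"] == eye].reset_index(drop=True)

    def frames(self, eye: str) -> Iterator["Frame"]:
        """Deterministic frame stream for one camera."""
        from .detect import Frame  # local import to avoid a cycle

        eye_idx = EYES.index(eye)
        sub = self.truth_for(eye)
        for row in sub.itertuples(index=False):
            truth = EyeStateTruth(
                frame_index=int(row.frame_index),
                eye=eye,
                gaze_h=row.gaze_h_deg,
                gaze_v=row.gaze_v_deg,
                pupil_diameter_mm=row.pupil_mm,
                pupil_center_offset_mm=row.pupil_offset_mm,
                eyelid_aperture=row.eyelid_aperture,
                blink=bool(row.blink),
            )
            rng = np.random.default_rng(
                np.random.SeedSequence([self.seed, eye_idx, int(row.frame_index)]))
            img, _ = render_eye_frame(truth, self.cfg, rng)
            yield Frame(image=img, camera_id=eye, frame_index=int(row.frame_index),
                        time_s=float(row.time_s))

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write one multi-page TIFF per camera plus the truth CSV."""
        from .io_cli.frames import write_frames

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for eye in EYES:
            p = outdir / f"{eye}.tif"
            write_frames(self.frames(eye), p)
            paths[eye] = p
        truth_path = outdir / "truth.csv"
        self.truth[TRUTH_COLUMNS].assign(
            blink=self.truth["blink"].astype(int)
        ).to_csv(truth_path, index=False, float_format="%.6f")
        paths["truth"] = truth_path
        return paths


def simulate_protocol(protocol: Protocol, cfg: OpticalConfig | None = None,
                      seed: int = 0) -> Simulation:
    """Run a stimulus protocol through the model eyes.

    Builds the complete per-frame truth log: target-driven gaze with
    minimum-jerk saccadic transitions, first-order pupil light responses to
    the segment screen grey, eyelid blink sweeps and the (optional)
    pupil-decentration artifact.  Frames are rendered lazily by the returned
    :class:`Simulation`; identical ``(protocol, cfg, seed)`` triples produce
    bit-identical frames and truth logs.
    """
    cfg = cfg or OpticalConfig()
    n = protocol.n_frames
    fs = cfg.frame_rate
    dt = 1.0 / fs

    # per-segment per-eye target gaze, with addressable-field validation
    seg_targets = {eye: [] for eye in EYES}
    for k, seg in enumerate(protocol.segments):
        for eye in EYES:
            gh, gv = target_gaze(seg, eye, cfg)
            if abs(gh) > cfg.max_gaze_deg or abs(gv) > cfg.max_gaze_deg:
                name = seg.label or f"segment {k}"
                raise ValueError(
                    f"target of {name} outside addressable field "
                    f"(|gaze| > {cfg.max_gaze_deg} deg)")
            seg_targets[eye].append((gh, gv))

    # frame -> segment mapping and segment start frames
    seg_of_frame = np.empty(n, dtype=int)
    seg_start = np.empty(len(protocol.segments), dtype=int)
    i = 0
    for k, seg in enumerate(protocol.segments):
        seg_start[k] = i
        seg_of_frame[i:i + seg.duration_frames] = k
        i += seg.duration_frames

    # gaze trajectories with minimum-jerk transitions at segment boundaries
    gaze = {eye: np.empty((n, 2)) for eye in EYES}
    for eye in EYES:
        targets = seg_targets[eye]
        prev = np.array(targets[0])
        for k, seg in enumerate(protocol.segments):
            s0 = seg_start[k]
            cur = np.array(targets[k])
            dur = seg.duration_frames
            nsac = min(cfg.saccade_frames, dur) if k > 0 else 0
            for j in range(dur):
                if j < nsac:
                    frac = minimum_jerk((j + 1) / nsac)
                    gaze[eye][s0 + j] = prev + (cur - prev) * frac
                else:
                    gaze[eye][s0 + j] = cur
            prev = cur

    # pupil kinetics: first-order relaxation toward a screen-grey-driven
    # target diameter, with the stimulus acting after a fixed latency
    latency_frames = int(round(cfg.pupil_latency_s * fs))
    alpha = 1.0 - math.exp(-dt / cfg.pupil_tau_s)
    seg_grey = np.array([s.screen_grey for s in protocol.segments])
    target_d = np.where(seg_grey[seg_of_frame] >= cfg.bright_screen_grey,
                        cfg.pupil_constricted_mm, cfg.pupil_baseline_mm)
    pupil = np.empty(n)
    d = cfg.pupil_baseline_mm
    for i in range(n):
        tgt = target_d[max(i - latency_frames, 0)] if i >= latency_frames \
            else cfg.pupil_baseline_mm
        d += alpha * (tgt - d)
        pupil[i] = d

    # eyelid / blink profile (same for both eyes)
    blink_onsets = [int(seg_start[k] + b)
                    for k, seg in enumerate(protocol.segments) for b in seg.blinks]
    aperture = _eyelid_profile(n, blink_onsets, cfg)
    blink = aperture < cfg.blink_aperture_threshold

    # pupil-decentration artifact
    offset = cfg.artifact_coefficient * (pupil - cfg.artifact_reference_mm)

    frames_idx = np.arange(n)
    time_s = frames_idx * dt
    segs = [protocol.segments[k] for k in seg_of_frame]
    ttl = np.zeros(n, dtype=int)
    ttl[seg_start] = 1

    rows = []
    for eye in EYES:
        eye_offset = offset if eye in cfg.artifact_eyes else np.zeros(n)
        rows.append(pd.DataFrame({
            "frame_index": frames_idx,
            "time_s": time_s,
            "eye": eye,
            "gaze_h_deg": gaze[eye][:, 0],
            "gaze_v_deg": gaze[eye][:, 1],
            "pupil_mm": pupil,
            "pupil_offset_mm": eye_offset,
            "eyelid_aperture": aperture,
            "blink": blink,
            "segment": seg_of_frame,
            "segment_label": [s.label for s in segs],
            "target_x_px": [s.target_x_px for s in segs],
            "target_y_px": [s.target_y_px for s in segs],
            "ttl": ttl,
        }))
    truth = pd.concat(rows, ignore_index=True)
    verg = (truth.loc[truth["eye"] == "left", "gaze_h_deg"].to_numpy()
            - truth.loc[truth["eye"] == "right", "gaze_h_deg"].to_numpy())
    truth["vergence_deg"] = np.tile(verg, 2)
    return Simulation(protocol, cfg, seed, truth)
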