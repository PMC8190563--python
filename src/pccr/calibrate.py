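"""Automated per-eye four-point calibration of PC-CR vectors to gaze angles.

Each eye is calibrated independently but on a shared target timeline: a
fixation point is accepted once the running standard deviation of eye
position (converted to degrees through the nominal Hirschberg/magnification
factor, about 18.1 arcmin per pixel) drops below 0.5 degrees, after which
the next 100 PC-CR samples are averaged and stored.  A least-squares affine
map (six parameters per eye) then converts any PC-CR vector to
screen-referenced gaze by linear extrapolation over the whole plane.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .simulate import OpticalConfig, vergence_from_distance

__all__ = [
    "CalibrationPoint",
    "EyeCalibration",
    "CalibrationModel",
    "fixation_trigger",
    "acquire_point",
    "fit_calibration",
    "map_gaze",
    "compute_vergence",
    "CalibrationTimeout",
]

TRIGGER_WINDOW = 25
SAMPLES_PER_POINT = 100


class CalibrationTimeout(RuntimeError):
    """Raised when a fixation point never reaches stable fixation."""


@dataclass
class CalibrationPoint:
    """One stored calibration target: its gaze position (deg) and the mean
    PC-CR vector (px) averaged over the stored samples."""

    target_deg: tuple[float, float]
    mean_pcr: tuple[float, float]
    n_samples: int


@dataclass
class EyeCalibration:
    """Affine map gaze = gain @ pcr + offset for one eye."""

    gain: np.ndarray                     # (2, 2), deg per px
    offset: np.ndarray                   # (2,), deg
    targets: np.ndarray                  # (n, 2) calibration targets, deg
    mean_pcrs: np.ndarray                # (n, 2) stored mean PC-CR vectors, px
    residuals_deg: np.ndarray            # (n,) Euclidean residual per target

    @property
    def max_residual_deg(self) -> float:
        return float(np.max(self.residuals_deg))

    def to_dict(self) -> dict:
        return {
            "gain": self.gain.tolist(),
            "offset": self.offset.tolist(),
            "targets": self.targets.tolist(),
            "mean_pcrs": self.mean_pcrs.tolist(),
            "residuals_deg": self.residuals_deg.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EyeCalibration":
        return cls(*(np.asarray(d[k], dtype=float) for k in
                     ("gain", "offset", "targets", "mean_pcrs", "residuals_deg")))


@dataclass
class CalibrationModel:
    """Binocular calibration: independent affine maps for both eyes."""

    eyes: dict[str, EyeCalibration]
    screen_distance_mm: float = 540.0

    def map_gaze(self, eye: str, pcr) -> np.ndarray:
        return map_gaze(self.eyes[eye], pcr)

    def save(self, path: str | Path) -> None:
        payload = {
            "screen_distance_mm": self.screen_distance_mm,
            "eyes": {eye: cal.to_dict() for eye, cal in self.eyes.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            eyes={eye: EyeCalibration.from_dict(d)
                  for eye, d in payload["eyes"].items()},
            screen_distance_mm=payload["screen_distance_mm"],
        )


def fixation_trigger(pcr_window, cfg: OpticalConfig | None = None, *,
                     sd_threshold_deg: float = 0.5,
                     window: int = TRIGGER_WINDOW) -> bool:
    """True when the last ``window`` PC-CR samples are stable enough to store.

    The per-component sample SD is converted to degrees through the nominal
    fixed factor ``hirschberg_ratio / magnification`` (~18.1 arcmin/px at
    default optics — no calibration exists yet at trigger time) and both
    components must stay below ``sd_threshold_deg``.  Windows containing
    invalid (non-finite) samples are simply not stable.
    """
    cfg = cfg or OpticalConfig()
    arr = np.asarray(pcr_window, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] < window:
        raise ValueError(f"need at least {window} samples, got {arr.shape[0]}")
    arr = arr[-window:]
    if not np.all(np.isfinite(arr)):
        return False
    sd_deg = arr.std(axis=0, ddof=1) * cfg.deg_per_px
    return bool(np.all(sd_deg < sd_threshold_deg))


def acquire_point(samples: Iterable, target_deg: Sequence[float],
                  cfg: OpticalConfig | None = None, *,
                  n_average: int = SAMPLES_PER_POINT,
                  window: int = TRIGGER_WINDOW,
                  timeout: int = 3000,
                  sd_threshold_deg: float = 0.5) -> CalibrationPoint:
    """Wait for stable fixation, then average the next ``n_average`` PC-CR
    vectors.

    ``samples`` yields (dx, dy) pairs or None for invalid frames.  Raises
    :class:`CalibrationTimeout` if the trigger is not reached (and the
    average completed) within ``timeout`` samples.
    """
    cfg = cfg or OpticalConfig()
    buf: list = []
    collected: list[np.ndarray] = []
    triggered = False
    for i, s in enumerate(samples):
        if i >= timeout:
            break
        v = None if s is None else np.asarray(s, dtype=float)
        if v is not None and not np.all(np.isfinite(v)):
            v = None
        if not triggered:
            buf.append([np.nan, np.nan] if v is None else v)
            if len(buf) >= window and fixation_trigger(
                    buf[-window:], cfg, sd_threshold_deg=sd_threshold_deg,
                    window=window):
                triggered = True
            continue
        if v is not None:
            collected.append(v)
            if len(collected) == n_average:
                mean = np.mean(collected, axis=0)
                return CalibrationPoint(
                    target_deg=(float(target_deg[0]), float(target_deg[1])),
                    mean_pcr=(float(mean[0]), float(mean[1])),
                    n_samples=n_average,
                )
    raise CalibrationTimeout(
        f"fixation never stabilised for target {tuple(target_deg)} "
        f"within {timeout} samples")


def fit_calibration(points: Sequence[CalibrationPoint]) -> EyeCalibration:
    """Least-squares affine fit of target gaze on mean PC-CR vectors.

    Four points over-determine the six-parameter map; the fit is exact when
    the underlying PC-CR-to-gaze relation is truly affine.  Fewer than four
    points, or collinear/duplicate targets, raise ``ValueError``.
    """
    if len(points) < 4:
        raise ValueError(f"need 4 calibration points, got {len(points)}")
    pcr = np.asarray([p.mean_pcr for p in points], dtype=float)
    tgt = np.asarray([p.target_deg for p in points], dtype=float)
    design = np.column_stack([pcr, np.ones(len(points))])
    if np.linalg.matrix_rank(design, tol=1e-8 * max(1.0, np.abs(design).max())) < 3:
        raise ValueError("calibration targets/PC-CR vectors are degenerate "
                         "(collinear or duplicated)")
    coef, *_ = np.linalg.lstsq(design, tgt, rcond=None)
    gain = coef[:2].T                    # (2, 2)
    offset = coef[2]
    fitted = pcr @ gain.T + offset
    residuals = np.linalg.norm(fitted - tgt, axis=1)
    return EyeCalibration(gain=gain, offset=offset, targets=tgt,
                          mean_pcrs=pcr, residuals_deg=residuals)


def map_gaze(model: EyeCalibration, pcr) -> np.ndarray:
    """Apply the affine calibration to PC-CR vector(s) -> gaze in degrees.

    Defined on the whole plane (linear extrapolation outside the calibration
    rectangle).  Accepts a single (dx, dy) pair or an (n, 2) array.
    """
    arr = np.asarray(pcr, dtype=float)
    single = arr.ndim == 1
    out = np.atleast_2d(arr) @ model.gain.T + model.offset
    return out[0] if single else out


def compute_vergence(left_gaze_h, right_gaze_h,
                     cfg: OpticalConfig | None = None, *,
                     units: str = "arcmin"):
    """Absolute binocular vergence from calibrated horizontal gaze.

    The relative difference (left - right, positive = convergent) is
    anchored by the geometric vergence at the calibration screen distance,
    so fixation on the screen reads the true binocular angle.  NaN inputs
    (blinks/missing eye) propagate to NaN.
    """
    cfg = cfg or OpticalConfig()
    anchor = vergence_from_distance(cfg.screen_distance_mm, cfg)
    verg_deg = np.asarray(left_gaze_h, dtype=float) - np.asarray(right_gaze_h, dtype=float) + anchor
    if units == "deg":
        out = verg_deg
    elif units == "arcmin":
        out = verg_deg * 60.0
    else:
        raise ValueError("units must be 'arcmin' or 'deg'")
    return float(out) if out.ndim == 0 else out
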