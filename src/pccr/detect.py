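"""Per-frame pupil and first-Purkinje-image (corneal reflection) detection.

The pupil is located by simple thresholding: every pixel darker than an
adjustable threshold (default 0.6 x the mean ROI brightness) is stored, the
centre of mass taken as the pupil centre and the pixel count as the pupil
area; the pupil radius follows ``r = sqrt(area / pi)``.  The same procedure
with an inverted, fixed threshold (250, independent of image brightness)
yields the corneal-reflection centre, whose pixel count doubles as a focus
score.  Gaze is carried by the PC-CR vector, the difference between the two
sub-pixel centres, which is invariant to whole-image translation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Frame",
    "Roi",
    "DetectionConfig",
    "DetectionResult",
    "pupil_radius_from_area",
    "detect_pupil",
    "detect_purkinje",
    "pcr_vector",
    "PupilTracker",
    "run_detection",
]

_FOUR_CONNECTED = ndimage.generate_binary_structure(2, 1)

DETECTION_COLUMNS = [
    "frame_index", "time_s", "camera_id",
    "pupil_x", "pupil_y", "pupil_area", "pupil_mm",
    "cr_x", "cr_y", "cr_area", "valid",
]


@dataclass
class Frame:
    """One 8-bit monochrome camera frame."""

    image: np.ndarray
    camera_id: str = "left"
    frame_index: int = 0
    time_s: float = 0.0

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 2:
            raise ValueError("frame image must be 2-D")
        if self.image.dtype != np.uint8:
            if self.image.min() < 0 or self.image.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.image = self.image.astype(np.uint8)
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")


@dataclass(frozen=True)
class Roi:
    """Half-open pixel rectangle [x0, x1) x [y0, y1)."""

    x0: int
    y0: int
    x1: int
    y1: int

    def clipped(self, width: int, height: int) -> "Roi":
        return Roi(max(self.x0, 0), max(self.y0, 0),
                   min(self.x1, width), min(self.y1, height))

    def validate(self, width: int, height: int) -> None:
        if not (0 <= self.x0 < self.x1 <= width and 0 <= self.y0 < self.y1 <= height):
            raise ValueError(f"ROI {self} outside {width}x{height} frame")

    @classmethod
    def full(cls, image: np.ndarray) -> "Roi":
        h, w = image.shape
        return cls(0, 0, w, h)


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable detection parameters.

    Minimum areas are specified at the nominal 39.7 px/mm magnification and
    scaled by ``(magnification / 39.7)**2`` by :class:`PupilTracker`.
    """

    threshold_factor: float = 0.6        # pupil threshold as fraction of ROI mean
    cr_threshold: float = 250.0          # fixed CR intensity threshold
    min_pupil_area_px: float = 500.0
    min_cr_area_px: float = 20.0
    largest_component: bool = True       # keep only the largest 4-connected blob
    fill_holes: bool = True              # include the CR "hole" in the pupil blob
    cr_window_dilation: float = 0.5      # CR search box = pupil bbox dilated by this
    roi_scale: float = 3.0               # tracking ROI side = roi_scale * pupil diameter
    magnification: float = 39.7


@dataclass
class DetectionResult:
    """Sub-pixel detection output for one frame."""

    pupil_center: Optional[tuple[float, float]] = None
    pupil_area: Optional[int] = None
    pupil_radius_px: Optional[float] = None
    pupil_diameter_mm: Optional[float] = None
    cr_center: Optional[tuple[float, float]] = None
    cr_area: Optional[int] = None
    valid: bool = False
    threshold_used: Optional[float] = None

    @property
    def pcr_vector(self) -> Optional[np.ndarray]:
        """Pupil centre minus CR centre (pixels); None when invalid."""
        return pcr_vector(self.pupil_center, self.cr_center)


def pupil_radius_from_area(area: float) -> float:
    """Radius of a disc with the given pixel count: ``sqrt(area / pi)``."""
    if area < 0:
        raise ValueError("area must be non-negative")
    return math.sqrt(area / math.pi)


def _masked_blob(mask: np.ndarray, largest_component: bool,
                 fill_holes: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates (rows, cols) of the blob, optionally restricted to
    the largest 4-connected component and optionally hole-filled.

    Hole filling matters for the pupil: the bright corneal reflection sits
    inside the dark pupil and would otherwise carve an off-centre hole that
    biases the centre of mass with gaze.
    """
    if largest_component:
        labels, n = ndimage.label(mask, structure=_FOUR_CONNECTED)
        if n == 0:
            return np.empty(0, int), np.empty(0, int)
        if n > 1:
            counts = np.bincount(labels.ravel())[1:]
            mask = labels == (int(np.argmax(counts)) + 1)
    if fill_holes and mask.any():
        mask = ndimage.binary_fill_holes(mask)
    return np.nonzero(mask)


def detect_pupil(frame: Frame | np.ndarray, roi: Roi | None = None,
                 threshold_factor: float = 0.6, *,
                 largest_component: bool = True,
                 fill_holes: bool = True,
                 magnification: float = 39.7) -> DetectionResult:
    """Locate the pupil inside ``roi`` by dark-pixel thresholding.

    The threshold is ``threshold_factor`` times the mean ROI intensity;
    pixels strictly below it form the pupil blob whose intensity-agnostic
    centroid, count and equivalent-disc radius are reported.  With zero
    sub-threshold pixels the result is returned with ``valid=False``.
    """
    image = frame.image if isinstance(frame, Frame) else np.asarray(frame)
    if not (0.0 < threshold_factor < 1.0):
        raise ValueError("threshold_factor must be in (0, 1)")
    roi = roi or Roi.full(image)
    roi.validate(image.shape[1], image.shape[0])
    sub = image[roi.y0:roi.y1, roi.x0:roi.x1].astype(np.float64)
    threshold = threshold_factor * float(sub.mean())
    rows, cols = _masked_blob(sub < threshold, largest_component, fill_holes)
    if rows.size == 0:
        return DetectionResult(valid=False, threshold_used=threshold)
    area = int(rows.size)
    radius = pupil_radius_from_area(area)
    return DetectionResult(
        pupil_center=(float(cols.mean()) + roi.x0, float(rows.mean()) + roi.y0),
        pupil_area=area,
        pupil_radius_px=radius,
        pupil_diameter_mm=2.0 * radius / magnification,
        valid=True,
        threshold_used=threshold,
    )


def detect_purkinje(frame: Frame | np.ndarray, roi: Roi | None = None,
                    threshold: float = 250.0, *,
                    largest_component: bool = True) -> DetectionResult:
    """Locate the corneal reflection: pixels at or above a fixed intensity
    threshold (independent of image brightness) inside ``roi``."""
    image = frame.image if isinstance(frame, Frame) else np.asarray(frame)
    roi = roi or Roi.full(image)
    roi.validate(image.shape[1], image.shape[0])
    sub = image[roi.y0:roi.y1, roi.x0:roi.x1]
    rows, cols = _masked_blob(sub >= threshold, largest_component)
    if rows.size == 0:
        return DetectionResult(valid=False, threshold_used=float(threshold))
    return DetectionResult(
        cr_center=(float(cols.mean()) + roi.x0, float(rows.mean()) + roi.y0),
        cr_area=int(rows.size),
        valid=True,
        threshold_used=float(threshold),
    )


def pcr_vector(pupil_center, cr_center) -> Optional[np.ndarray]:
    """PC-CR vector: pupil centre minus CR centre, in pixels.

    Translation-invariant by construction; propagates None for invalid
    detections.
    """
    if pupil_center is None or cr_center is None:
        return None
    return np.asarray(pupil_center, dtype=float) - np.asarray(cr_center, dtype=float)


class PupilTracker:
    """Stateful per-frame detector with ROI tracking.

    The ROI defaults to the full frame, then follows the pupil (a square of
    side ``roi_scale`` x pupil diameter centred on the last pupil centre) and
    is re-seeded from the full frame after an invalid frame.  The CR search
    is confined to the pupil bounding box dilated by ``cr_window_dilation``,
    so stray specular highlights elsewhere cannot capture the centroid.
    """

    def __init__(self, cfg: DetectionConfig | None = None):
        self.cfg = cfg or DetectionConfig()
        scale = (self.cfg.magnification / 39.7) ** 2
        self.min_pupil_area = self.cfg.min_pupil_area_px * scale
        self.min_cr_area = self.cfg.min_cr_area_px * scale
        self._roi: Roi | None = None

    def reset(self) -> None:
        self._roi = None

    def detect_frame(self, frame: Frame) -> DetectionResult:
        image = frame.image
        h, w = image.shape
        roi = (self._roi or Roi.full(image)).clipped(w, h)
        pupil = detect_pupil(frame, roi, self.cfg.threshold_factor,
                             largest_component=self.cfg.largest_component,
                             fill_holes=self.cfg.fill_holes,
                             magnification=self.cfg.magnification)
        if (not pupil.valid or pupil.pupil_area < self.min_pupil_area) \
                and self._roi is not None:
            # lost inside the tracking ROI: retry on the full frame
            pupil = detect_pupil(frame, Roi.full(image), self.cfg.threshold_factor,
                                 largest_component=self.cfg.largest_component,
                                 fill_holes=self.cfg.fill_holes,
                                 magnification=self.cfg.magnification)
        if not pupil.valid or pupil.pupil_area < self.min_pupil_area:
            self._roi = None
            return DetectionResult(valid=False,
                                   threshold_used=pupil.threshold_used)

        px, py = pupil.pupil_center
        r = pupil.pupil_radius_px
        half = r * (1.0 + self.cfg.cr_window_dilation)
        cr_roi = Roi(int(px - half), int(py - half),
                     int(math.ceil(px + half)) + 1,
                     int(math.ceil(py + half)) + 1).clipped(w, h)
        cr = detect_purkinje(frame, cr_roi, self.cfg.cr_threshold,
                             largest_component=self.cfg.largest_component)
        valid = cr.valid and cr.cr_area >= self.min_cr_area

        side = self.cfg.roi_scale * 2.0 * r
        self._roi = Roi(int(px - side / 2), int(py - side / 2),
                        int(math.ceil(px + side / 2)),
                        int(math.ceil(py + side / 2))).clipped(w, h)
        return DetectionResult(
            pupil_center=pupil.pupil_center,
            pupil_area=pupil.pupil_area,
            pupil_radius_px=pupil.pupil_radius_px,
            pupil_diameter_mm=pupil.pupil_diameter_mm,
            cr_center=cr.cr_center,
            cr_area=cr.cr_area,
            valid=bool(valid),
            threshold_used=pupil.threshold_used,
        )


def run_detection(frames: Iterable[Frame],
                  cfg: DetectionConfig | None = None) -> pd.DataFrame:
    """Detect pupil and CR over a frame stream; one output row per frame."""
    tracker = PupilTracker(cfg)
    rows = []
    for frame in frames:
        det = tracker.detect_frame(frame)
        rows.append({
            "frame_index": frame.frame_index,
            "time_s": frame.time_s,
            "camera_id": frame.camera_id,
            "pupil_x": det.pupil_center[0] if det.pupil_center else np.nan,
            "pupil_y": det.pupil_center[1] if det.pupil_center else np.nan,
            "pupil_area": det.pupil_area if det.pupil_area is not None else 0,
            "pupil_mm": det.pupil_diameter_mm if det.pupil_diameter_mm else np.nan,
            "cr_x": det.cr_center[0] if det.cr_center else np.nan,
            "cr_y": det.cr_center[1] if det.cr_center else np.nan,
            "cr_area": det.cr_area if det.cr_area is not None else 0,
            "valid": int(det.valid),
        })
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)
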