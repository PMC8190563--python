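"""Real-time-style quality analysis of the sample stream.

Three concerns live here: running noise statistics over the latest 25
samples (63 ms at 395 Hz — short enough not to be dominated by ocular
drift, so they reflect detection repeatability), blink detection from the
running SD of pupil size, and the pupil-decentration artifact assessment
and vergence correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .simulate import OpticalConfig

__all__ = [
    "RunningStats",
    "ArtifactRegression",
    "running_stats",
    "rolling_stats",
    "detect_blink",
    "assess_pupil_artifact",
    "correct_vergence",
]

WINDOW = 25
BLINK_SD_MM = 0.2
BLINK_PAD = 5


@dataclass
class RunningStats:
    """Noise statistics over the most recent window of samples.

    ``sd`` is the per-channel sample standard deviation; ``mad1`` the mean
    absolute successive difference of the horizontal (first) channel — a
    more conservative noise measure.  ``*_arcmin`` use the nominal
    pixel-to-angle conversion.
    """

    sd: np.ndarray
    mad1: float
    sd_arcmin: np.ndarray
    mad1_arcmin: float
    window: int = WINDOW


def running_stats(series, window: int = WINDOW,
                  cfg: OpticalConfig | None = None) -> RunningStats:
    """Noise statistics of the latest ``window`` samples of ``series``.

    ``series`` is (n,) or (n, k) in pixels with n >= window; statistics are
    computed over the trailing window only.
    """
    cfg = cfg or OpticalConfig()
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] < window:
        raise ValueError(f"need at least {window} samples, got {arr.shape[0]}")
    tail = arr[-window:]
    sd = tail.std(axis=0, ddof=1)
    mad1 = float(np.mean(np.abs(np.diff(tail[:, 0]))))
    k = cfg.arcmin_per_px
    return RunningStats(sd=sd, mad1=mad1, sd_arcmin=sd * k,
                        mad1_arcmin=mad1 * k, window=window)


def rolling_stats(series, window: int = WINDOW,
                  cfg: OpticalConfig | None = None) -> pd.DataFrame:
    """Per-sample running statistics (window ending at each sample).

    Returns a DataFrame with ``sd_<ch>`` per channel plus ``mad1``, in
    pixels, and the arcmin conversions.  The first ``window - 1`` rows are
    NaN (not enough history).
    """
    cfg = cfg or OpticalConfig()
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    df = pd.DataFrame(arr, columns=[f"ch{i}" for i in range(arr.shape[1])])
    out = pd.DataFrame(index=df.index)
    names = ["x", "y"] if arr.shape[1] == 2 else list(df.columns)
    for col, name in zip(df.columns, names):
        out[f"sd_{name}"] = df[col].rolling(window).std(ddof=1)
        out[f"sd_{name}_arcmin"] = out[f"sd_{name}"] * cfg.arcmin_per_px
    mad1 = df[df.columns[0]].diff().abs().rolling(window - 1).mean()
    out["mad1"] = mad1
    out["mad1_arcmin"] = mad1 * cfg.arcmin_per_px
    return out


def detect_blink(pupil_series_mm, window: int = WINDOW,
                 threshold_mm: float = BLINK_SD_MM,
                 pad: int = BLINK_PAD) -> np.ndarray:
    """Per-sample blink flags from the running SD of pupil size.

    A sample is flagged when the SD of pupil diameter over the latest
    ``window`` samples exceeds ``threshold_mm`` (pupil size cannot change
    that fast except when the lids sweep across it) or when the sample
    itself is invalid (NaN, pupil lost).  Flagged spans are extended by
    ``pad`` samples on each side as a recovery margin.
    """
    p = np.asarray(pupil_series_mm, dtype=float)
    invalid = ~np.isfinite(p)
    sd = pd.Series(p).rolling(window).std(ddof=1).to_numpy()
    with np.errstate(invalid="ignore"):
        flags = (sd > threshold_mm) | invalid
    if pad > 0 and flags.any():
        flags = ndimage.binary_dilation(flags, iterations=pad)
    return flags


@dataclass
class ArtifactRegression:
    """Linear regression of vergence on pupil diameter.

    A significant slope means the pupil centre moves with pupil size and
    vergence must be corrected; ``reference_pupil`` is the mean pupil size
    of the fitting window, around which the correction is centred.
    """

    slope: float                      # arcmin per mm
    intercept: float                  # arcmin
    slope_se: float
    p_value: float
    significant: bool
    reference_pupil: float            # mm
    n: int
    alpha: float = 0.05


def assess_pupil_artifact(pupil_mm_series, vergence_arcmin_series,
                          alpha: float = 0.05,
                          min_pairs: int = 30) -> ArtifactRegression:
    """OLS fit of vergence (arcmin) on pupil diameter (mm), with a two-sided
    t-test of slope = 0.

    Pairs containing NaN (blinks) are dropped; fewer than ``min_pairs``
    remaining pairs or zero pupil-size variance (the light step failed to
    elicit a response) raise ``ValueError``.
    """
    p = np.asarray(pupil_mm_series, dtype=float)
    v = np.asarray(vergence_arcmin_series, dtype=float)
    if p.shape != v.shape:
        raise ValueError("pupil and vergence series must have equal length")
    keep = np.isfinite(p) & np.isfinite(v)
    p, v = p[keep], v[keep]
    if p.size < min_pairs:
        raise ValueError(f"need at least {min_pairs} valid pairs, got {p.size}")
    if np.ptp(p) == 0:
        raise ValueError("pupil size has zero variance; no response elicited")
    fit = stats.linregress(p, v)
    return ArtifactRegression(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_se=float(fit.stderr),
        p_value=float(fit.pvalue),
        significant=bool(fit.pvalue < alpha),
        reference_pupil=float(p.mean()),
        n=int(p.size),
        alpha=alpha,
    )


def correct_vergence(vergence_arcmin, pupil_mm, reg: ArtifactRegression):
    """Remove the pupil-size-driven component from a vergence trace.

    When the regression slope is significant the correction
    ``v - slope * (pupil - reference_pupil)`` is applied; centring on the
    reference pupil preserves the mean vergence over the fitting window.
    With a non-significant slope the input is returned unchanged.
    """
    v = np.asarray(vergence_arcmin, dtype=float)
    if not reg.significant:
        out = v.copy()
    else:
        p = np.asarray(pupil_mm, dtype=float)
        out = v - reg.slope * (p - reg.reference_pupil)
    return float(out) if out.ndim == 0 else out
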