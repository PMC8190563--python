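"""The per-frame gaze recording file.

One CSV row per frame: computer time (seconds since session start), frame
number, pupil sizes of both eyes (mm), horizontal gaze of both eyes in
screen coordinates (pixels from screen centre), vergence in arcmin with and
without pupil-centration correction, target position, and a TTL column that
is 1 only on frames where a new target appears.  Rows flagged as blinks
carry zeros in all measured data columns; the explicit ``blink`` flag
column distinguishes zeroed rows from genuine zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RECORDING_COLUMNS",
    "DATA_COLUMNS",
    "GazeRecording",
    "write_recording",
    "read_recording",
]

RECORDING_COLUMNS = [
    "computer_time",
    "frame_number",
    "pupil_left_mm",
    "pupil_right_mm",
    "x_left_px",
    "x_right_px",
    "vergence_raw_arcmin",
    "vergence_corrected_arcmin",
    "target_x",
    "target_y",
    "ttl",
    "blink",
]

# measured columns zeroed on blink rows (stimulus columns and flags are kept)
DATA_COLUMNS = [
    "pupil_left_mm",
    "pupil_right_mm",
    "x_left_px",
    "x_right_px",
    "vergence_raw_arcmin",
    "vergence_corrected_arcmin",
]


@dataclass
class GazeRecording:
    """A validated per-frame binocular gaze recording."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"recording is missing columns: {missing}")
        self.frame = df = df[RECORDING_COLUMNS].reset_index(drop=True)
        fn = df["frame_number"].to_numpy()
        if len(fn) and np.any(np.diff(fn) <= 0):
            bad = int(np.argmax(np.diff(fn) <= 0)) + 1
            raise ValueError(
                f"frame_number must be strictly increasing (row {bad})")
        bad_ttl = ~df["ttl"].isin([0, 1])
        if bad_ttl.any():
            row = int(np.argmax(bad_ttl.to_numpy()))
            raise ValueError(f"ttl must be 0 or 1 (data row {row}, "
                             f"file line {row + 2})")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def blink_mask(self) -> np.ndarray:
        return self.frame["blink"].to_numpy().astype(bool)

    def data_with_nan(self) -> pd.DataFrame:
        """Copy of the table with blink-zeroed data columns set to NaN, the
        convenient form for downstream statistics."""
        df = self.frame.copy()
        df.loc[self.blink_mask, DATA_COLUMNS] = np.nan
        return df


def write_recording(samples: pd.DataFrame | GazeRecording,
                    path: str | Path) -> Path:
    """Write a recording CSV; blink rows are zeroed in all data columns.

    Floats use 6 significant digits; the written file round-trips through
    :func:`read_recording` up to that formatting.
    """
    rec = samples if isinstance(samples, GazeRecording) else GazeRecording(samples)
    df = rec.frame.copy()
    blink = rec.blink_mask
    df.loc[blink, DATA_COLUMNS] = 0.0
    df["frame_number"] = df["frame_number"].astype(int)
    df["ttl"] = df["ttl"].astype(int)
    df["blink"] = df["blink"].astype(int)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def read_recording(path: str | Path) -> GazeRecording:
    """Read and validate a recording CSV written by :func:`write_recording`.

    Malformed headers or rows raise ``ValueError`` naming the offending
    line; a header-only file yields an empty recording.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    if header.split(",") != RECORDING_COLUMNS:
        raise ValueError(
            f"{path}: line 1: unexpected header {header!r}; "
            f"expected {','.join(RECORDING_COLUMNS)}")
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message
        raise ValueError(f"{path}: malformed CSV: {exc}") from exc
    if df.empty:
        return GazeRecording(df.astype(float))
    for col in RECORDING_COLUMNS:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise ValueError(f"{path}: line {line}: non-numeric value "
                             f"in column {col!r}")
    return GazeRecording(df)
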