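"""Reading and writing of eye-camera frame streams.

Streams are stored as one multi-page 8-bit TIFF per camera; a directory of
single-frame PNG files (sorted lexically) is accepted on read.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import imageio.v3 as iio
import numpy as np
import tifffile

from ..detect import Frame

__all__ = ["write_frames", "read_frames"]


def write_frames(frames: Iterable[Frame], path: str | Path) -> Path:
    """Stream frames to a multi-page 8-bit grey TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with tifffile.TiffWriter(path) as tif:
        for frame in frames:
            tif.write(frame.image, photometric="minisblack", contiguous=False)
    return path


def read_frames(path: str | Path, camera_id: str = "left",
                frame_rate: float = 395.0) -> Iterator[Frame]:
    """Yield frames from a multi-page TIFF file or a PNG directory.

    Frame indices/timestamps are assigned sequentially at ``frame_rate``.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in {".png", ".tif", ".tiff"})
        if not files:
            raise FileNotFoundError(f"no image files in {path}")
        for i, f in enumerate(files):
            img = np.asarray(iio.imread(f))
            if img.ndim == 3:            # collapse accidental RGB
                img = img[..., 0]
            yield Frame(image=img.astype(np.uint8), camera_id=camera_id,
                        frame_index=i, time_s=i / frame_rate)
    else:
        with tifffile.TiffFile(path) as tif:
            for i, page in enumerate(tif.pages):
                yield Frame(image=page.asarray().astype(np.uint8),
                            camera_id=camera_id, frame_index=i,
                            time_s=i / frame_rate)
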