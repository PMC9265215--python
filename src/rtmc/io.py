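"""Movie and table I/O.

Movies are read and written as multi-page grayscale TIFF (8- or 16-bit
unsigned, or float for analysis output) via tifffile. Shift logs, shift
truth and ROI tables are plain CSV handled with pandas.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import tifffile

from .exceptions import InputError, UnsupportedFormatError
from .movie import Movie
from .registration import RegistrationResult
from .synth import ShiftTruth

__all__ = [
    "read_movie",
    "write_movie",
    "write_shift_log",
    "read_shift_log",
    "write_shift_truth",
    "read_shift_truth",
    "read_rois",
    "write_rois",
]

_TIFF_EXT = {".tif", ".tiff"}


def _check_tiff(path: str) -> None:
    ext = os.path.splitext(path)[1].lower()
    if ext not in _TIFF_EXT:
        raise UnsupportedFormatError(
            f"unsupported movie format '{ext}' for {path!r}: only multi-page "
            "TIFF (.tif/.tiff) is supported in this build"
        )


def read_movie(path: str, frame_rate: float = 20.0) -> Movie:
    """Read a grayscale multi-page TIFF as a Movie."""
    _check_tiff(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise InputError(f"{path!r}: expected a grayscale stack, got shape {data.shape}")
    return Movie(frames=data.astype(np.float64), frame_rate=frame_rate,
                 source_dtype=data.dtype, path=path)


def write_movie(movie: Movie, path: str, dtype: np.dtype | str | None = None) -> None:
    """Write a Movie as a multi-page TIFF.

    Integer target dtypes get the frames clipped to the dtype's valid range
    and rounded; float32/float64 preserve the real-valued data.
    """
    _check_tiff(path)
    dt = np.dtype(dtype) if dtype is not None else movie.source_dtype
    frames = movie.frames
    if np.issubdtype(dt, np.integer):
        info = np.iinfo(dt)
        frames = np.clip(np.rint(frames), info.min, info.max).astype(dt)
    else:
        frames = frames.astype(dt)
    tifffile.imwrite(path, frames, photometric="minisblack")


def write_shift_log(results: list[RegistrationResult], path: str) -> None:
    pd.DataFrame(
        {
            "frame": [r.frame_index for r in results],
            "dx": [r.dx for r in results],
            "dy": [r.dy for r in results],
            "peak_ncc": [r.peak_ncc for r in results],
            "fallback": [int(r.integer_fallback) for r in results],
        }
    ).to_csv(path, index=False)


def read_shift_log(path: str) -> pd.DataFrame:
    return pd.read_csv(path)


def write_shift_truth(truth: ShiftTruth, path: str) -> None:
    truth.to_frame().to_csv(path, index=False)


def read_shift_truth(path: str) -> ShiftTruth:
    df = pd.read_csv(path)
    dx = df["dx"].to_numpy(float)
    dy = df["dy"].to_numpy(float)
    bound = float(max(np.abs(dx).max(), np.abs(dy).max(), 0.0)) if len(df) else 0.0
    return ShiftTruth(dx=dx, dy=dy, max_offset=bound)


def read_rois(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"id", "row", "col", "radius"} - set(df.columns)
    if missing:
        raise InputError(f"ROI table {path!r} missing columns: {sorted(missing)}")
    return df


def write_rois(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False)
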