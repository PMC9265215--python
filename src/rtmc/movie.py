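"""In-memory movie container shared across modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InputError

__all__ = ["Movie"]


@dataclass
class Movie:
    """A grayscale movie as a (T, H, W) real-valued stack.

    ``source_dtype`` records the bit depth of the file the movie came from
    (or will be written as); frames are always held as float64 internally.
    """

    frames: np.ndarray
    frame_rate: float = 20.0
    source_dtype: np.dtype = np.dtype(np.uint8)
    path: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] == 0:
            raise InputError(
                f"movie frames must be a non-empty (T, H, W) stack, "
                f"got shape {self.frames.shape}"
            )
        self.source_dtype = np.dtype(self.source_dtype)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self):
        return iter(self.frames)
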