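"""Rolling-buffer template management.

The reference template lives in the filtered domain. It is initialized as the
high-pass-filtered temporal mean of a prerecorded movie, and refreshed during
streaming: corrected filtered frames accumulate in a buffer of capacity ``k``
(200 by default), and each time the buffer fills the template becomes the
average of its previous value and the buffer mean, after which the buffer is
emptied. Averaging with the running history keeps time-invariant landmarks
(vessels, bright fixed features) sharp in the template while tracking slow
changes in the field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DimensionError, InputError
from .filtering import FilterKernel, highpass_filter

__all__ = ["TemplateState", "init_template", "push_and_maybe_update"]


@dataclass
class TemplateState:
    template: np.ndarray
    k: int = 200
    buffer: list[np.ndarray] = field(default_factory=list)
    frames_seen: int = 0
    updates_done: int = 0

    @property
    def buffer_occupancy(self) -> int:
        return len(self.buffer)


def init_template(
    prerecorded: np.ndarray, kernel: FilterKernel | None, k: int = 200
) -> TemplateState:
    """Build the initial template from a prerecorded movie.

    The temporal mean image is computed first and then high-pass filtered
    (filtering is linear, so this equals averaging filtered frames up to
    boundary effects; filtering once is cheaper). With ``kernel=None`` the
    template is the raw mean image — the unfiltered baseline mode.

    Parameters
    ----------
    prerecorded : ndarray, shape (T, H, W)
        Motion-free (or representative) movie of the same geometry as the
        stream to be corrected.
    """
    movie = np.asarray(prerecorded, dtype=np.float64)
    if movie.ndim == 2:
        movie = movie[None]
    if movie.ndim != 3 or movie.shape[0] == 0:
        raise InputError("prerecorded movie must be a non-empty (T, H, W) stack")
    if k < 1:
        raise InputError(f"buffer capacity k must be >= 1, got {k}")
    mean_img = movie.mean(axis=0)
    template = mean_img if kernel is None else highpass_filter(mean_img, kernel)
    return TemplateState(template=template, k=int(k))


def push_and_maybe_update(
    state: TemplateState, corrected_filtered: np.ndarray
) -> TemplateState:
    """Append a corrected filtered frame; refresh the template at capacity.

    When the buffer reaches ``k`` frames the template is replaced by
    ``(template + mean(buffer)) / 2`` elementwise and the buffer is emptied.
    Mutates and returns ``state``.
    """
    frame = np.asarray(corrected_filtered, dtype=np.float64)
    if frame.shape != state.template.shape:
        raise DimensionError(
            f"frame {frame.shape} does not match template {state.template.shape}"
        )
    state.buffer.append(frame)
    state.frames_seen += 1
    if len(state.buffer) >= state.k:
        buffer_mean = np.mean(state.buffer, axis=0)
        state.template = 0.5 * (state.template + buffer_mean)
        state.buffer.clear()
        state.updates_done += 1
    return state
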