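"""Streaming motion-correction orchestration.

The per-frame loop mirrors the online algorithm: each incoming raw frame is
copied and high-pass filtered; the filtered copy is registered against the
current template; the negated estimated shift is applied (bilinear, zero
fill) to the raw frame for output and to the filtered frame, which is pushed
into the template manager's rolling buffer; the template refreshes whenever
the buffer fills. Only the current frame and previously seen data are ever
used, so the same code path serves file-at-a-time batch correction and a
live frame source.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np

from .config import RtmcConfig
from .exceptions import InputError, StreamError
from .filtering import FilterKernel, highpass_filter, make_highpass_kernel
from .io import read_movie, write_movie, write_shift_log
from .movie import Movie
from .registration import (
    RegistrationParams,
    RegistrationResult,
    apply_shift,
    register_frame,
)
from .template import TemplateState, init_template, push_and_maybe_update

__all__ = ["CorrectionRun", "correct_stream", "correct_movie_file"]


@dataclass
class CorrectionRun:
    """Log and outputs of one correction pass."""

    results: list[RegistrationResult] = field(default_factory=list)
    corrected: Movie | None = None
    config_snapshot: dict = field(default_factory=dict)
    frames_in: int = 0
    frames_out: int = 0
    output_path: str | None = None

    @property
    def shifts(self) -> np.ndarray:
        """Estimated per-frame (dx, dy), shape (n, 2)."""
        return np.array([[r.dx, r.dy] for r in self.results])


def correct_stream(
    source: Iterable[np.ndarray],
    state: TemplateState,
    kernel: FilterKernel | None,
    params: RegistrationParams | None = None,
    collect: bool = True,
    on_frame: Callable[[int, np.ndarray, RegistrationResult], None] | None = None,
) -> CorrectionRun:
    """Correct a stream of raw frames against an initialized template.

    Parameters
    ----------
    source : iterable of 2-D arrays
        Raw frames, all of the template's geometry.
    state : TemplateState
        Initialized template (see :func:`rtmc.template.init_template`);
        mutated in place as the stream advances.
    kernel : FilterKernel or None
        High-pass kernel; ``None`` runs the naive unfiltered-NCC baseline
        (the template must then also be unfiltered).
    collect : bool
        Keep corrected frames in memory as a Movie on the returned run.
    on_frame : callable, optional
        ``on_frame(index, corrected_raw, result)`` called per frame — the
        hook a live display or a streaming event detector plugs into.
    """
    params = params or RegistrationParams()
    run = CorrectionRun()
    corrected_frames: list[np.ndarray] = []
    shape = state.template.shape
    for idx, raw in enumerate(source):
        raw = np.asarray(raw, dtype=np.float64)
        if raw.shape != shape:
            raise StreamError(
                f"frame {idx}: geometry {raw.shape} does not match template {shape}"
            )
        filt = raw if kernel is None else highpass_filter(raw, kernel)
        res = register_frame(filt, state.template, params, frame_index=idx)
        fixed_raw = apply_shift(raw, -res.dx, -res.dy)
        fixed_filt = apply_shift(filt, -res.dx, -res.dy)
        push_and_maybe_update(state, fixed_filt)
        run.results.append(res)
        run.frames_in += 1
        run.frames_out += 1
        if collect:
            corrected_frames.append(fixed_raw)
        if on_frame is not None:
            on_frame(idx, fixed_raw, res)
    if run.frames_in == 0:
        raise InputError("empty frame stream")
    if collect:
        run.corrected = Movie(frames=np.stack(corrected_frames))
    return run


def correct_movie_file(
    in_path: str,
    out_path: str,
    config: RtmcConfig | None = None,
    template_path: str | None = None,
    shifts_path: str | None = None,
    report_path: str | None = None,
) -> CorrectionRun:
    """File-level wrapper: read a TIFF, correct it, write TIFF + CSV + report.

    The template comes from ``template_path`` (or ``config.prerecorded_path``)
    when given; otherwise it is initialized from the input movie's own
    temporal mean — adequate for batch correction, whereas a streaming run
    should always supply a prerecorded movie.
    """
    cfg = config or RtmcConfig()
    movie = read_movie(in_path, frame_rate=cfg.frame_rate)
    kernel = make_highpass_kernel(cfg.neuron_diameter, cfg.sigma, cfg.size_factor)
    pre_path = template_path or cfg.prerecorded_path
    if pre_path is not None:
        prerecorded = read_movie(pre_path).frames
    else:
        prerecorded = movie.frames.mean(axis=0)[None]
    state = init_template(prerecorded, kernel, k=cfg.k)
    params = RegistrationParams(
        max_shift=cfg.max_shift, min_overlap=cfg.min_overlap, eps=cfg.eps
    )
    run = correct_stream(movie, state, kernel, params, collect=True)
    run.config_snapshot = cfg.snapshot()
    run.corrected.frame_rate = movie.frame_rate
    run.corrected.source_dtype = movie.source_dtype
    out_dtype = np.float32 if cfg.float_out else movie.source_dtype
    write_movie(run.corrected, out_path, dtype=out_dtype)
    run.output_path = out_path
    if shifts_path is not None:
        write_shift_log(run.results, shifts_path)
    if report_path is not None:
        with open(report_path, "w") as fh:
            json.dump(
                {
                    "input": in_path,
                    "output": out_path,
                    "frames_in": run.frames_in,
                    "frames_out": run.frames_out,
                    "config": run.config_snapshot,
                },
                fh,
                indent=2,
            )
    return run
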