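"""ROI fluorescence trace extraction and calcium event detection.

A neuron's signal is read out as the mean intensity over a circular ROI
minus the mean over a surrounding annulus (the local background ring), which
cancels local background fluctuation and any frame-wide additive offset.
Calcium events are complete threshold excursions: the background-subtracted
trace must rise strictly above the threshold (mean + n·SD of a baseline
recording by default) and later return to or below it; the event is logged
at the return frame, so an excursion still open at the end of the recording
is not counted. The same excursion rule is available as a batch pass over a
finished trace and as a streaming detector that consumes corrected frames
one at a time and is exactly equivalent to the batch pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import GeometryError, InputError, ParameterError
from .movie import Movie

__all__ = [
    "ROI",
    "TraceSet",
    "extract_trace",
    "compute_threshold",
    "detect_events",
    "StreamingEventDetector",
    "trace_psnr",
    "trace_power_spectrum",
]


@dataclass(frozen=True)
class ROI:
    """A circular neuron region with an annular local-background ring.

    The annulus defaults to inner radius = radius + 2 px and outer radius =
    radius + 6 px, i.e. a ring slightly larger than the neuron.
    """

    id: int
    center: tuple[float, float]  # (row, col)
    radius: float
    inner_radius: float | None = None
    outer_radius: float | None = None

    def __post_init__(self) -> None:
        inner = self.radius + 2.0 if self.inner_radius is None else self.inner_radius
        outer = self.radius + 6.0 if self.outer_radius is None else self.outer_radius
        if not (0 < self.radius < inner < outer):
            raise ParameterError(
                f"ROI {self.id}: need 0 < radius < inner_radius < outer_radius, "
                f"got radius={self.radius}, inner={inner}, outer={outer}"
            )
        object.__setattr__(self, "inner_radius", float(inner))
        object.__setattr__(self, "outer_radius", float(outer))

    def masks(self, frame_shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Boolean (disk, annulus) pixel masks; errors if outside the frame."""
        h, w = frame_shape
        cy, cx = self.center
        if not (
            self.outer_radius <= cy <= h - 1 - self.outer_radius
            and self.outer_radius <= cx <= w - 1 - self.outer_radius
        ):
            raise GeometryError(
                f"ROI {self.id} at ({cy}, {cx}) with outer radius "
                f"{self.outer_radius} does not fit inside a {h}x{w} frame"
            )
        y = np.arange(h)[:, None]
        x = np.arange(w)[None, :]
        d2 = (y - cy) ** 2 + (x - cx) ** 2
        disk = d2 <= self.radius**2
        annulus = (d2 >= self.inner_radius**2) & (d2 <= self.outer_radius**2)
        if not disk.any() or not annulus.any():
            raise GeometryError(f"ROI {self.id}: empty disk or annulus mask")
        return disk, annulus


def rois_from_frame(df: pd.DataFrame, **annulus_kwargs) -> list[ROI]:
    """Build ROIs from a table with columns id, row, col, radius."""
    return [
        ROI(id=int(r.id), center=(float(r.row), float(r.col)),
            radius=float(r.radius), **annulus_kwargs)
        for r in df.itertuples(index=False)
    ]


@dataclass
class TraceSet:
    """Background-subtracted traces plus thresholds, events and PSNR per ROI."""

    traces: pd.DataFrame                 # frames x ROI ids
    frame_rate: float = 20.0
    thresholds: dict[int, float] = field(default_factory=dict)
    events: dict[int, list[int]] = field(default_factory=dict)
    psnr: dict[int, float] = field(default_factory=dict)


def _frame_trace_value(frame: np.ndarray, disk: np.ndarray, annulus: np.ndarray) -> float:
    return float(frame[disk].mean() - frame[annulus].mean())


def extract_trace(movie: Movie | np.ndarray, roi: ROI) -> np.ndarray:
    """Per-frame ROI-disk mean minus annulus mean."""
    frames = movie.frames if isinstance(movie, Movie) else np.asarray(movie, float)
    if frames.ndim != 3:
        raise InputError("movie must be a (T, H, W) stack")
    disk, annulus = roi.masks(frames.shape[1:])
    return frames[:, disk].mean(axis=1) - frames[:, annulus].mean(axis=1)


def compute_threshold(baseline_trace: np.ndarray, n_sd: float = 3.0) -> float:
    """Event threshold from a baseline recording: mean + n_sd * SD."""
    baseline = np.asarray(baseline_trace, dtype=np.float64)
    if baseline.size == 0:
        raise InputError("baseline trace is empty")
    if n_sd <= 0:
        raise ParameterError(f"n_sd must be > 0, got {n_sd}")
    sd = float(baseline.std())
    if sd == 0.0:
        warnings.warn("baseline trace has zero standard deviation; "
                      "threshold equals the baseline mean", stacklevel=2)
    return float(baseline.mean() + n_sd * sd)


def detect_events(trace: np.ndarray, threshold: float) -> list[int]:
    """Find complete threshold excursions; one event per excursion.

    An excursion opens when the trace rises strictly above the threshold from
    at-or-below, and closes (the event, logged at that frame) when it falls
    back to at-or-below. An excursion still open at the end is discarded.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if not np.all(np.isfinite(trace)):
        raise InputError("trace contains non-finite values")
    events: list[int] = []
    above = False
    for t, v in enumerate(trace):
        if not above and v > threshold:
            above = True
        elif above and v <= threshold:
            events.append(t)
            above = False
    return events


class StreamingEventDetector:
    """Online excursion detector over a stream of corrected frames.

    Holds the ROI masks and threshold, consumes one frame at a time, and
    maintains the open/closed excursion state so that after the last frame
    its event list equals the batch :func:`detect_events` output on the full
    trace exactly.
    """

    def __init__(self, roi: ROI, threshold: float,
                 frame_shape: tuple[int, int]) -> None:
        self.roi = roi
        self.threshold = float(threshold)
        self._disk, self._annulus = roi.masks(frame_shape)
        self._above = False
        self.trace: list[float] = []
        self.events: list[int] = []

    @property
    def event_count(self) -> int:
        return len(self.events)

    def update(self, frame: np.ndarray) -> bool:
        """Consume one frame; returns True if an event closed on this frame."""
        v = _frame_trace_value(np.asarray(frame, float), self._disk, self._annulus)
        t = len(self.trace)
        self.trace.append(v)
        if not self._above and v > self.threshold:
            self._above = True
        elif self._above and v <= self.threshold:
            self._above = False
            self.events.append(t)
            return True
        return False


def trace_psnr(trace: np.ndarray, events: list[int],
               threshold: float | None = None) -> float:
    """Peak signal-to-noise ratio of a trace, in dB.

    PSNR = 20·log10(peak / noise_sd) with peak = max(trace − baseline
    median) and noise_sd the SD of the trace over frames outside detected
    excursions (frames above the threshold, when one is given, are treated
    as in-excursion).
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.size == 0:
        raise InputError("trace is empty")
    baseline_median = float(np.median(trace))
    peak = float(np.max(trace - baseline_median))
    if threshold is not None:
        quiet = trace <= threshold
    else:
        quiet = np.ones(trace.size, dtype=bool)
        # mask a symmetric window around each event's return frame
        for t in events:
            quiet[max(0, t - 10): t + 1] = False
    if not quiet.any():
        raise InputError("no non-event frames: PSNR undefined")
    noise_sd = float(trace[quiet].std())
    if noise_sd == 0.0:
        return float("inf") if peak > 0 else float("nan")
    return float(20.0 * np.log10(peak / noise_sd)) if peak > 0 else float("-inf")


def trace_power_spectrum(
    trace: np.ndarray, frame_rate: float = 20.0
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-removed one-sided power spectrum of a trace.

    Normalized so that the total spectral power equals the trace variance
    (Parseval). Returns (frequencies in Hz up to frame_rate/2, power).
    """
    trace = np.asarray(trace, dtype=np.float64)
    n = trace.size
    if n < 8:
        raise InputError(f"trace too short for a spectrum (n={n} < 8)")
    x = trace - trace.mean()
    spec = np.fft.rfft(x)
    power = np.abs(spec) ** 2 / n**2
    # fold negative frequencies into the one-sided spectrum
    if n % 2 == 0:
        power[1:-1] *= 2.0
    else:
        power[1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / frame_rate)
    return freqs, power


def extract_trace_set(
    movie: Movie,
    rois: list[ROI],
    baseline_movie: Movie | None = None,
    n_sd: float = 3.0,
) -> TraceSet:
    """Extract traces for all ROIs; threshold/detect events if a baseline is given."""
    data = {roi.id: extract_trace(movie, roi) for roi in rois}
    ts = TraceSet(traces=pd.DataFrame(data), frame_rate=movie.frame_rate)
    if baseline_movie is not None:
        for roi in rois:
            baseline = extract_trace(baseline_movie, roi)
            thr = compute_threshold(baseline, n_sd=n_sd)
            ev = detect_events(data[roi.id], thr)
            ts.thresholds[roi.id] = thr
            ts.events[roi.id] = ev
            try:
                ts.psnr[roi.id] = trace_psnr(data[roi.id], ev, threshold=thr)
            except InputError:
                ts.psnr[roi.id] = float("nan")
    return ts
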