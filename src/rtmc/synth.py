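"""Synthetic one-photon calcium movies with known ground truth.

Real miniscope frames are dominated by a heavily blurred background from
out-of-focus light scatter, crossed by dark vessel shadows, with neuron
somata (~10 px across) riding on top. Motion appears as frame-wide rigid
translation of everything at once. The generator emulates exactly those
ingredients — a smooth low-frequency background, curvilinear dark vessels,
Gaussian-profile neurons, exponentially decaying calcium transients,
frame-wide multiplicative illumination fluctuation, additive sensor noise,
and known rigid shifts — so registration, metrics and trace extraction can
all be tested against exact ground truth without any recorded data.

Sign convention: a truth entry (dx, dy) means the scene content moved dx
columns right and dy rows down relative to the base frame; registration
reports the same quantity and correction applies (-dx, -dy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.signal.windows import tukey

from .exceptions import ParameterError
from .movie import Movie
from .registration import apply_shift

__all__ = [
    "SceneSpec",
    "ShiftTruth",
    "Scene",
    "render_scene",
    "render_scene_detailed",
    "simulate_shifted_movie",
    "simulate_activity_movie",
]

# fixed intensity layout of the synthetic scene (pre-quantization units in [0, 1))
_BG_LOW, _BG_HIGH = 0.25, 0.55   # background intensity range
_VESSEL_DEPTH = 0.15             # how dark vessels are relative to background
_NEURON_BASELINE = 0.12          # resting-fluorescence blob amplitude
_TRANSIENT_AMP = 0.25            # amplitude jump per calcium event
_VIGNETTE_TAPER = 0.4            # Tukey taper fraction of the aperture vignette
_VIGNETTE_CUT = 0.1              # window level below which the FOV is black


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of the synthetic field of view.

    Defaults describe a typical miniscope recording: 256x256 px, 20 neurons
    of ~10 px diameter, background blurred far beyond the neuron scale.
    """

    height: int = 256
    width: int = 256
    n_neurons: int = 20
    neuron_diameter: float = 10.0
    background_blur_sigma: float = 50.0
    vessel_count: int = 6
    noise_sd: float = 0.01
    illumination_fluctuation_sd: float = 0.01
    background_fluctuation_sd: float = 0.15
    transient_decay: float = 0.95
    event_rate: float = 0.01
    texture_sd: float = 0.08
    texture_grain_sigma: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ParameterError(
                f"height/width must be >= 16, got {self.height}x{self.width}"
            )
        if self.n_neurons < 0:
            raise ParameterError(f"n_neurons must be >= 0, got {self.n_neurons}")
        if not (3 <= self.neuron_diameter < min(self.height, self.width) / 4):
            raise ParameterError(
                f"neuron_diameter must be in [3, min(height, width)/4), "
                f"got {self.neuron_diameter}"
            )
        if self.background_blur_sigma <= 0:
            raise ParameterError(
                f"background_blur_sigma must be > 0, got {self.background_blur_sigma}"
            )
        if self.vessel_count < 0:
            raise ParameterError(f"vessel_count must be >= 0, got {self.vessel_count}")
        if self.texture_grain_sigma <= 0:
            raise ParameterError(
                f"texture_grain_sigma must be > 0, got {self.texture_grain_sigma}"
            )
        for name in ("noise_sd", "illumination_fluctuation_sd",
                     "background_fluctuation_sd", "event_rate", "texture_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not (0 < self.transient_decay < 1):
            raise ParameterError(
                f"transient_decay must be in (0, 1), got {self.transient_decay}"
            )


@dataclass(frozen=True)
class ShiftTruth:
    """Ground-truth rigid translation of every frame, in pixels."""

    dx: np.ndarray
    dy: np.ndarray
    max_offset: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "dx", np.asarray(self.dx, dtype=np.float64))
        object.__setattr__(self, "dy", np.asarray(self.dy, dtype=np.float64))
        if self.dx.shape != self.dy.shape or self.dx.ndim != 1:
            raise ParameterError("dx and dy must be equal-length 1-D arrays")
        if self.max_offset >= 0 and (
            np.any(np.abs(self.dx) > self.max_offset)
            or np.any(np.abs(self.dy) > self.max_offset)
        ):
            raise ParameterError("shift truth exceeds max_offset bound")

    def __len__(self) -> int:
        return self.dx.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": np.arange(len(self)), "dx": self.dx, "dy": self.dy}
        )


@dataclass(frozen=True)
class Scene:
    """A rendered base frame together with its planted ground truth."""

    frame: np.ndarray
    neuron_centers: np.ndarray          # (n, 2) as (row, col)
    neuron_sigma: float                 # Gaussian blob sd, px
    neuron_amplitude: float             # baseline blob peak amplitude
    background: np.ndarray              # frame without neurons
    vignette: np.ndarray                # aperture falloff factor in (0, 1]

    def neuron_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(len(self.neuron_centers)),
                "row": self.neuron_centers[:, 0],
                "col": self.neuron_centers[:, 1],
                "radius": np.full(len(self.neuron_centers), 3 * self.neuron_sigma),
            }
        )


def _neuron_blobs(
    shape: tuple[int, int], centers: np.ndarray, sigma: float
) -> np.ndarray:
    """Stack of unit-peak Gaussian blobs, one per center, shape (n, H, W)."""
    h, w = shape
    y = np.arange(h)[:, None]
    x = np.arange(w)[None, :]
    blobs = np.empty((len(centers), h, w))
    for i, (cy, cx) in enumerate(centers):
        blobs[i] = np.exp(-((y - cy) ** 2 + (x - cx) ** 2) / (2.0 * sigma**2))
    return blobs


def _vignette(shape: tuple[int, int]) -> np.ndarray:
    """Aperture vignette: bright flat center falling off to black at the edge.

    One-photon miniscope frames are viewed through a lens aperture, so
    intensity falls smoothly toward the border and the outermost margin of
    the sensor sees no light at all; a Tukey window, re-leveled so values
    below a small cut are exactly zero, emulates that falloff with a true
    black rim ~10 px wide.
    """
    h, w = shape
    v = np.outer(tukey(h, _VIGNETTE_TAPER), tukey(w, _VIGNETTE_TAPER))
    v = np.clip((v - _VIGNETTE_CUT) / (1.0 - _VIGNETTE_CUT), 0.0, 1.0)
    return v * v * (3.0 - 2.0 * v)  # smoothstep: no gradient kink at the rim


def _place_centers(
    rng: np.random.Generator, spec: SceneSpec
) -> np.ndarray:
    """Draw neuron centers with an edge margin and minimum pairwise spacing.

    The margin keeps neurons inside the flat (unvignetted) part of the FOV.
    """
    margin = max(
        1.5 * spec.neuron_diameter,
        _VIGNETTE_TAPER / 2 * min(spec.height, spec.width),
    )
    min_sep = 1.5 * spec.neuron_diameter
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < spec.n_neurons:
        if attempts > 10000 * max(spec.n_neurons, 1):
            raise ParameterError(
                "n_neurons: could not place this many neurons at the requested "
                "diameter without overlap"
            )
        cy = rng.uniform(margin, spec.height - margin)
        cx = rng.uniform(margin, spec.width - margin)
        attempts += 1
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_sep**2 for y, x in centers):
            centers.append((cy, cx))
    return np.array(centers).reshape(-1, 2)


def _draw_vessels(rng: np.random.Generator, spec: SceneSpec) -> np.ndarray:
    """Dark curvilinear vessel mask in [0, 1], smoothly varying direction."""
    mask = np.zeros((spec.height, spec.width))
    y_grid = np.arange(spec.height)[:, None]
    x_grid = np.arange(spec.width)[None, :]
    for _ in range(spec.vessel_count):
        # random-walk centerline stamped with small disks
        cy = rng.uniform(0, spec.height)
        cx = rng.uniform(0, spec.width)
        angle = rng.uniform(0, 2 * np.pi)
        thickness = rng.uniform(1.5, 3.0)
        n_steps = int(1.2 * max(spec.height, spec.width))
        for _ in range(n_steps):
            angle += rng.normal(0, 0.15)
            cy += np.sin(angle)
            cx += np.cos(angle)
            if not (0 <= cy < spec.height and 0 <= cx < spec.width):
                break
            y0, y1 = int(max(0, cy - 4)), int(min(spec.height, cy + 5))
            x0, x1 = int(max(0, cx - 4)), int(min(spec.width, cx + 5))
            d2 = (y_grid[y0:y1] - cy) ** 2 + (x_grid[:, x0:x1] - cx) ** 2
            mask[y0:y1, x0:x1] = np.maximum(
                mask[y0:y1, x0:x1], np.exp(-d2 / (2 * thickness**2))
            )
    return gaussian_filter(mask, 1.0)


def render_scene_detailed(spec: SceneSpec) -> Scene:
    """Render a motion-free base frame and return it with its ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    # low-frequency structured background: blurred white noise, rescaled
    rough = rng.standard_normal((spec.height, spec.width))
    bg = gaussian_filter(rough, spec.background_blur_sigma, mode="reflect")
    lo, hi = bg.min(), bg.max()
    if hi - lo < 1e-12:
        bg = np.full_like(bg, 0.5 * (_BG_LOW + _BG_HIGH))
    else:
        bg = _BG_LOW + (_BG_HIGH - _BG_LOW) * (bg - lo) / (hi - lo)

    vessels = _draw_vessels(rng, spec)
    vignette = _vignette((spec.height, spec.width))
    background = bg * (1.0 - _VESSEL_DEPTH * vessels) * vignette

    # fine static tissue speckle — the "mark point" texture that survives
    # high-pass filtering and anchors registration in real recordings
    if spec.texture_sd > 0:
        tex = gaussian_filter(
            rng.standard_normal((spec.height, spec.width)),
            spec.texture_grain_sigma,
        )
        background = background + spec.texture_sd * (tex / tex.std()) * vignette

    centers = _place_centers(rng, spec)
    sigma = spec.neuron_diameter / 4.0  # ~95% of blob mass within the diameter
    frame = background.copy()
    if spec.n_neurons:
        frame = frame + vignette * (
            _NEURON_BASELINE
            * _neuron_blobs((spec.height, spec.width), centers, sigma).sum(axis=0)
        )

    frame = np.clip(frame, 0.0, 1.0 - 1e-9)
    return Scene(
        frame=frame,
        neuron_centers=centers,
        neuron_sigma=sigma,
        neuron_amplitude=_NEURON_BASELINE,
        background=background,
        vignette=vignette,
    )


def render_scene(spec: SceneSpec) -> np.ndarray:
    """Render the motion-free base frame for a scene spec (see Scene for truth)."""
    return render_scene_detailed(spec).frame


def simulate_shifted_movie(
    base: np.ndarray,
    n_frames: int = 5000,
    max_offset: float = 10.0,
    seed: int = 0,
    frame_rate: float = 20.0,
) -> tuple[Movie, ShiftTruth]:
    """Translate one base frame by random subpixel offsets, recording truth.

    Each frame is the base translated by (dx, dy) drawn uniformly from
    [-max_offset, +max_offset] per axis, resampled bilinearly with zero fill
    at the exposed border.
    """
    base = np.asarray(base, dtype=np.float64)
    if base.ndim != 2:
        raise ParameterError(f"base frame must be 2-D, got shape {base.shape}")
    if n_frames < 1:
        raise ParameterError(f"n_frames must be >= 1, got {n_frames}")
    if max_offset < 0:
        raise ParameterError(f"max_offset must be >= 0, got {max_offset}")
    h, w = base.shape
    if max_offset >= min(h, w) / 2:
        raise ParameterError(
            f"max_offset {max_offset} too large for {h}x{w} frames"
        )
    if min(h, w) <= 4 * max_offset:
        raise ParameterError(
            f"base frame must be larger than 4*max_offset in both dimensions"
        )

    rng = np.random.default_rng(seed)
    dx = rng.uniform(-max_offset, max_offset, n_frames) if max_offset else np.zeros(n_frames)
    dy = rng.uniform(-max_offset, max_offset, n_frames) if max_offset else np.zeros(n_frames)
    frames = np.empty((n_frames, h, w))
    for t in range(n_frames):
        frames[t] = apply_shift(base, dx[t], dy[t])
    movie = Movie(frames=frames, frame_rate=frame_rate)
    return movie, ShiftTruth(dx=dx, dy=dy, max_offset=max_offset)


def simulate_activity_movie(
    spec: SceneSpec,
    n_frames: int,
    shifts: ShiftTruth | None = None,
    frame_rate: float = 20.0,
    events: np.ndarray | None = None,
) -> tuple[Movie, pd.DataFrame, np.ndarray]:
    """Simulate a movie with calcium transients, illumination noise and motion.

    Per neuron, calcium events arrive at Poisson times (``event_rate`` events
    per frame); each event adds a fixed-amplitude jump to the neuron's
    transient trace, which decays by the factor ``transient_decay`` per
    frame. A frame is the static scene plus the instantaneous transient
    contribution plus a per-frame smooth local background fluctuation field
    (amplitude ``background_fluctuation_sd``, spatial scale
    ``background_blur_sigma`` — the dominant nuisance in one-photon data),
    scaled by a per-frame global illumination gain
    ``1 + N(0, illumination_fluctuation_sd)``, plus additive Gaussian sensor
    noise; the rigid shift is applied last.

    ``events`` overrides the Poisson draw with a fixed (n_frames, n_neurons)
    array of per-frame event counts, for planting transients at known times.

    Returns
    -------
    movie : Movie
    neuron_truth : DataFrame with columns id, row, col, radius
    trace_truth : ndarray, shape (n_frames, n_neurons)
        Noiseless transient amplitude of each neuron over time.
    """
    spec.validate()
    if n_frames < 1:
        raise ParameterError(f"n_frames must be >= 1, got {n_frames}")
    if shifts is not None and len(shifts) != n_frames:
        raise ParameterError(
            f"shifts length {len(shifts)} does not match n_frames {n_frames}"
        )
    scene = render_scene_detailed(spec)
    rng = np.random.default_rng(spec.seed + 1)  # independent of scene layout

    n = spec.n_neurons
    if events is None:
        events = rng.poisson(spec.event_rate, size=(n_frames, n)) if n else np.zeros((n_frames, 0), int)
    else:
        events = np.asarray(events)
        if events.shape != (n_frames, n):
            raise ParameterError(
                f"events must have shape ({n_frames}, {n}), got {events.shape}"
            )
    traces = np.zeros((n_frames, n))
    level = np.zeros(n)
    for t in range(n_frames):
        level = spec.transient_decay * level + _TRANSIENT_AMP * events[t]
        traces[t] = level

    blobs = _neuron_blobs(scene.frame.shape, scene.neuron_centers, scene.neuron_sigma) if n else None
    # envelope for the haze field: aperture profile blurred well beyond the
    # filter scale, so the haze neither survives high-pass filtering nor
    # creates a step against the zero-filled border
    haze_envelope = gaussian_filter(scene.vignette, 25.0)
    gains = 1.0 + rng.normal(0.0, spec.illumination_fluctuation_sd, n_frames)
    frames = np.empty((n_frames,) + scene.frame.shape)
    for t in range(n_frames):
        img = scene.frame
        if n and traces[t].any():
            img = img + scene.vignette * np.tensordot(traces[t], blobs, axes=1)
        if spec.background_fluctuation_sd:
            # additive local background fluctuation (out-of-focus haze with its
            # own smooth spatial pattern), faded out toward the FOV rim by a
            # blurred copy of the aperture profile so the dark border stays dark
            field = gaussian_filter(
                rng.standard_normal(img.shape), spec.background_blur_sigma
            )
            img = img + (
                spec.background_fluctuation_sd * field / field.std()
            ) * haze_envelope
        img = gains[t] * img
        if spec.noise_sd:
            img = img + rng.normal(0.0, spec.noise_sd, img.shape)
        if shifts is not None and (shifts.dx[t] or shifts.dy[t]):
            img = apply_shift(img, shifts.dx[t], shifts.dy[t])
        frames[t] = img

    return Movie(frames=frames, frame_rate=frame_rate), scene.neuron_table(), traces
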