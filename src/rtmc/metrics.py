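"""Evaluation measures for motion correction.

Two complementary views of registration quality:

* with simulated ground truth — per-frame deviation between estimated and
  true shifts (per-axis absolute error and Euclidean distance), with summary
  statistics and a paired Wilcoxon signed-rank comparison between methods;
* without ground truth — the correlation-with-mean (CM) metric: the Pearson
  correlation of every frame with the movie's temporal mean image, computed
  after cropping the black border that shifting leaves behind. A well
  registered movie has frames that all resemble the mean, so CM near 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import GeometryError, InputError
from .movie import Movie
from .synth import ShiftTruth

__all__ = ["DeviationReport", "CMReport", "deviation_stats", "cm_metric",
           "compare_deviations", "auto_crop_width", "simulated_shift_assessment"]


@dataclass(frozen=True)
class DeviationReport:
    """Per-frame shift-estimation errors and their summary statistics."""

    err_dx: np.ndarray       # estimated - true, signed, per frame
    err_dy: np.ndarray
    euclidean: np.ndarray    # sqrt(err_dx^2 + err_dy^2)

    @property
    def abs_per_axis(self) -> np.ndarray:
        """Per-frame per-axis absolute errors, shape (n_frames, 2)."""
        return np.abs(np.column_stack([self.err_dx, self.err_dy]))

    def summary(self) -> pd.DataFrame:
        per_axis = self.abs_per_axis.ravel()
        rows = {}
        for name, v in (("abs_per_axis", per_axis), ("euclidean", self.euclidean)):
            rows[name] = {
                "median": np.median(v),
                "mean": np.mean(v),
                "max": np.max(v),
                "q25": np.percentile(v, 25),
                "q75": np.percentile(v, 75),
            }
        return pd.DataFrame(rows).T

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.euclidean)),
                "err_dx": self.err_dx,
                "err_dy": self.err_dy,
                "euclidean": self.euclidean,
            }
        )


@dataclass(frozen=True)
class CMReport:
    """Per-frame correlation with the temporal mean image."""

    values: np.ndarray
    crop: int

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values))


def _shifts_as_arrays(obj) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(obj, ShiftTruth):
        return obj.dx, obj.dy
    if isinstance(obj, pd.DataFrame):
        return obj["dx"].to_numpy(float), obj["dy"].to_numpy(float)
    arr = np.asarray(obj, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InputError("shifts must be a ShiftTruth, a DataFrame with dx/dy "
                         "columns, or an (n, 2) array")
    return arr[:, 0], arr[:, 1]


def deviation_stats(estimated, truth) -> DeviationReport:
    """Per-frame deviation between estimated and true shifts.

    Accepts ``ShiftTruth`` objects, DataFrames with ``dx``/``dy`` columns, or
    (n, 2) arrays. Symmetric under swapping the two arguments (errors are
    reported signed, deviations as absolute values).
    """
    edx, edy = _shifts_as_arrays(estimated)
    tdx, tdy = _shifts_as_arrays(truth)
    if edx.shape != tdx.shape:
        raise InputError(
            f"length mismatch: estimated {edx.shape[0]} vs truth {tdx.shape[0]}"
        )
    err_dx = edx - tdx
    err_dy = edy - tdy
    return DeviationReport(
        err_dx=err_dx, err_dy=err_dy, euclidean=np.hypot(err_dx, err_dy)
    )


def compare_deviations(
    report_a: DeviationReport,
    report_b: DeviationReport,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test on per-frame Euclidean deviations.

    ``alternative='less'`` tests that method A's deviations are
    stochastically smaller than method B's. Returns (statistic, p-value).
    """
    a, b = report_a.euclidean, report_b.euclidean
    if a.shape != b.shape:
        raise InputError("deviation reports must cover the same frames")
    res = stats.wilcoxon(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def cm_metric(movie: Movie | np.ndarray, crop: int = 0) -> CMReport:
    """Correlation of each frame with the movie's temporal mean image.

    A border of ``crop`` pixels is removed from every frame first, discarding
    the zero-filled margin that translation leaves behind; the mean image is
    computed from the cropped movie. Frames with zero variance after cropping
    get NaN.
    """
    frames = movie.frames if isinstance(movie, Movie) else np.asarray(movie, float)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise InputError("movie must be a non-empty (T, H, W) stack")
    t, h, w = frames.shape
    crop = int(crop)
    if crop < 0 or crop >= min(h, w) / 2:
        raise GeometryError(f"crop {crop} must be in [0, min(h, w)/2)")
    if crop:
        frames = frames[:, crop:-crop, crop:-crop]
    flat = frames.reshape(t, -1)
    mean_img = flat.mean(axis=0)
    dm = mean_img - mean_img.mean()
    dm_norm = np.sqrt(np.sum(dm * dm))
    df = flat - flat.mean(axis=1, keepdims=True)
    f_norm = np.sqrt(np.sum(df * df, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        values = (df @ dm) / (f_norm * dm_norm)
    values[(f_norm == 0) | (dm_norm == 0)] = np.nan
    return CMReport(values=values, crop=crop)


def simulated_shift_assessment(
    spec=None,
    n_frames: int = 500,
    max_offset: float = 10.0,
    seed: int = 0,
    n_prerecorded: int = 60,
    filtered: bool = True,
    collect: bool = False,
):
    """Ground-truth accuracy assessment on a simulated shifted movie.

    Emulates the evaluation protocol for a registration method: simulate a
    short motion-free prerecorded movie of a synthetic scene (calcium
    activity, background fluctuation, sensor noise), build the template from
    it, hold out one further activity frame as the base, translate that base
    ``n_frames`` times by random subpixel offsets within ``max_offset``, run
    the correction pipeline over the shifted movie, and score the estimated
    shifts against the recorded truth.

    ``filtered=False`` runs the naive unfiltered-NCC baseline used as the
    internal ablation.

    Returns
    -------
    run : CorrectionRun
    truth : ShiftTruth
    report : DeviationReport
    """
    from .pipeline import correct_stream
    from .registration import RegistrationParams
    from .filtering import make_highpass_kernel
    from .synth import SceneSpec, simulate_activity_movie, simulate_shifted_movie
    from .template import init_template

    spec = spec if spec is not None else SceneSpec(seed=seed)
    pre_movie, _, _ = simulate_activity_movie(spec, n_prerecorded + 1)
    prerecorded = pre_movie.frames[:n_prerecorded]
    base = pre_movie.frames[n_prerecorded]
    movie, truth = simulate_shifted_movie(base, n_frames, max_offset, seed=seed)
    kernel = make_highpass_kernel(spec.neuron_diameter) if filtered else None
    state = init_template(prerecorded, kernel)
    run = correct_stream(movie, state, kernel, RegistrationParams(),
                         collect=collect)
    report = deviation_stats(run.shifts, truth)
    return run, truth, report


def auto_crop_width(shifts, safety: int = 1) -> int:
    """Default CM crop: ceiling of the largest |shift| plus a safety pixel."""
    dx, dy = _shifts_as_arrays(shifts)
    if dx.size == 0:
        return safety
    return int(np.ceil(max(np.abs(dx).max(), np.abs(dy).max()))) + safety
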