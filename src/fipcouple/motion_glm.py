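"""Motion-energy GLM: regress dF/F0 on kernel-convolved motion energy.

Motion energy is the summed absolute frame-by-frame grayscale difference of
a behavioral video; it is resampled to the 40 Hz photometry clock and
convolved with a 2.5 s Gaussian kernel (approximating the calcium
indicator's temporal dynamics) before an ordinary-least-squares fit of the
dF/F0 signal on the regressor. The fit yields a slope (beta) quantifying
motion-signal coupling and a coefficient of determination (R^2); per-mouse
summaries are means of trial-level values.

The "2.5 s Gaussian kernel" is parameterized as full width 2.5 s with
sigma = 2.5/6 s, truncated at +/- 3 sigma; ``sigma_is_width=False`` reads
the 2.5 s as sigma directly instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LinearRegression

__all__ = [
    "MotionEnergyTrace",
    "GLMFit",
    "motion_energy",
    "resample_to",
    "gaussian_convolve",
    "fit_motion_glm",
    "summarize_glm",
]


@dataclass
class MotionEnergyTrace:
    """Nonnegative motion-energy time series at the source (video) rate."""

    time: np.ndarray
    values: np.ndarray
    source_rate: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time.shape != self.values.shape:
            raise ValueError("time and values must have equal length")
        if self.time.size and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.values.size and self.values.min() < 0:
            raise ValueError("motion energy must be nonnegative")
        if self.source_rate <= 0:
            raise ValueError("source_rate must be positive")


@dataclass
class GLMFit:
    """OLS fit of one trial's dF/F0 on the convolved motion-energy regressor."""

    beta: float
    intercept: float
    r_squared: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples <= 2:
            raise ValueError("need more than 2 samples for a slope fit")
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError(f"R^2 = {self.r_squared} outside [0, 1]")


def motion_energy(frames: np.ndarray, fs_video: float = 30.0) -> MotionEnergyTrace:
    """Summed absolute frame-by-frame grayscale difference of a video stack.

    ``frames`` is a (n_frames, height, width) array; the output has
    ``n_frames - 1`` values, value[i] = sum |frame[i+1] - frame[i]|.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be a (n_frames, h, w) grayscale stack")
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    values = np.abs(np.diff(frames, axis=0)).sum(axis=(1, 2))
    time = np.arange(values.size) / fs_video
    return MotionEnergyTrace(time=time, values=values, source_rate=fs_video)


def resample_to(trace: MotionEnergyTrace, target_rate: float = 40.0) -> MotionEnergyTrace:
    """Linear interpolation of a motion-energy trace onto the photometry clock.

    The target clock spans the source time range at ``target_rate``;
    endpoints are clamped (np.interp semantics), which preserves
    nonnegativity exactly.
    """
    if trace.values.size == 0:
        raise ValueError("cannot resample an empty trace")
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    t0, t1 = trace.time[0], trace.time[-1]
    t_new = t0 + np.arange(int(np.floor((t1 - t0) * target_rate)) + 1) / target_rate
    v_new = np.interp(t_new, trace.time, trace.values)
    return MotionEnergyTrace(time=t_new, values=v_new, source_rate=target_rate)


def gaussian_convolve(
    trace: np.ndarray,
    fs: float,
    width: float = 2.5,
    sigma_is_width: bool = True,
) -> np.ndarray:
    """Convolve a regressor with a unit-area Gaussian kernel (default 2.5 s).

    ``width`` is the kernel's full width (sigma = width/6, truncated at
    +/- 3 sigma); with ``sigma_is_width=False`` it is sigma itself.
    Reflective padding keeps the output the same length without onset
    transients; a constant trace passes through unchanged.
    """
    trace = np.asarray(trace, dtype=float)
    sigma = width / 6.0 if sigma_is_width else width
    radius = max(1, round(3.0 * sigma * fs))
    if trace.size <= radius:
        raise ValueError(
            f"trace of {trace.size} samples shorter than kernel half-support {radius}"
        )
    x = np.arange(-radius, radius + 1) / fs
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()
    padded = np.pad(trace, radius, mode="reflect")
    return np.convolve(padded, kernel, mode="valid")


def fit_motion_glm(dff: np.ndarray, regressor: np.ndarray) -> GLMFit | None:
    """OLS of a trial's dF/F0 on the convolved motion-energy regressor.

    Returns beta (dF/F0 per motion-energy unit), intercept and R^2 = 1 -
    RSS/TSS. A zero-variance regressor leaves the fit undefined; the trial
    is excluded (``None`` returned) with a warning.
    """
    dff = np.asarray(dff, dtype=float)
    regressor = np.asarray(regressor, dtype=float)
    if dff.shape != regressor.shape:
        raise ValueError("dff and regressor must have equal length")
    if regressor.std() == 0:
        warnings.warn("zero-variance regressor: GLM fit undefined, trial excluded",
                      RuntimeWarning, stacklevel=2)
        return None
    X = regressor.reshape(-1, 1)
    model = LinearRegression().fit(X, dff)
    r2 = float(model.score(X, dff)) if dff.std() > 0 else 0.0
    return GLMFit(
        beta=float(model.coef_[0]),
        intercept=float(model.intercept_),
        r_squared=max(0.0, r2),
        n_samples=dff.size,
    )


def summarize_glm(fits: list[GLMFit]) -> dict:
    """Per-mouse aggregation: mean of trial-level beta and R^2."""
    kept = [f for f in fits if f is not None]
    if not kept:
        return {"mean_beta": None, "mean_r_squared": None, "n_trials": 0}
    return {
        "mean_beta": float(np.mean([f.beta for f in kept])),
        "mean_r_squared": float(np.mean([f.r_squared for f in kept])),
        "n_trials": len(kept),
    }
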