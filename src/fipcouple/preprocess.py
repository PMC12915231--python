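"""Raw fluorescence to behavior-locked dF/F0 segments.

Converts multi-channel photometry recordings into artifact-corrected,
peri-event dF/F0 trial windows. The processing chain is:

1. isosbestic correction of each signal channel (whole-session linear
   regression on the calcium-independent reference channel),
2. extraction of a behavior-specific peri-event window,
3. dF/F0 = (F - F0) / F0 with F0 the mean of F over the behavior-specific
   baseline sub-window,
4. zero-phase 0.001-3 Hz bandpass,
5. 1 s trim at both ends (digging and licking trials only).

Windows are half-open sample-index ranges [round(start*fs), round(end*fs))
relative to the onset sample; the onset is snapped to the nearest sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import signal as sps

__all__ = [
    "PhotometrySession",
    "TrialWindow",
    "BEHAVIOR_WINDOWS",
    "TRIM_BEHAVIORS",
    "isosbestic_correct",
    "compute_dff",
    "extract_trial",
    "bandpass",
    "trim",
]

#: Peri-event analysis window and baseline (seconds relative to onset).
BEHAVIOR_WINDOWS: dict[str, dict[str, tuple[float, float]]] = {
    "digging": {"window": (-5.0, 5.0), "baseline": (-4.0, -2.0)},
    "licking": {"window": (-5.0, 5.0), "baseline": (-4.0, -2.0)},
    "turning": {"window": (-1.0, 1.0), "baseline": (-1.0, 0.0)},
}

#: Behaviors whose trial traces are trimmed 1 s at both ends after filtering.
TRIM_BEHAVIORS = frozenset({"digging", "licking"})


@dataclass
class PhotometrySession:
    """Synchronized multi-channel fluorescence recording.

    Parameters
    ----------
    time : array of seconds, strictly increasing, nominally uniform.
    channels : mapping of channel name to raw fluorescence trace (a.u.),
        each the same length as ``time``.
    sampling_rate : nominal rate in Hz; must agree with the median time
        step within 1%.
    metadata : free-form session annotations (subject, group, date ...).
    """

    time: np.ndarray
    channels: Mapping[str, np.ndarray]
    sampling_rate: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValueError("time must be a 1-D array with >= 2 samples")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name, trace in self.channels.items():
            if trace.shape != self.time.shape:
                raise ValueError(
                    f"channel {name!r} length {trace.size} != time length {self.time.size}"
                )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        step = float(np.median(np.diff(self.time)))
        if abs(step - 1.0 / self.sampling_rate) > 0.01 / self.sampling_rate:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} Hz inconsistent with median "
                f"time step {step:.6g} s (>1% off)"
            )

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def index_of(self, t: float) -> int:
        """Nearest-sample index of time ``t`` on the session clock."""
        return int(np.argmin(np.abs(self.time - t)))


@dataclass
class TrialWindow:
    """One peri-event dF/F0 segment pair (two regions).

    ``dff_a`` / ``dff_b`` are unitless dF/F0 traces on the window's sample
    grid; ``F0_a`` / ``F0_b`` are the raw-unit baseline means they were
    normalized by. ``window`` and ``baseline`` are in seconds relative to
    the event onset (t = 0).
    """

    behavior: str
    onset: float
    window: tuple[float, float]
    baseline: tuple[float, float]
    dff_a: np.ndarray
    dff_b: np.ndarray
    F0_a: float
    F0_b: float
    sampling_rate: float = 40.0
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.window[0] <= self.baseline[0] <= self.baseline[1] <= self.window[1]):
            raise ValueError("baseline must lie inside the analysis window")

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds relative to onset."""
        i0 = round(self.window[0] * self.sampling_rate)
        return (i0 + np.arange(self.dff_a.size)) / self.sampling_rate


class DegenerateBaselineError(ValueError):
    """Baseline mean F0 <= 0: dF/F0 undefined for this trial."""


class WindowOutOfBoundsError(ValueError):
    """Requested peri-event window exceeds the recording extent."""


def _slow_trend(trace: np.ndarray, fs: float, cutoff: float = 0.1) -> np.ndarray:
    """Low-pass estimate of the slow (bleaching-scale) trend of a trace."""
    if trace.size < 10:
        return np.full_like(trace, trace.mean())
    sos = sps.butter(2, cutoff, btype="low", fs=fs, output="sos")
    padlen = min(trace.size - 1, 3 * (2 * sos.shape[0] + 1))
    return sps.sosfiltfilt(sos, trace, padlen=padlen)


def isosbestic_correct(
    signal: np.ndarray, isosbestic: np.ndarray, fs: float
) -> np.ndarray:
    """Remove bleaching and motion artifacts using the isosbestic channel.

    Fits ``signal ~ a * isosbestic + b`` by ordinary least squares over the
    whole session and returns ``signal - (a*isosbestic + b) + mean(signal)``,
    so shared artifact components (bleaching, motion) cancel while the mean
    fluorescence level is preserved. If the isosbestic channel carries no
    variance there is nothing to regress on; a low-pass trend is subtracted
    instead (with a warning).
    """
    signal = np.asarray(signal, dtype=float)
    isosbestic = np.asarray(isosbestic, dtype=float)
    if signal.shape != isosbestic.shape:
        raise ValueError("signal and isosbestic must have equal length")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if np.ptp(isosbestic) == 0 or np.var(isosbestic) == 0:
        warnings.warn(
            "isosbestic channel has zero variance; falling back to low-pass detrend",
            RuntimeWarning,
            stacklevel=2,
        )
        return signal - _slow_trend(signal, fs) + signal.mean()
    a, b = np.polyfit(isosbestic, signal, 1)
    return signal - (a * isosbestic + b) + signal.mean()


def compute_dff(
    session: PhotometrySession,
    onset: float,
    channel: str,
    behavior: str = "digging",
) -> tuple[np.ndarray, float]:
    """Behavior-locked dF/F0 for one channel around one event onset.

    dF/F0(t) = (F(t) - F0) / F0, with F0 the mean of F over the
    behavior-specific baseline (digging/licking: -4 to -2 s; turning:
    -1 to 0 s relative to onset).

    Returns ``(dff, F0)`` where ``dff`` covers the behavior's analysis
    window as a half-open sample range.

    Raises
    ------
    WindowOutOfBoundsError
        if the window does not fit inside the recording.
    DegenerateBaselineError
        if F0 <= 0.
    """
    if behavior not in BEHAVIOR_WINDOWS:
        raise ValueError(f"unknown behavior {behavior!r}")
    win = BEHAVIOR_WINDOWS[behavior]["window"]
    base = BEHAVIOR_WINDOWS[behavior]["baseline"]
    fs = session.sampling_rate
    trace = session.channels[channel]
    onset_idx = session.index_of(onset)
    i0 = onset_idx + round(win[0] * fs)
    i1 = onset_idx + round(win[1] * fs)
    if i0 < 0 or i1 > trace.size:
        raise WindowOutOfBoundsError(
            f"window [{win[0]}, {win[1]}) s around onset {onset:.3f} s exceeds "
            f"recording bounds"
        )
    b0 = onset_idx + round(base[0] * fs)
    b1 = onset_idx + round(base[1] * fs)
    if b1 <= b0:
        raise ValueError("empty baseline")
    F0 = float(trace[b0:b1].mean())
    if F0 <= 0:
        raise DegenerateBaselineError(f"baseline mean F0 = {F0:.4g} <= 0")
    return (trace[i0:i1] - F0) / F0, F0


def extract_trial(
    session: PhotometrySession,
    onset: float,
    channel_a: str,
    channel_b: str,
    behavior: str = "digging",
    attributes: dict | None = None,
) -> TrialWindow:
    """Build a two-region :class:`TrialWindow` around one event onset."""
    dff_a, f0a = compute_dff(session, onset, channel_a, behavior)
    dff_b, f0b = compute_dff(session, onset, channel_b, behavior)
    spec = BEHAVIOR_WINDOWS[behavior]
    return TrialWindow(
        behavior=behavior,
        onset=onset,
        window=spec["window"],
        baseline=spec["baseline"],
        dff_a=dff_a,
        dff_b=dff_b,
        F0_a=f0a,
        F0_b=f0b,
        sampling_rate=session.sampling_rate,
        attributes=dict(attributes or {}),
    )


def bandpass(
    trace: np.ndarray, fs: float, low: float = 0.001, high: float = 3.0
) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth bandpass (default 0.001-3 Hz).

    Realized as a zero-phase low-pass at the upper edge followed by
    subtraction of the mean and of a zero-phase low-pass trend at the lower
    edge. The trend filter uses Gustafsson's minimal-transient
    forward-backward method: with a 0.001 Hz corner the filter's settling
    time (hundreds of seconds) exceeds any trial, so conventional
    edge-padding initial conditions would swamp short traces with drift.
    Phase is preserved throughout, so downstream lag estimates are
    unaffected.
    """
    trace = np.asarray(trace, dtype=float)
    if fs <= 2 * high:
        raise ValueError(f"sampling rate {fs} Hz must exceed twice the upper edge {high} Hz")
    if trace.size < 10:
        raise ValueError(f"trace of {trace.size} samples is too short to bandpass")
    sos = sps.butter(2, high, btype="low", fs=fs, output="sos")
    padlen = min(trace.size - 1, 3 * (2 * sos.shape[0] + 1))
    y = sps.sosfiltfilt(sos, trace - trace.mean(), padlen=padlen)
    b_lo, a_lo = sps.butter(2, low, btype="low", fs=fs)
    trend = sps.filtfilt(b_lo, a_lo, y, method="gust")
    return y - trend


def trim(trace: np.ndarray, fs: float, seconds: float = 1.0) -> np.ndarray:
    """Drop ``round(seconds*fs)`` samples from each end of a trial trace.

    Removes filter edge effects; the pipeline applies this to digging and
    licking trials only.
    """
    trace = np.asarray(trace)
    k = round(seconds * fs)
    if trace.size - 2 * k < 2:
        raise ValueError(
            f"cannot trim {seconds} s ({k} samples) from each end of a "
            f"{trace.size}-sample trace"
        )
    return trace[k : trace.size - k]
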