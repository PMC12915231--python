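"""Coupling statistics between the two regional dF/F0 signals.

Static Pearson correlation (after bandpass and, for digging/licking, 1 s
trim), sliding-window correlation (4 s window, 0.5 s step), phase lag from
the absolute cross-correlation maximum, plateau/peak amplitudes, and
sum-dFF activity with per-bin QC.

Sign convention for the phase lag: ``c(tau)`` is the Pearson correlation
between ``A(t)`` and ``B(t - tau)`` over the overlapping samples, so a
positive estimated lag means region B precedes (leads) region A. Ties in
``|c|`` are broken toward smaller ``|tau|``, then toward negative ``tau``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import TRIM_BEHAVIORS, bandpass, trim

__all__ = [
    "CouplingMetrics",
    "ActivitySummary",
    "static_correlation",
    "sliding_correlation",
    "phase_lag",
    "cross_correlogram",
    "plateau_amplitude",
    "peak_amplitude",
    "sum_dff",
    "trial_coupling",
]


class DegenerateTraceError(ValueError):
    """A correlation is undefined (zero-variance trace); trial excluded."""


@dataclass
class CouplingMetrics:
    """Per-trial (or per-subject) coupling summary."""

    correlation: float
    phase_lag: float
    plateau_a: float | None = None
    plateau_b: float | None = None
    peak_a: float | None = None
    peak_b: float | None = None
    sliding_r: np.ndarray | None = field(default=None, repr=False)
    n_trials: int = 1

    def __post_init__(self) -> None:
        if np.isfinite(self.correlation) and abs(self.correlation) > 1 + 1e-12:
            raise ValueError(f"|r| = {abs(self.correlation)} > 1")


@dataclass
class ActivitySummary:
    """Sum-dFF activity over an unstructured epoch, with QC bookkeeping."""

    sum_dff: float
    n_bins: int
    n_excluded_bins: int
    excluded_bins: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_excluded_bins > self.n_bins:
            raise ValueError("more excluded bins than bins")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        raise DegenerateTraceError("zero-variance trace: Pearson r undefined")
    return float(np.corrcoef(a, b)[0, 1])


def static_correlation(
    dff_a: np.ndarray,
    dff_b: np.ndarray,
    fs: float,
    behavior: str = "digging",
    filtered: bool = False,
) -> float:
    """Static (global) Pearson r of a trial's two dF/F0 traces.

    Traces are bandpassed (0.001-3 Hz) and, for digging/licking, trimmed
    1 s at both ends before the coefficient is computed. Pass
    ``filtered=True`` if the caller already bandpassed the traces.
    """
    dff_a = np.asarray(dff_a, dtype=float)
    dff_b = np.asarray(dff_b, dtype=float)
    if dff_a.shape != dff_b.shape:
        raise ValueError("traces must have equal length")
    if not filtered:
        dff_a = bandpass(dff_a, fs)
        dff_b = bandpass(dff_b, fs)
    if behavior in TRIM_BEHAVIORS:
        dff_a = trim(dff_a, fs)
        dff_b = trim(dff_b, fs)
    return _pearson(dff_a, dff_b)


def sliding_correlation(
    dff_a: np.ndarray,
    dff_b: np.ndarray,
    fs: float,
    window: float = 4.0,
    step: float = 0.5,
) -> np.ndarray:
    """Time-resolved Pearson r in a sliding window (4 s advanced by 0.5 s).

    Returns a ``(n_windows, 2)`` array of ``(window_center_s, r)`` rows;
    only complete windows are evaluated, so the count is
    ``floor((T - window)/step) + 1``. A trace shorter than one window
    yields an empty array with a warning.
    """
    dff_a = np.asarray(dff_a, dtype=float)
    dff_b = np.asarray(dff_b, dtype=float)
    if dff_a.shape != dff_b.shape:
        raise ValueError("traces must have equal length")
    wlen = round(window * fs)
    slen = round(step * fs)
    n = dff_a.size
    if n < wlen:
        warnings.warn("trace shorter than sliding window; empty result", RuntimeWarning, stacklevel=2)
        return np.empty((0, 2))
    rows = []
    start = 0
    while start + wlen <= n:
        center = (start + wlen / 2.0) / fs
        rows.append((center, _pearson(dff_a[start : start + wlen], dff_b[start : start + wlen])))
        start += slen
    return np.asarray(rows)


def _lagged_correlations(
    a: np.ndarray, b: np.ndarray, max_lag_samples: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-lag Pearson r between A(t) and B(t - tau) over overlapping samples.

    Lag is in samples; positive lag pairs A[k:] with B[:-k] (B shifted
    later onto A's clock, i.e. B leading). Degenerate (zero-variance)
    overlaps yield NaN for that lag.
    """
    n = a.size
    lags = np.arange(-max_lag_samples, max_lag_samples + 1)
    out = np.full(lags.size, np.nan)
    for i, k in enumerate(lags):
        if k > 0:
            aa, bb = a[k:], b[: n - k]
        elif k < 0:
            aa, bb = a[: n + k], b[-k:]
        else:
            aa, bb = a, b
        if aa.size < 3 or aa.std() == 0 or bb.std() == 0:
            continue
        out[i] = np.corrcoef(aa, bb)[0, 1]
    return lags, out


def phase_lag(
    dff_a: np.ndarray,
    dff_b: np.ndarray,
    fs: float,
    max_lag: float = 2.0,
) -> float:
    """Signed lag (s) maximizing the absolute cross-correlation.

    Positive lag means region B precedes region A. Traces should already be
    bandpassed. Ties in ``|c|`` are broken toward smaller ``|tau|``, then
    negative ``tau``.
    """
    dff_a = np.asarray(dff_a, dtype=float)
    dff_b = np.asarray(dff_b, dtype=float)
    if dff_a.shape != dff_b.shape:
        raise ValueError("traces must have equal length")
    if max_lag >= dff_a.size / fs / 2.0:
        raise ValueError("max_lag must be smaller than half the trace duration")
    L = round(max_lag * fs)
    lags, c = _lagged_correlations(dff_a, dff_b, L)
    if np.all(np.isnan(c)):
        raise DegenerateTraceError("all lags degenerate: phase lag undefined")
    # tie-break: smaller |tau| first, then negative tau
    order = sorted(range(lags.size), key=lambda i: (abs(int(lags[i])), int(lags[i])))
    best_i, best_abs = None, -np.inf
    for i in order:
        if np.isnan(c[i]):
            continue
        if abs(c[i]) > best_abs:
            best_abs = abs(c[i])
            best_i = i
    return float(lags[best_i] / fs)


def cross_correlogram(
    dff_a: np.ndarray,
    dff_b: np.ndarray,
    fs: float,
    max_lag: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Full normalized cross-correlation curve ``(lags_s, c(tau))``.

    Each value is a per-lag Pearson r over the overlapping segment, so the
    curve is bounded in [-1, 1] and curves from trials of different lengths
    can be averaged directly. ``c(0)`` equals the static Pearson r of the
    input traces.
    """
    dff_a = np.asarray(dff_a, dtype=float)
    dff_b = np.asarray(dff_b, dtype=float)
    if dff_a.shape != dff_b.shape:
        raise ValueError("traces must have equal length")
    L = round(max_lag * fs)
    lags, c = _lagged_correlations(dff_a, dff_b, L)
    return lags / fs, c


def _interval_mean(
    dff: np.ndarray, fs: float, interval: tuple[float, float], window_start: float
) -> float:
    i0 = round((interval[0] - window_start) * fs)
    i1 = round((interval[1] - window_start) * fs)
    if i0 < 0 or i1 > dff.size:
        raise ValueError(
            f"trial window starting at {window_start} s does not cover "
            f"[{interval[0]}, {interval[1]}) s"
        )
    return float(np.asarray(dff[i0:i1], dtype=float).mean())


def plateau_amplitude(dff: np.ndarray, fs: float, window_start: float = -5.0) -> float:
    """Mean dF/F0 over the plateau stage, [1, 2) s after behavior onset."""
    return _interval_mean(dff, fs, (1.0, 2.0), window_start)


def peak_amplitude(dff: np.ndarray, fs: float, window_start: float = -5.0) -> float:
    """Mean dF/F0 over the peak stage, [0, 0.5) s after behavior onset."""
    return _interval_mean(dff, fs, (0.0, 0.5), window_start)


def sum_dff(
    raw_F: np.ndarray,
    fs: float,
    bin_s: float = 8.0,
    qc_threshold: float = 0.8,
    raw_reference: np.ndarray | None = None,
) -> ActivitySummary:
    """Sum-dFF activity of a long free-moving/treadmill epoch, with QC.

    The trace is cut into equal bins (default 8 s; a final partial bin is
    dropped). Within each bin, dF/F0 is computed with F0 = the bin's 20th
    percentile; the bin is retained only if the Pearson r between its
    dF/F0 and the raw reference trace is >= ``qc_threshold`` (bins with
    undefined r, or F0 <= 0, are excluded and logged). The activity is the
    sum of dF/F0 samples over retained bins.

    ``raw_reference`` is the uncorrected raw F used for the QC comparison;
    it defaults to the input itself (in which case the processed and raw
    traces coincide).
    """
    F = np.asarray(raw_F, dtype=float)
    ref = F if raw_reference is None else np.asarray(raw_reference, dtype=float)
    if ref.shape != F.shape:
        raise ValueError("raw_reference must match raw_F in length")
    blen = round(bin_s * fs)
    if F.size < blen:
        raise ValueError(f"epoch shorter than one {bin_s} s bin")
    n_bins = F.size // blen
    total = 0.0
    excluded: list[tuple[int, str]] = []
    for b in range(n_bins):
        seg = F[b * blen : (b + 1) * blen]
        seg_ref = ref[b * blen : (b + 1) * blen]
        F0 = np.percentile(seg, 20)
        if F0 <= 0:
            excluded.append((b, f"F0 = {F0:.4g} <= 0"))
            continue
        dff = (seg - F0) / F0
        if dff.std() == 0 or seg_ref.std() == 0:
            excluded.append((b, "undefined r (zero variance)"))
            continue
        r = np.corrcoef(dff, seg_ref)[0, 1]
        if r < qc_threshold:
            excluded.append((b, f"r = {r:.3f} < {qc_threshold}"))
            continue
        total += float(dff.sum())
    return ActivitySummary(
        sum_dff=total,
        n_bins=n_bins,
        n_excluded_bins=len(excluded),
        excluded_bins=excluded,
    )


def trial_coupling(
    dff_a: np.ndarray,
    dff_b: np.ndarray,
    fs: float,
    behavior: str = "digging",
    max_lag: float = 2.0,
    window: float = 4.0,
    step: float = 0.5,
) -> CouplingMetrics:
    """All coupling metrics for one trial, on the standard processing path.

    Bandpasses once, computes the static r (with behavior-appropriate
    trim), the phase lag and sliding-window r on the filtered traces, and
    the plateau (digging) or peak (licking) amplitudes on the unfiltered
    dF/F0.
    """
    fa = bandpass(np.asarray(dff_a, dtype=float), fs)
    fb = bandpass(np.asarray(dff_b, dtype=float), fs)
    r = static_correlation(fa, fb, fs, behavior, filtered=True)
    ta, tb = (trim(fa, fs), trim(fb, fs)) if behavior in TRIM_BEHAVIORS else (fa, fb)
    lag = phase_lag(ta, tb, fs, max_lag=max_lag)
    sr = sliding_correlation(ta, tb, fs, window=window, step=step)
    metrics = CouplingMetrics(correlation=r, phase_lag=lag, sliding_r=sr)
    if behavior == "digging":
        metrics.plateau_a = plateau_amplitude(dff_a, fs)
        metrics.plateau_b = plateau_amplitude(dff_b, fs)
    elif behavior == "licking":
        metrics.peak_a = peak_amplitude(dff_a, fs)
        metrics.peak_b = peak_amplitude(dff_b, fs)
    return metrics
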