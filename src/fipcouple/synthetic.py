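"""Synthetic dual-region photometry sessions with known ground truth.

Generates everything the downstream estimators consume — raw two-region
fluorescence with isosbestic reference channels, behavioral event streams,
lick/cue timestamp trains, and motion-energy regressors — from a small set
of interpretable parameters, so every estimator has a parameter-recovery
test against stored truth.

Signal model (per signal channel)::

    F(t) = baseline_F * (1 + bleach(t) + motion(t) + calcium(t) + noise(t))

where ``bleach`` is a slow multiplicative exponential decay, ``motion`` is
a smooth artifact shared bit-for-bit between each signal channel and its
isosbestic reference (so isosbestic regression can cancel it exactly),
``calcium`` is an event-locked transient drive, and ``noise`` is white
Gaussian sensor noise. The isosbestic channels carry bleach + motion +
noise but no calcium component.

The calcium transient is a double-exponential kernel (rise/decay) convolved
with a boxcar spanning each behavioral event, normalized so that the mean
drive over 1-2 s after onset (the plateau window) equals 1; region
amplitudes then read directly in dF/F0 plateau units. The region-B drive is
the region-A drive advanced by ``inter_region_lag`` (positive lag = region
B precedes region A), mixed with an independent smooth drive at weight
``1 - shared_fraction``.

All randomness flows from one seed; per-component substreams are derived
deterministically from the component name, so identical parameters give
bit-identical sessions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .events import BehaviorEvent
from .motion_glm import MotionEnergyTrace
from .preprocess import PhotometrySession

__all__ = [
    "SimParams",
    "GroundTruth",
    "simulate_session",
    "simulate_var_pair",
    "simulate_lick_stream",
    "simulate_motion_energy",
    "simulate_correlated_pair",
]


def component_rng(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-component substream derived from (seed, name)."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


@dataclass
class SimParams:
    """Ground-truth parameters of a simulated dual-region session.

    Amplitudes are in dF/F0 (plateau) units; ``inter_region_lag`` is signed
    with positive values meaning region B precedes region A;
    ``shared_fraction`` is the weight of the common transient drive in
    region B (1 = fully shared, 0 = independent).
    """

    sampling_rate: float = 40.0
    session_length: float = 300.0
    n_events: dict = field(default_factory=lambda: {"digging": 8})
    transient_amplitude: tuple[float, float] = (0.30, 0.25)
    transient_rise: float = 0.3
    transient_decay: float = 1.5
    event_duration: float = 4.0
    inter_region_lag: float = 0.0
    shared_fraction: float = 1.0
    noise_sd: float | tuple[float, float] = 0.01
    bleach_tau: float = 600.0
    bleach_amplitude: float = 0.10
    motion_artifact_sd: float = 1.0
    baseline_F: float = 100.0
    motion_coupling_beta: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")
        if self.transient_rise >= self.transient_decay:
            raise ValueError("transient_rise must be shorter than transient_decay")
        if self.event_duration < 3.0:
            raise ValueError("event_duration must be >= 3 s (digging inclusion rule)")

    @property
    def noise_sd_ab(self) -> tuple[float, float]:
        if np.isscalar(self.noise_sd):
            return float(self.noise_sd), float(self.noise_sd)
        return float(self.noise_sd[0]), float(self.noise_sd[1])


@dataclass
class GroundTruth:
    """True generative quantities stored alongside a simulated session."""

    true_lag: float
    true_correlation: float
    true_beta: float
    event_onsets: np.ndarray
    true_plateau: tuple[float, float]
    latent_drive: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not -1.0 <= self.true_correlation <= 1.0:
            raise ValueError("true_correlation must lie in [-1, 1]")


class SessionSizeError(ValueError):
    """Session too short for the requested event schedule."""


def _transient_kernel(rise: float, decay: float, fs: float) -> np.ndarray:
    """Unit-peak double-exponential kernel sampled until 8 decay constants."""
    t = np.arange(0.0, 8.0 * decay, 1.0 / fs)
    k = np.exp(-t / decay) - np.exp(-t / rise)
    return k / k.max()


def _unit_drive(onsets, duration: float, n: int, fs: float, kernel: np.ndarray) -> np.ndarray:
    """Boxcar event train convolved with the transient kernel, plateau-normalized.

    Normalized so the mean response over [1, 2) s after an isolated onset
    equals 1; region amplitudes then equal the plateau dF/F0 exactly.
    """
    box = np.zeros(n)
    for onset in np.atleast_1d(onsets):
        i0 = round(onset * fs)
        i1 = min(n, i0 + round(duration * fs))
        box[i0:i1] = 1.0
    drive = np.convolve(box, kernel)[:n]
    # reference response of one isolated event, for normalization
    ref_len = round((duration + 8.0) * fs)
    ref_box = np.zeros(ref_len)
    ref_box[: round(duration * fs)] = 1.0
    ref = np.convolve(ref_box, kernel)[:ref_len]
    plateau = ref[round(1.0 * fs) : round(2.0 * fs)].mean()
    return drive / plateau


def _schedule_events(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample digging onsets satisfying the inclusion rules.

    Every event gets >= 10 s of non-digging baseline before onset, >= 3 s
    duration (enforced at construction), and a full (-5, 5) s analysis
    window inside the recording with 1 s margin.
    """
    n = int(params.n_events.get("digging", 0))
    if n == 0:
        return np.empty(0)
    dur, T = params.event_duration, params.session_length
    lo = max(10.0, 5.0) + 1.0
    hi = T - (dur + 5.0 + 1.0)
    needed = lo + n * (dur + 10.0) + 6.0
    if hi <= lo or needed > T:
        raise SessionSizeError(
            f"session_length {T} s too short for {n} events of {dur} s with "
            f">=10 s clean baseline and (-5, 5) s windows (needs >= {needed:.0f} s)"
        )
    onsets: list[float] = []
    for _ in range(20000):
        if len(onsets) == n:
            break
        cand = rng.uniform(lo, hi)
        ok = all(
            (cand - (o + dur) >= 10.0) if cand > o else ((o - (cand + dur)) >= 10.0)
            for o in onsets
        )
        if ok:
            onsets.append(cand)
    if len(onsets) < n:
        raise SessionSizeError(
            f"could not place {n} events of {dur} s in {T} s after rejection sampling; "
            "increase session_length"
        )
    return np.sort(np.asarray(onsets))


def _shift(x: np.ndarray, k: int) -> np.ndarray:
    """Advance a trace by k samples (out[i] = x[i + k]), zero padded."""
    out = np.zeros_like(x)
    if k == 0:
        out[:] = x
    elif k > 0:
        out[: x.size - k] = x[k:]
    else:
        out[-k:] = x[: x.size + k]
    return out


def _smooth_noise(n: int, sigma_samples: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD low-pass Gaussian process (smoothed white noise)."""
    raw = gaussian_filter1d(rng.standard_normal(n), sigma_samples, mode="reflect")
    sd = raw.std()
    return raw / sd if sd > 0 else raw


def simulate_session(
    params: SimParams,
) -> tuple[PhotometrySession, list[BehaviorEvent], GroundTruth]:
    """Simulate one dual-region photometry session.

    Returns the raw-fluorescence session (channels ``region_a_raw``,
    ``region_b_raw``, ``isosbestic_a``, ``isosbestic_b``), the behavioral
    event list (all events satisfy the digging inclusion rules by
    construction), and the stored ground truth.
    """
    fs = params.sampling_rate
    n = round(params.session_length * fs)
    t = np.arange(n) / fs

    onsets = _schedule_events(params, component_rng(params.seed, "events"))
    kernel = _transient_kernel(params.transient_rise, params.transient_decay, fs)
    drive_a = _unit_drive(onsets, params.event_duration, n, fs, kernel)

    lag_samples = round(params.inter_region_lag * fs)
    shared_b = _shift(drive_a, lag_samples)
    indep_rng = component_rng(params.seed, "independent_drive")
    indep = _smooth_noise(n, params.transient_decay * fs, indep_rng)
    drive_sd = drive_a.std()
    if drive_sd > 0:
        indep = indep * drive_sd  # match the shared drive's scale
    s = params.shared_fraction
    drive_b = s * shared_b + (1.0 - s) * indep

    amp_a, amp_b = params.transient_amplitude
    ca_a = amp_a * drive_a
    ca_b = amp_b * drive_b

    bleach = params.bleach_amplitude * np.exp(-t / params.bleach_tau)
    motion = _smooth_noise(n, 0.2 * fs, component_rng(params.seed, "motion"))
    motion *= params.motion_artifact_sd / params.baseline_F

    sd_a, sd_b = params.noise_sd_ab
    noise = {
        name: component_rng(params.seed, f"noise_{name}").standard_normal(n) * sd
        for name, sd in [
            ("region_a", sd_a),
            ("region_b", sd_b),
            ("iso_a", sd_a),
            ("iso_b", sd_b),
        ]
    }

    F0 = params.baseline_F
    channels = {
        "region_a_raw": F0 * (1.0 + bleach + motion + ca_a + noise["region_a"]),
        "region_b_raw": F0 * (1.0 + bleach + motion + ca_b + noise["region_b"]),
        "isosbestic_a": F0 * (1.0 + bleach + motion + noise["iso_a"]),
        "isosbestic_b": F0 * (1.0 + bleach + motion + noise["iso_b"]),
    }

    session = PhotometrySession(
        time=t,
        channels=channels,
        sampling_rate=fs,
        metadata={"seed": params.seed, "synthetic": True},
    )
    events = [
        BehaviorEvent("digging", float(o), float(o + params.event_duration))
        for o in onsets
    ]

    truth = GroundTruth(
        true_lag=params.inter_region_lag,
        true_correlation=_population_correlation(ca_a, ca_b, onsets, fs, sd_a, sd_b),
        true_beta=params.motion_coupling_beta,
        event_onsets=onsets,
        true_plateau=(
            _noiseless_plateau(ca_a, bleach, onsets, fs),
            _noiseless_plateau(ca_b, bleach, onsets, fs),
        ),
        latent_drive=drive_a,
    )
    return session, events, truth


def _noiseless_plateau(ca: np.ndarray, bleach: np.ndarray, onsets: np.ndarray,
                       fs: float) -> float:
    """Mean plateau dF/F0 implied by the noiseless components.

    Applies the trial dF/F0 rule (baseline -4..-2 s, plateau 1..2 s) to the
    noiseless fluorescence ``1 + bleach + ca``; with zero bleaching this
    equals the region's transient amplitude up to residual overlap from
    neighboring events.
    """
    if onsets.size == 0:
        return 0.0
    clean = 1.0 + bleach + ca
    vals = []
    for o in onsets:
        b0, b1 = round((o - 4.0) * fs), round((o - 2.0) * fs)
        p0, p1 = round((o + 1.0) * fs), round((o + 2.0) * fs)
        F0 = clean[b0:b1].mean()
        vals.append((clean[p0:p1].mean() - F0) / F0)
    return float(np.mean(vals))


def _population_correlation(
    ca_a: np.ndarray,
    ca_b: np.ndarray,
    onsets: np.ndarray,
    fs: float,
    sd_a: float,
    sd_b: float,
) -> float:
    """Population trial correlation implied by the noiseless components.

    Correlation of the noiseless calcium traces over the (-5, 5) s trial
    windows, attenuated by the per-channel noise factor
    ``sd(signal) / sqrt(sd(signal)^2 + noise_sd^2)``.
    """
    if onsets.size == 0:
        return 0.0
    rs = []
    for o in onsets:
        i0, i1 = round((o - 5.0) * fs), round((o + 5.0) * fs)
        a, b = ca_a[i0:i1], ca_b[i0:i1]
        if a.std() == 0 or b.std() == 0:
            continue
        att_a = a.std() / np.hypot(a.std(), sd_a)
        att_b = b.std() / np.hypot(b.std(), sd_b)
        rs.append(np.corrcoef(a, b)[0, 1] * att_a * att_b)
    return float(np.clip(np.mean(rs), -1.0, 1.0)) if rs else 0.0


def _coef_array(c, order: int, name: str) -> np.ndarray:
    arr = np.zeros(order)
    if np.isscalar(c):
        arr[0] = c
    else:
        c = np.asarray(c, dtype=float)
        if c.size != order:
            raise ValueError(f"{name} must be scalar or length-{order} sequence")
        arr[:] = c
    return arr


def simulate_var_pair(
    a_xy,
    a_yx,
    order: int = 1,
    n: int = 2000,
    noise_sd: float = 1.0,
    seed: int = 0,
    a_xx=0.0,
    a_yy=0.0,
    burn_in: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Realize a bivariate VAR with the given cross/diagonal coefficients.

    ``a_xy`` is the influence of x on y (appears in the y equation) and
    ``a_yx`` the reverse; coefficients may be scalars (lag-1 only) or
    length-``order`` sequences. Raises if the companion matrix has spectral
    radius >= 1 (explosive system).
    """
    if n <= 10 * order:
        raise ValueError(f"n = {n} must exceed 10 * order = {10 * order}")
    axy = _coef_array(a_xy, order, "a_xy")
    ayx = _coef_array(a_yx, order, "a_yx")
    axx = _coef_array(a_xx, order, "a_xx")
    ayy = _coef_array(a_yy, order, "a_yy")
    # A_k maps (x_{t-k}, y_{t-k}) -> (x_t, y_t)
    A = [np.array([[axx[k], ayx[k]], [axy[k], ayy[k]]]) for k in range(order)]
    companion = np.zeros((2 * order, 2 * order))
    companion[:2, :] = np.hstack(A)
    if order > 1:
        companion[2:, :-2] = np.eye(2 * (order - 1))
    radius = np.max(np.abs(np.linalg.eigvals(companion)))
    if radius >= 1.0:
        raise ValueError(f"coefficient set is explosive (spectral radius {radius:.3f} >= 1)")
    rng = np.random.default_rng(seed)
    total = n + burn_in
    e = rng.standard_normal((total, 2)) * noise_sd
    z = np.zeros((total, 2))
    for t in range(order, total):
        acc = e[t].copy()
        for k in range(order):
            acc += A[k] @ z[t - 1 - k]
        z[t] = acc
    return z[burn_in:, 0].copy(), z[burn_in:, 1].copy()


def simulate_lick_stream(
    cue_times,
    response_prob: float = 1.0,
    ili_distribution: float | Callable[[np.random.Generator, int], np.ndarray] = 0.15,
    seed: int = 0,
    licks_per_cue: int = 5,
    latency: tuple[float, float] = (0.2, 0.5),
) -> np.ndarray:
    """Simulate a lick-sensor timestamp stream in response to cues.

    Each cue elicits, with probability ``response_prob``, a bout of
    ``licks_per_cue`` licks whose first lick follows the cue by a uniform
    latency and whose inter-lick intervals are drawn from
    ``ili_distribution`` (a constant, or a callable ``(rng, size) ->
    intervals``). Output timestamps are strictly increasing; licks that
    would collide with the next cue's bout are dropped.
    """
    rng = np.random.default_rng(seed)
    cues = np.sort(np.asarray(cue_times, dtype=float))
    licks: list[float] = []
    for cue in cues:
        if rng.uniform() >= response_prob:
            continue
        start = cue + rng.uniform(*latency)
        if np.isscalar(ili_distribution):
            ilis = np.full(licks_per_cue - 1, float(ili_distribution))
        else:
            ilis = np.asarray(ili_distribution(rng, licks_per_cue - 1), dtype=float)
        times = start + np.concatenate([[0.0], np.cumsum(ilis)])
        for lt in times:
            if not licks or lt > licks[-1]:
                licks.append(float(lt))
    return np.asarray(licks)


def simulate_motion_energy(
    latent_drive: np.ndarray,
    gain: float,
    noise_sd: float,
    fs_video: float = 30.0,
    seed: int = 0,
    fs_latent: float = 40.0,
) -> MotionEnergyTrace:
    """Motion-energy trace at video rate, correlated with the latent drive.

    ``gain * latent`` (resampled to the video clock) plus half-normal noise
    ``|N(0, noise_sd)|`` — nonnegative by construction without clipping, and
    independent of the drive so a downstream OLS slope stays unbiased.
    """
    if gain < 0:
        raise ValueError("gain must be nonnegative")
    latent = np.asarray(latent_drive, dtype=float)
    t_latent = np.arange(latent.size) / fs_latent
    t_video = np.arange(0.0, t_latent[-1] + 0.5 / fs_video, 1.0 / fs_video)
    latent_v = np.interp(t_video, t_latent, latent)
    rng = np.random.default_rng(seed)
    noise = np.abs(rng.standard_normal(t_video.size) * noise_sd) if noise_sd > 0 else 0.0
    return MotionEnergyTrace(time=t_video, values=gain * latent_v + noise, source_rate=fs_video)


def simulate_correlated_pair(
    rho: float,
    n: int,
    seed: int = 0,
    smooth_sigma: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stationary trace pair with exact population correlation ``rho``.

    ``y = rho*z1 + sqrt(1-rho^2)*z2`` with iid Gaussian ``z1, z2``;
    optionally both smoothed by the same Gaussian kernel, which preserves
    the population correlation (identical filtering of proportional
    spectra). Used for correlation-recovery tests where the population r
    must be known exactly.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    x = z1
    y = rho * z1 + np.sqrt(1.0 - rho**2) * z2
    if smooth_sigma > 0:
        x = gaussian_filter1d(x, smooth_sigma, mode="reflect")
        y = gaussian_filter1d(y, smooth_sigma, mode="reflect")
    return x, y
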