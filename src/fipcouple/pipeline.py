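"""Pipeline orchestration and cohort-level statistics.

Runs the full per-session chain — isosbestic correction, trial selection,
behavior-locked dF/F0, coupling metrics, Granger causality, motion GLM —
and aggregates per-trial results to per-subject and per-group tables, with
nonparametric group comparisons (Mann-Whitney unpaired, Wilcoxon paired).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .causality import gc_pipeline, summarize_gc
from .config import PipelineConfig
from .coupling import DegenerateTraceError, trial_coupling
from .events import BehaviorEvent, select_digging_trials, select_turning_trials
from .motion_glm import fit_motion_glm, gaussian_convolve, summarize_glm
from .preprocess import PhotometrySession, extract_trial, isosbestic_correct
from .synthetic import SimParams, simulate_session, simulate_motion_energy

__all__ = [
    "SessionResult",
    "run_session",
    "run_cohort",
    "group_compare",
    "simulate_cohort",
]


@dataclass
class SessionResult:
    """Per-trial metric table and exclusion log for one session."""

    trials: pd.DataFrame
    exclusions: list = field(default_factory=list)
    gc_summary: dict = field(default_factory=dict)
    subject: str = ""
    group: str = ""


def _corrected_session(session: PhotometrySession, config: PipelineConfig) -> PhotometrySession:
    """Isosbestic-correct both signal channels, leaving raw channels intact."""
    channels = dict(session.channels)
    for sig, iso in ((config.channel_a, config.isosbestic_a),
                     (config.channel_b, config.isosbestic_b)):
        if sig not in channels:
            raise KeyError(f"session lacks required channel {sig!r}")
        if iso in channels:
            channels[sig] = isosbestic_correct(channels[sig], channels[iso],
                                               session.sampling_rate)
    return PhotometrySession(time=session.time, channels=channels,
                             sampling_rate=session.sampling_rate,
                             metadata=dict(session.metadata))


def run_session(
    session: PhotometrySession,
    events: list[BehaviorEvent],
    config: PipelineConfig | None = None,
    motion_energy_40hz: np.ndarray | None = None,
    with_gc: bool = True,
) -> SessionResult:
    """Run the full analysis chain on one session.

    Returns a per-trial table with correlation, phase lag, amplitudes, GC
    (both directions, with p-values) and, when a motion-energy trace on the
    photometry clock is supplied, GLM beta and R^2. Every exclusion carries
    the violated rule.
    """
    config = config or PipelineConfig()
    fs = session.sampling_rate
    corrected = _corrected_session(session, config)

    included_dig, excl_dig = select_digging_trials(events)
    included_turn, excl_turn = select_turning_trials(events)
    exclusions = [(e.event.event_type, e.event.onset, e.rule)
                  for e in excl_dig + excl_turn]

    regressor = None
    if motion_energy_40hz is not None:
        regressor = gaussian_convolve(np.asarray(motion_energy_40hz, dtype=float),
                                      fs, width=config.glm_kernel_width)

    rows = []
    gc_results = []
    for ev in included_dig + included_turn:
        behavior = ev.event_type
        try:
            tw = extract_trial(corrected, ev.onset, config.channel_a,
                               config.channel_b, behavior)
        except ValueError as err:
            exclusions.append((behavior, ev.onset, str(err)))
            continue
        row: dict = {"behavior": behavior, "onset": ev.onset}
        try:
            m = trial_coupling(tw.dff_a, tw.dff_b, fs, behavior,
                               max_lag=config.max_lag,
                               window=config.sliding_window,
                               step=config.sliding_step)
        except DegenerateTraceError as err:
            exclusions.append((behavior, ev.onset, str(err)))
            continue
        row.update(correlation=m.correlation, phase_lag=m.phase_lag,
                   plateau_a=m.plateau_a, plateau_b=m.plateau_b,
                   peak_a=m.peak_a, peak_b=m.peak_b)
        if with_gc:
            gc = gc_pipeline(tw.dff_a, tw.dff_b, fs, alpha=config.gc_alpha,
                             max_order=config.gc_max_order,
                             max_diff=config.gc_max_diff,
                             criterion=config.gc_criterion)
            if gc is None:
                exclusions.append((behavior, ev.onset, "non-stationary at max_diff"))
            else:
                gc_results.append(gc)
                row.update(gc_ab=gc.gc_ab, gc_ba=gc.gc_ba,
                           gc_p_ab=gc.p_ab, gc_p_ba=gc.p_ba,
                           gc_order=gc.lag_order, gc_d=gc.d_a)
        if regressor is not None:
            i0 = session.index_of(ev.onset) + round(tw.window[0] * fs)
            i1 = i0 + tw.dff_a.size
            if 0 <= i0 and i1 <= regressor.size:
                fit = fit_motion_glm(tw.dff_a, regressor[i0:i1])
                if fit is not None:
                    row.update(glm_beta=fit.beta, glm_r2=fit.r_squared)
        rows.append(row)

    trials = pd.DataFrame(rows)
    gc_summary = summarize_gc(gc_results, config.gc_alpha) if gc_results else {}
    return SessionResult(
        trials=trials,
        exclusions=exclusions,
        gc_summary=gc_summary,
        subject=str(session.metadata.get("subject", "")),
        group=str(session.metadata.get("group", "")),
    )


def run_cohort(
    results: list[SessionResult],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Aggregate per-session results to one row per subject.

    Default aggregation is the mean of per-trial values (``mean_trial_r``
    mode); correlation/lag/amplitude/GLM columns are averaged, GC means are
    taken over significant trials via each session's summary.
    """
    config = config or PipelineConfig()
    rows = []
    for res in results:
        if res.trials.empty:
            continue
        row = {"subject": res.subject, "group": res.group,
               "n_trials": len(res.trials)}
        for col in ("correlation", "phase_lag", "plateau_a", "plateau_b",
                    "peak_a", "peak_b", "glm_beta", "glm_r2"):
            if col in res.trials and res.trials[col].notna().any():
                row[col] = float(res.trials[col].dropna().mean())
        for key in ("mean_gc_ab", "mean_gc_ba",
                    "fraction_significant_ab", "fraction_significant_ba"):
            if key in res.gc_summary:
                row[key] = res.gc_summary[key]
        rows.append(row)
    return pd.DataFrame(rows)


def group_compare(values_a, values_b, paired: bool = False) -> tuple[float, float]:
    """Nonparametric two-tailed group comparison.

    Mann-Whitney U for unpaired data, Wilcoxon matched-pairs for paired.
    All-tied data (no separation) returns p = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs n >= 3")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison needs equal-length groups")
        diffs = a - b
        if np.all(diffs == 0):
            warnings.warn("all paired differences zero: p = 1", RuntimeWarning,
                          stacklevel=2)
            return 0.0, 1.0
        stat, p = stats.wilcoxon(a, b)
        return float(stat), float(p)
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn("all values tied: p = 1", RuntimeWarning, stacklevel=2)
        return float(a.size * b.size / 2.0), 1.0
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(stat), float(p)


def simulate_cohort(
    n_subjects: int,
    base_params: SimParams,
    seed: int,
    group: str = "control",
    with_motion: bool = False,
    config: PipelineConfig | None = None,
    with_gc: bool = True,
) -> list[SessionResult]:
    """Simulate and analyze a cohort of subjects with shared parameters.

    Each subject gets an independent seed derived from ``seed``; sessions
    are run through :func:`run_session` and labelled with the group name.
    """
    import dataclasses

    config = config or PipelineConfig()
    out = []
    for i in range(n_subjects):
        params = dataclasses.replace(base_params, seed=int(seed) * 10_000 + i)
        session, events, truth = simulate_session(params)
        session.metadata.update(subject=f"{group}_{i}", group=group)
        me40 = None
        if with_motion:
            gain = (params.transient_amplitude[0] / params.motion_coupling_beta
                    if params.motion_coupling_beta > 0 else 1.0)
            me = simulate_motion_energy(truth.latent_drive, gain=gain,
                                        noise_sd=0.05 * gain,
                                        fs_video=params.sampling_rate,
                                        seed=params.seed + 7,
                                        fs_latent=params.sampling_rate)
            me40 = me.values[: session.n_samples]
            if me40.size < session.n_samples:
                me40 = np.pad(me40, (0, session.n_samples - me40.size), mode="edge")
        res = run_session(session, events, config, motion_energy_40hz=me40,
                          with_gc=with_gc)
        res.subject, res.group = f"{group}_{i}", group
        out.append(res)
    return out
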