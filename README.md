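# fipcouple

Dual-site fiber-photometry coupling analysis for cortico-striatal recordings.

Simultaneous photometry from primary motor cortex (M1) and dorsal striatum
(STR) at 40 Hz yields two calcium traces whose behavior-locked co-fluctuation
— "cortico-striatal coupling" — changes in parkinsonian mouse models.
`fipcouple` implements the full analysis chain for such recordings:

* **Normalization** — ΔF/F0 = (F − F0)/F0 with behavior-specific peri-event
  windows: digging/licking (−5, 5) s with F0 from (−4, −2) s; turning
  (−1, 1) s with F0 from (−1, 0) s. Bleaching and motion artifacts are
  removed by regression on the 405 nm isosbestic channel.
* **Trial selection** — digging trials need ≥ 3 s of digging and ≥ 10 s of
  non-digging baseline; turning trials need ≥ 90° and ≥ 4 s inter-trial
  interval; licks < 1 s apart form bouts.
* **Coupling** — static Pearson *r* (after a zero-phase 0.001–3 Hz bandpass
  and 1 s trim), sliding-window *r* (4 s window, 0.5 s step), and the phase
  lag τ\* = argmax<sub>|τ| ≤ 2 s</sub> |c(τ)| of the lag-wise normalized
  cross-correlation (τ\* > 0 ⇔ region B leads). Plateau (1–2 s) and peak
  (0–0.5 s) amplitudes, and sum-dFF activity over 8 s bins with a
  ΔF/F0-vs-raw QC (*r* ≥ 0.8).
* **Directionality** — time-domain Granger causality in nats,
  GC = ln(σ²<sub>restricted</sub>/σ²<sub>full</sub>), after ADF stationarity
  testing, differencing, and BIC lag-order selection; means reported over
  significant trials (p < 0.05).
* **Motion GLM** — ΔF/F0 regressed on motion energy (summed |frame
  differences|, resampled to 40 Hz, convolved with a 2.5 s Gaussian kernel),
  yielding per-trial β and R².
* **Synthetic sessions** — a generator producing raw two-region fluorescence
  with isosbestic channels, bleaching, shared motion artifacts, event-locked
  transients with a configurable inter-region lag and shared-drive fraction,
  plus lick streams and motion-energy regressors — all with stored ground
  truth, so every estimator has a parameter-recovery test.

## Worked example

```python
from fipcouple import SimParams, simulate_session, run_session

params = SimParams(session_length=200.0, n_events={"digging": 5},
                   inter_region_lag=0.25, shared_fraction=0.95,
                   noise_sd=0.02, seed=42)
session, events, truth = simulate_session(params)
res = run_session(session, events)
print(res.trials[["onset", "correlation", "phase_lag",
                  "plateau_a", "plateau_b", "gc_ab", "gc_p_ab"]].round(3))
```

```
  onset  correlation  phase_lag  plateau_a  plateau_b  gc_ab  gc_p_ab
 49.784        0.994      0.200      0.278      0.247  0.035    0.216
 81.869        0.996      0.150      0.260      0.232  0.045    0.080
 97.909        0.995      0.175      0.271      0.245  0.030    0.347
112.504        0.994      0.250      0.277      0.251  0.054    0.031
168.972        0.997      0.150      0.281      0.248  0.030    0.347
```

The five digging trials recover the generator's truth: trial correlations
≈ 1 (95% shared drive, low noise), phase lags cluster at the true +0.25 s
(positive = striatal channel leads; the slow plateau shape flattens the
cross-correlation peak, so individual trials scatter by a few samples),
and plateau amplitudes match the stored ground truth (0.275, 0.245). The
`gc_ab` column is the M1→STR Granger causality in nats with its F-test
p-value; `res.gc_summary` averages it over significant trials only.

A `fipcouple` command-line tool wraps the same functions
(`simulate`, `preprocess`, `events`, `couple`, `gc`, `glm`, `run`), reading
and writing delimited tables, HDF5 and YAML/JSON configs.

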