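"""Pipeline configuration with the standard analysis defaults.

Defaults encode the canonical analysis settings: 40 Hz sampling, 0.001-3 Hz
bandpass, digging/licking windows (-5, 5) s with (-4, -2) s baseline,
turning (-1, 1) s with (-1, 0) s baseline, 1 s trial trim, 4 s / 0.5 s
sliding correlation, 2 s maximum cross-correlation lag, 8 s sum-dFF bins
with r >= 0.8 QC, GC at alpha 0.05 with BIC lag selection up to order 10
and at most 2 differencings, and a 2.5 s Gaussian GLM kernel.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    sampling_rate: float = 40.0
    band_low: float = 0.001
    band_high: float = 3.0
    trim_seconds: float = 1.0
    windows: dict = field(default_factory=lambda: {
        "digging": {"window": [-5.0, 5.0], "baseline": [-4.0, -2.0]},
        "licking": {"window": [-5.0, 5.0], "baseline": [-4.0, -2.0]},
        "turning": {"window": [-1.0, 1.0], "baseline": [-1.0, 0.0]},
    })
    sliding_window: float = 4.0
    sliding_step: float = 0.5
    max_lag: float = 2.0
    plateau_interval: tuple = (1.0, 2.0)
    peak_interval: tuple = (0.0, 0.5)
    bin_seconds: float = 8.0
    qc_threshold: float = 0.8
    gc_alpha: float = 0.05
    gc_criterion: str = "bic"
    gc_max_order: int = 10
    gc_max_diff: int = 2
    glm_kernel_width: float = 2.5
    subject_aggregation: str = "mean_trial_r"  # or "r_of_mean_trace"
    channel_a: str = "region_a_raw"
    channel_b: str = "region_b_raw"
    isosbestic_a: str = "isosbestic_a"
    isosbestic_b: str = "isosbestic_b"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["plateau_interval"] = list(d["plateau_interval"])
        d["peak_interval"] = list(d["peak_interval"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            import warnings
            warnings.warn(f"ignoring unknown config keys: {sorted(extra)}", stacklevel=2)
        kwargs = {k: v for k, v in d.items() if k in known}
        for key in ("plateau_interval", "peak_interval"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2) if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=False))
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = path.read_text()
        d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(d)
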