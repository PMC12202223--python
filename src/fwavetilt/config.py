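"""Analysis configuration: every threshold of the pipeline in one place.

Defaults are the published or documented values; anything here can be
overridden from a YAML file, and a config round-trips losslessly through
serialization.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    # f-wave frequency tracking
    resample_fs: float = 50.0  # Hz, f-wave analysis rate
    f_band: tuple[float, float] = (4.0, 12.0)  # Hz, Welch anchor search band
    f_half_range: float = 1.5  # Hz, constrained search half-width around f0
    welch_segment_s: float = 10.0
    s_threshold: float = 0.3  # block quality gate
    max_bad_block_fraction: float = 0.10  # recording exclusion rule
    min_valid_fraction: float = 0.5  # per-phase Ff sufficiency

    # ectopic classification
    ectopic_corr_threshold: float = 0.9
    ectopic_rr_threshold: float = 0.4

    # respiration
    pica_band: tuple[float, float] = (0.08, 0.5)  # Hz

    # orthogonal subspace projection
    q_delays: int | None = None  # None -> quarter respiratory period
    max_gap_s: float = 5.0
    min_run_s: float = 60.0

    # activation-series analysis
    peak_threshold: float = 0.25
    peak_halfwidth: float = 0.05  # Hz
    sim_resp_rate: float = 0.14  # Hz
    activation_window_s: float | None = None  # None -> full series
    activation_min_duration_s: float = 60.0

    # statistics
    alpha: float = 0.05
    comparison_pairs: list[tuple[str, str]] = field(default_factory=lambda: [
        ("B1", "B2"), ("B2", "HDT1"), ("HDT1", "HDT2"),
        ("HDT2", "HUT1"), ("HUT1", "HUT2"),
        ("B1", "HDT1"), ("HDT1", "HUT1"),
        ("B2", "HDT2"), ("HDT2", "HUT2"),
    ])

    # default six-phase timeline when the record carries none (s)
    phase_durations: tuple[float, ...] = (120.0, 180.0, 120.0, 180.0, 120.0, 180.0)

    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["f_band"] = list(self.f_band)
        d["pica_band"] = list(self.pica_band)
        d["phase_durations"] = list(self.phase_durations)
        d["comparison_pairs"] = [list(p) for p in self.comparison_pairs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        kw = dict(d)
        if "f_band" in kw:
            kw["f_band"] = tuple(kw["f_band"])
        if "pica_band" in kw:
            kw["pica_band"] = tuple(kw["pica_band"])
        if "phase_durations" in kw:
            kw["phase_durations"] = tuple(kw["phase_durations"])
        if "comparison_pairs" in kw:
            kw["comparison_pairs"] = [tuple(p) for p in kw["comparison_pairs"]]
        return cls(**kw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
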