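"""Analysis configuration: the timing windows and thresholds of the method.

Defaults encode the printed constants of the applied protocol: the arterial
spike occupies the first 2 min; the uptake peak falls in the 2–10 min
window; BP_ND uses washout data to 60 min; SUVR integrates 40–60 min; the
reference detector thresholds Θ at 1660 s over a 1890 s horizon.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .exceptions import WarmkitError

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    arterial_end_s: float = 120.0
    peak_window_s: tuple = (120.0, 600.0)
    washout_end_s: float = 3600.0
    fixed_washout_start_s: float | None = None  # override: t0 fixed instead of at peak
    suvr_window_s: tuple = (2400.0, 3600.0)
    theta_threshold_s: float = 1660.0
    duration_T_s: float = 1890.0
    seed: int = 0
    missing_value: str = "nan"

    def __post_init__(self):
        self.peak_window_s = tuple(float(x) for x in self.peak_window_s)
        self.suvr_window_s = tuple(float(x) for x in self.suvr_window_s)
        lo, hi = self.peak_window_s
        if not (self.arterial_end_s <= lo < hi):
            raise WarmkitError("peak window must follow the arterial phase")
        if self.washout_end_s <= hi and self.washout_end_s <= lo:
            raise WarmkitError("washout_end_s must exceed the start of the peak window")
        s, e = self.suvr_window_s
        if s >= e:
            raise WarmkitError("SUVR window start must precede its end")
        if self.missing_value not in ("nan", "zero"):
            raise WarmkitError("missing_value must be 'nan' or 'zero'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["peak_window_s"] = list(self.peak_window_s)
        d["suvr_window_s"] = list(self.suvr_window_s)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise WarmkitError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise WarmkitError("config file must contain a YAML mapping")
        return cls.from_dict(data)
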