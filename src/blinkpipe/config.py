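"""Pipeline configuration: the standard analysis constants, all overridable."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis constants of the eyeblink pipeline and the stats layer.

    Defaults are the field's standard detection and filtering constants: a trial is
    invalid when pre-CS activity exceeds 7x the reference IQR; a CR needs a
    normalized amplitude above 0.1, onset in [50, 500] ms and peak in
    [100, 1000] ms; perfectly timed CRs peak within 250 +- 50 ms (ISI 250)
    or 500 +- 100 ms (ISI 500).
    """

    filter_factor: float = 7.0
    iqr_scope: str = "session"
    ur_window_ms: float = 500.0
    amplitude_threshold: float = 0.1
    onset_window_ms: tuple[float, float] = (50.0, 500.0)
    peak_window_ms: tuple[float, float] = (100.0, 1000.0)
    onset_threshold: float = 0.05
    perfect_windows_ms: Mapping[int, float] = field(
        default_factory=lambda: {250: 50.0, 500: 100.0}
    )
    per_day_average_perfect: bool = False
    alpha: float = 0.05
    df_method: str = "containment"
    correction: str = "holm"
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["onset_window_ms"] = list(self.onset_window_ms)
        d["peak_window_ms"] = list(self.peak_window_ms)
        d["perfect_windows_ms"] = {
            int(k): float(v) for k, v in self.perfect_windows_ms.items()
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(
                f"unknown pipeline config fields: {sorted(unknown)}"
            )
        if "onset_window_ms" in d:
            d["onset_window_ms"] = tuple(d["onset_window_ms"])
        if "peak_window_ms" in d:
            d["peak_window_ms"] = tuple(d["peak_window_ms"])
        if "perfect_windows_ms" in d:
            d["perfect_windows_ms"] = {
                int(k): float(v) for k, v in d["perfect_windows_ms"].items()
            }
        return cls(**d)
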