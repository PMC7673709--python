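"""Pipeline configuration: typed options, unit-suffixed times, typo safety.

All internal times are SI seconds; configuration files and CLI flags accept
unit-suffixed strings ("31us", "8.8ms", "4s"). Unknown configuration keys
are rejected rather than ignored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["parse_time", "PipelineConfig", "load_config"]

_UNITS = {"s": 1.0, "ms": 1e-3, "us": 1e-6, "ns": 1e-9}
_TIME_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*(s|ms|us|ns)?\s*$")


def parse_time(value) -> float:
    """Parse a time as SI seconds; accepts numbers or suffixed strings."""
    if isinstance(value, (int, float)):
        return float(value)
    m = _TIME_RE.match(str(value))
    if not m:
        raise ValueError(f"cannot parse time value {value!r}")
    return float(m.group(1)) * _UNITS[m.group(2) or "s"]


@dataclass
class PipelineConfig:
    """Options for the pipeline subcommands (g2 / fit / lsci / simulate)."""

    input: str | None = None
    output_dir: str = "."
    max_lag: float = 8.8e-3
    model: str = "auto"         # "auto" or siegert|siegert_offset|static|mixed
    alpha: float = 0.05
    adaptive_bounds: bool = True
    lsci_kind: str = "spatial"
    spatial_window: int = 5
    temporal_block: int = 25
    n_avg: int = 114
    seed: int | None = None
    log_level: str = "info"

    def __post_init__(self) -> None:
        self.max_lag = parse_time(self.max_lag)
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.model not in ("auto", "siegert", "siegert_offset", "static", "mixed"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.lsci_kind not in ("spatial", "temporal"):
            raise ValueError(
                f"invalid contrast kind {self.lsci_kind!r}; valid kinds: spatial, temporal"
            )
        if self.spatial_window < 3 or self.spatial_window % 2 == 0:
            raise ValueError("spatial_window must be an odd integer >= 3")
        if self.temporal_block < 2:
            raise ValueError("temporal_block must be >= 2")
        if self.n_avg < 1:
            raise ValueError("n_avg must be >= 1")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML/JSON config file and apply non-None overrides.

    Unknown keys raise a ValueError (typo safety).
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded:
            data.update(loaded)
    for k, v in (overrides or {}).items():
        if v is not None:
            data[k] = v
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown configuration key(s): {', '.join(sorted(unknown))}")
    return PipelineConfig(**data)
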