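"""Run configuration and run manifest.

A :class:`RunConfig` collects every stage parameter of the pipeline with
defaults matching the published analysis protocol (9-pixel ROI windows,
15-px drusen threshold, 95% prediction-interval level, 33-point grid,
minimum sampling coverage 0.5, spline df 3).  It round-trips losslessly
through YAML; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    window: int = 9
    threshold_px: float = 15.0
    pi_level: float = 0.95
    prominence_k: float = 2.0
    min_coverage: float = 0.5
    spline_df: int = 3
    lld_convention: str = "table1"
    degrees_to_um: float = 288.0
    grid_rotation_deg: float = 0.0
    scale_factor: float = 1.0
    seed: int = 0
    input_paths: dict = field(default_factory=dict)
    output_dir: str = "out"
    verbosity: str = "info"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class RunManifest:
    """Provenance record of one pipeline run.

    ``counts`` entries of the form ``{"total": t, "included": i,
    "excluded": e}`` must satisfy ``i + e == t``.
    """

    config: dict = field(default_factory=dict)
    input_checksums: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    wall_time_s: float = 0.0
    warnings: list = field(default_factory=list)
    created: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def validate(self) -> None:
        for name, c in self.counts.items():
            if isinstance(c, dict) and {"total", "included", "excluded"} <= set(c):
                if c["included"] + c["excluded"] != c["total"]:
                    raise ValueError(f"inconsistent counts for {name}: {c}")
                if min(c.values()) < 0:
                    raise ValueError(f"negative counts for {name}: {c}")

    def to_json(self, path: str | Path) -> None:
        self.validate()
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))
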